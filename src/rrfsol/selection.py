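"""Recursive shuffle-decoy variable selection.

A regression random forest is trained on the candidate descriptors together
with one shuffled decoy per descriptor, and the number of internal split
nodes using each column ("occurrences") is the importance measure. A
descriptor survives a round when its occurrences exceed a marginal threshold
(default 110 at the default 500-tree forest) *and* are at least those of its
own decoy; survivors are then pruned greedily by descending occurrence count
so that no retained pair has absolute Pearson correlation above a threshold
(default 0.51). The procedure recurses on the surviving set — fresh decoys
each round — until the selection no longer changes.

The occurrence threshold and the forest size are meaningful only as a pair:
halving the forest roughly halves every count. Both are configurable
together in :class:`SelectionParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .descriptors import DescriptorMatrix, add_shuffled_decoys
from .forest import RegressionForest

__all__ = [
    "SelectionParams",
    "OccurrenceProfile",
    "SelectionRound",
    "InsufficientDataError",
    "EmptySelectionError",
    "count_occurrences",
    "decoy_filter",
    "correlation_prune",
    "select_variables",
    "audit_frame",
]


class InsufficientDataError(ValueError):
    pass


class EmptySelectionError(ValueError):
    pass


@dataclass(frozen=True)
class SelectionParams:
    occurrence_threshold: int = 110
    correlation_threshold: float = 0.51
    n_trees: int = 500
    max_features: float = 1 / 3
    min_samples_leaf: int = 5
    max_rounds: int = 10
    min_rows: int = 30
    min_features_per_split: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.occurrence_threshold < 0:
            raise ValueError("occurrence_threshold must be >= 0")
        if not (0 < self.correlation_threshold <= 1):
            raise ValueError("correlation_threshold must be in (0, 1]")


@dataclass
class OccurrenceProfile:
    """Split-node occurrence counts of one forest."""

    counts: dict                 # column name -> int
    n_trees: int
    round_index: int = 0


@dataclass
class SelectionRound:
    """Audit record of one selection round."""

    round_index: int
    profile: OccurrenceProfile
    decoy_map: dict
    offered: list
    after_decoy_filter: list
    selected: list


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, DescriptorMatrix):
        return X.data
    return X


def count_occurrences(X, y, params: SelectionParams) -> OccurrenceProfile:
    """Train one regression forest on (X, y) and count split-node uses.

    The counts sum to the total number of internal nodes over all trees.
    """
    frame = _as_frame(X)
    if frame.shape[1] < 2:
        raise InsufficientDataError("need at least 2 columns")
    if frame.shape[0] < params.min_rows:
        raise InsufficientDataError(
            f"insufficient data: {frame.shape[0]} rows < min_rows={params.min_rows}"
        )
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    # Examine at least min_features_per_split candidate columns per node:
    # with tiny node samples a tree is *forced* to split on whatever column
    # it drew, inflating decoy counts and breaking the parent-vs-decoy
    # comparison on small candidate pools.
    max_features = params.max_features
    if isinstance(max_features, float):
        max_features = max(
            max_features, min(1.0, params.min_features_per_split / frame.shape[1])
        )
    forest = RegressionForest(
        n_trees=params.n_trees,
        max_features=max_features,
        min_samples_leaf=params.min_samples_leaf,
        seed=params.seed,
    ).fit(frame.to_numpy(), y, feature_names=list(frame.columns))
    counts = dict(zip(frame.columns, forest.split_counts().tolist()))
    return OccurrenceProfile(counts=counts, n_trees=params.n_trees)


def decoy_filter(profile: OccurrenceProfile, decoy_map: dict, params: SelectionParams) -> list:
    """Apply the marginal-occurrence and decoy comparisons.

    A parent X is retained iff ``count(X) > occurrence_threshold`` (strict)
    and ``count(X) >= count(X__shuffled)``. Decoy columns themselves are
    always discarded.
    """
    parent_of = decoy_map
    decoy_of = {p: d for d, p in decoy_map.items()}
    retained = []
    for name, count in profile.counts.items():
        if name in parent_of:  # a decoy column
            continue
        if count <= params.occurrence_threshold:
            continue
        decoy = decoy_of.get(name)
        if decoy is not None and count < profile.counts.get(decoy, 0):
            continue
        retained.append(name)
    return retained


def correlation_prune(X, survivors: list, profile: OccurrenceProfile, params: SelectionParams) -> list:
    """Greedy collinearity pruning by descending occurrence count.

    A survivor is accepted iff its absolute Pearson correlation with every
    already-accepted variable is <= the threshold. Ties in occurrence count
    break lexicographically by name, making the result deterministic. Output
    is in acceptance order.
    """
    frame = _as_frame(X)
    if len(survivors) <= 1:
        return list(survivors)
    order = sorted(survivors, key=lambda name: (-profile.counts[name], name))
    sub = frame[order].to_numpy()
    corr = np.corrcoef(sub, rowvar=False)
    accepted_idx: list = []
    for i in range(len(order)):
        if all(abs(corr[i, j]) <= params.correlation_threshold for j in accepted_idx):
            accepted_idx.append(i)
    return [order[i] for i in accepted_idx]


def select_variables(X, y, params: SelectionParams) -> tuple:
    """Iterate [decoys -> count -> decoy filter -> correlation prune] to a
    fixed point.

    ``X`` must be a cleaned matrix *without* decoys; fresh decoy permutations
    are drawn each round from a round-derived seed. The candidate pool of a
    round is the previous round's selection, so the selected set never grows;
    recursion stops when it is unchanged or after ``max_rounds``.

    Returns ``(selected_names, rounds)`` where ``rounds`` is the full audit
    trail.
    """
    frame = _as_frame(X)
    if isinstance(X, DescriptorMatrix) and X.decoy_map:
        raise ValueError("X must not already contain decoys")
    pool = list(frame.columns)
    rounds: list = []
    for r in range(1, params.max_rounds + 1):
        sub = DescriptorMatrix(data=frame[pool], descriptor_set="selection-round")
        with_decoys = add_shuffled_decoys(sub, seed=derive_seed(params.seed, f"decoys-round{r}"))
        round_params = SelectionParams(
            occurrence_threshold=params.occurrence_threshold,
            correlation_threshold=params.correlation_threshold,
            n_trees=params.n_trees,
            max_features=params.max_features,
            min_samples_leaf=params.min_samples_leaf,
            max_rounds=params.max_rounds,
            min_rows=params.min_rows,
            seed=derive_seed(params.seed, f"forest-round{r}"),
        )
        profile = count_occurrences(with_decoys, y, round_params)
        profile.round_index = r
        after_decoy = decoy_filter(profile, with_decoys.decoy_map, params)
        selected = correlation_prune(sub, after_decoy, profile, params)
        rounds.append(
            SelectionRound(
                round_index=r,
                profile=profile,
                decoy_map=dict(with_decoys.decoy_map),
                offered=list(pool),
                after_decoy_filter=after_decoy,
                selected=selected,
            )
        )
        if not selected:
            raise EmptySelectionError(
                "no variable survived round 1; the occurrence threshold "
                f"({params.occurrence_threshold}) is likely too high for a "
                f"{params.n_trees}-tree forest on this dataset — lower the "
                "threshold or grow more trees"
                if r == 1
                else f"selection emptied at round {r}"
            )
        if set(selected) == set(pool):
            pool = selected
            break
        pool = selected
    return pool, rounds


def audit_frame(rounds: list, params: SelectionParams | None = None) -> pd.DataFrame:
    """Flatten the per-round audit trail to a table.

    Columns: round, variable, occurrences, shuffled_occurrences, decision,
    reason.
    """
    params = params or SelectionParams()
    records = []
    for rnd in rounds:
        decoy_of = {p: d for d, p in rnd.decoy_map.items()}
        selected = set(rnd.selected)
        after_decoy = set(rnd.after_decoy_filter)
        for name in rnd.offered:
            count = rnd.profile.counts[name]
            shuffled = rnd.profile.counts.get(decoy_of.get(name), np.nan)
            if name in selected:
                decision, reason = "keep", "selected"
            elif name in after_decoy:
                decision, reason = "drop", "correlation prune"
            elif count <= params.occurrence_threshold:
                decision, reason = "drop", "at or below occurrence threshold"
            else:
                decision, reason = "drop", "decoy outranked"
            records.append(
                (rnd.round_index, name, count, shuffled, decision, reason)
            )
    return pd.DataFrame(
        records,
        columns=["round", "variable", "occurrences", "shuffled_occurrences", "decision", "reason"],
    )
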