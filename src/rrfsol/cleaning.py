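"""Recursive prediction-variance (PV) cleaning of the UNRELIABLE set.

The PV of a molecule is the (n-1)-denominator variance of the individual
tree predictions of a regression forest at that molecule's descriptor row.
For a molecule *inside* the forest's training set this is a label-anomaly
score: the bootstrap trees that sampled the molecule carry its reported
logS down to their leaves, while the out-of-bag trees predict the value
implied by its descriptors — a grossly mislabelled molecule makes the two
groups disagree and its PV jumps by roughly p(1-p) times the squared label
shift (p being the in-bag fraction, about 0.63). For a molecule the forest
never saw, the PV reflects only local model uncertainty and carries no
information about the molecule's own label; such held-out PVs also sit on a
systematically larger scale. The recursion below is built around that
asymmetry:

1. *Split pass* — the UNRELIABLE set is split 50/50; a forest trained on one
   half scores its own half in-ensemble and the other half held-out, and the
   molecules are labelled CLEAN (PV at or below threshold) or UNCLEAN.
2. *Rescoring pass* — a companion forest trained on the whole UNRELIABLE set
   assigns every molecule an in-ensemble PV and all labels are redrawn on
   this single comparable scale (both directions of relabelling happen
   here).
3. *Refinement passes* — a forest retrained on the current CLEAN set
   rescores the CLEAN members in-ensemble; molecules beyond the threshold
   are expelled. Expulsion-only refinement makes the CLEAN set monotone
   non-increasing, so a label fixed point is guaranteed; cycle detection is
   retained as a safeguard.

The threshold can be fixed or optimized over a grid (by default quantiles of
the split-pass PVs) by minimizing the RMSE of a forest trained on the
resulting CLEAN set and evaluated on the RELIABLE test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .forest import RegressionForest

__all__ = [
    "CleaningParams",
    "PVRecord",
    "CleaningResult",
    "CleaningError",
    "prediction_variance",
    "initial_pv_pass",
    "recursive_clean",
    "optimize_threshold",
    "clean_dataset",
    "HELD_OUT",
    "IN_ENSEMBLE",
]

HELD_OUT = "held_out"
IN_ENSEMBLE = "in_ensemble"

CLEAN = "CLEAN"
UNCLEAN = "UNCLEAN"


class CleaningError(ValueError):
    pass


@dataclass(frozen=True)
class CleaningParams:
    """Parameters of the recursive PV cleaning.

    ``pv_threshold`` is a positive number or the string ``"optimize"``.
    ``split_fraction`` is fixed at 0.5. The default threshold grid (used
    when optimizing and ``threshold_grid`` is None) is the split-pass PV
    quantiles at ``grid_quantiles`` — scale-free, adapting to any dataset.
    """

    pv_threshold: float | str = "optimize"
    split_fraction: float = 0.5
    n_trees: int = 300
    max_features: float = 1.0
    min_samples_leaf: int = 1
    max_iterations: int = 20
    min_clean: int = 20
    threshold_grid: tuple | None = None
    grid_quantiles: tuple = (0.3, 0.45, 0.6, 0.75, 0.9, 0.95)
    seed: int = 0

    def __post_init__(self):
        if self.split_fraction != 0.5:
            raise ValueError("split_fraction is fixed at 0.5")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if isinstance(self.pv_threshold, str):
            if self.pv_threshold != "optimize":
                raise ValueError("pv_threshold must be a number or 'optimize'")
        elif self.pv_threshold <= 0:
            raise ValueError("pv_threshold must be > 0")


@dataclass(frozen=True)
class PVRecord:
    molecule_id: str
    pv: float
    pv_source: str              # held_out | in_ensemble
    label: str                  # CLEAN | UNCLEAN
    iteration: int


@dataclass
class CleaningResult:
    clean_ids: list
    unclean_ids: list
    trace: list                 # list of PVRecord, all iterations
    n_iterations: int
    converged: bool
    threshold: float
    objective: pd.DataFrame | None = None   # threshold optimization table

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.iteration, r.molecule_id, r.pv, r.pv_source, r.label) for r in self.trace],
            columns=["iteration", "molecule_id", "pv", "pv_source", "label"],
        )


def prediction_variance(forest: RegressionForest, x) -> float | np.ndarray:
    """Variance (n-1 denominator) of the per-tree predictions at ``x``.

    Identical trees give PV = 0; a single-tree forest is an error. Accepts a
    single row or a matrix (vectorized).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pv = forest.prediction_variance(x)
    return float(pv[0]) if single else pv


def _forest(params: CleaningParams, seed: int) -> RegressionForest:
    return RegressionForest(
        n_trees=params.n_trees,
        max_features=params.max_features,
        min_samples_leaf=params.min_samples_leaf,
        seed=seed,
    )


def _check_xy(X, y, ids):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if ids is None:
        ids = [f"u{i:05d}" for i in range(n)]
    ids = list(ids)
    if len(ids) != n or y.shape[0] != n:
        raise ValueError("X, y and ids must agree in length")
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    return X, y, ids


def initial_pv_pass(X, y, params: CleaningParams, ids=None):
    """Split pass: 50/50 split, one forest trained on half A.

    Half A (the training half) receives in-ensemble PVs, half B held-out
    PVs; no symmetric second model is trained. Returns
    ``(records, pv, half_a_mask)`` where labels follow
    ``pv <= pv_threshold`` when the threshold is numeric (labels are filled
    with UNCLEAN when it is still to be optimized).
    """
    X, y, ids = _check_xy(X, y, ids)
    n = X.shape[0]
    if n < 2 * params.min_clean:
        raise CleaningError(f"insufficient data for cleaning: {n} molecules")
    rng = np.random.default_rng(derive_seed(params.seed, "split"))
    half_a = np.zeros(n, dtype=bool)
    half_a[rng.choice(n, n // 2, replace=False)] = True
    forest = _forest(params, derive_seed(params.seed, "split-forest")).fit(X[half_a], y[half_a])
    pv = np.empty(n)
    pv[half_a] = forest.prediction_variance(X[half_a])
    pv[~half_a] = forest.prediction_variance(X[~half_a])
    thr = params.pv_threshold if not isinstance(params.pv_threshold, str) else np.inf
    records = [
        PVRecord(
            molecule_id=ids[i],
            pv=float(pv[i]),
            pv_source=IN_ENSEMBLE if half_a[i] else HELD_OUT,
            label=CLEAN if pv[i] <= thr else UNCLEAN,
            iteration=1,
        )
        for i in range(n)
    ]
    return records, pv, half_a


def recursive_clean(X, y, threshold: float, params: CleaningParams, ids=None) -> CleaningResult:
    """Run the full recursion at a fixed PV threshold.

    Ties at the threshold count as CLEAN ("within the threshold" read
    inclusively). Stops at a label fixed point, on cycle detection (the
    iteration with the smallest UNCLEAN count is returned with a warning),
    or at ``max_iterations``.
    """
    X, y, ids = _check_xy(X, y, ids)
    n = X.shape[0]
    if not np.isfinite(threshold) and threshold > 0:
        # +inf: everything is within the threshold after one pass
        pass
    records, pv, half_a = initial_pv_pass(X, y, params, ids)
    clean = pv <= threshold
    trace = [
        PVRecord(r.molecule_id, r.pv, r.pv_source, CLEAN if clean[i] else UNCLEAN, 1)
        for i, r in enumerate(records)
    ]
    if params.max_iterations == 1:
        return CleaningResult(
            clean_ids=[ids[i] for i in range(n) if clean[i]],
            unclean_ids=[ids[i] for i in range(n) if not clean[i]],
            trace=trace,
            n_iterations=1,
            converged=False,
            threshold=threshold,
        )

    # Rescoring pass: companion forest over the full set, single PV scale.
    companion = _forest(params, derive_seed(params.seed, "companion-forest")).fit(X, y)
    pv_full = companion.prediction_variance(X)
    new_clean = pv_full <= threshold
    trace.extend(
        PVRecord(ids[i], float(pv_full[i]), IN_ENSEMBLE, CLEAN if new_clean[i] else UNCLEAN, 2)
        for i in range(n)
    )
    converged = bool((new_clean == clean).all())
    clean = new_clean
    it = 2

    seen = {clean.tobytes(): 2}
    best = (int((~clean).sum()), clean.copy(), 2)
    while not converged and it < params.max_iterations:
        it += 1
        if clean.sum() < params.min_clean:
            warnings.warn(
                f"CLEAN set fell below {params.min_clean} molecules at iteration {it}; stopping"
            )
            break
        refit = _forest(params, derive_seed(params.seed, "refine-forest")).fit(X[clean], y[clean])
        pv_clean = refit.prediction_variance(X[clean])
        new = clean.copy()
        new[np.where(clean)[0][pv_clean > threshold]] = False
        pv_iter = np.where(clean, np.nan, pv_full)
        pv_iter[np.where(clean)[0]] = pv_clean
        trace.extend(
            PVRecord(
                ids[i],
                float(pv_iter[i]) if np.isfinite(pv_iter[i]) else float(pv_full[i]),
                IN_ENSEMBLE,
                CLEAN if new[i] else UNCLEAN,
                it,
            )
            for i in range(n)
        )
        if (new == clean).all():
            converged = True
            clean = new
            break
        key = new.tobytes()
        if key in seen:
            warnings.warn(
                f"label cycle detected at iteration {it}; returning the "
                f"iteration with the smallest UNCLEAN count"
            )
            if int((~new).sum()) < best[0]:
                best = (int((~new).sum()), new.copy(), it)
            clean = best[1]
            break
        seen[key] = it
        if int((~new).sum()) < best[0]:
            best = (int((~new).sum()), new.copy(), it)
        clean = new

    return CleaningResult(
        clean_ids=[ids[i] for i in range(n) if clean[i]],
        unclean_ids=[ids[i] for i in range(n) if not clean[i]],
        trace=trace,
        n_iterations=it,
        converged=converged,
        threshold=threshold,
    )


def optimize_threshold(X, y, X_reliable, y_reliable, params: CleaningParams, ids=None):
    """Choose the PV threshold minimizing RMSE on the RELIABLE test set.

    For each candidate threshold the full recursion is run, a forest is
    trained on the resulting CLEAN set and evaluated on the reliable test
    set; the argmin threshold is returned (ties favour the larger threshold,
    i.e. keeping more data). Candidates yielding a degenerate CLEAN set are
    skipped with a warning.

    Returns ``(threshold, objective_frame)``.
    """
    X, y, ids = _check_xy(X, y, ids)
    X_reliable = np.asarray(X_reliable, dtype=float)
    y_reliable = np.asarray(y_reliable, dtype=float)
    if y_reliable.size == 0:
        raise CleaningError("reliable test set is empty; cannot optimize the PV threshold")

    if params.threshold_grid is not None:
        grid = list(params.threshold_grid)
    else:
        _, pv1, _ = initial_pv_pass(X, y, params, ids)
        grid = np.quantile(pv1, params.grid_quantiles).tolist()
    if not grid:
        raise CleaningError("empty threshold grid")

    rows = []
    best = None  # (rmse, threshold)
    for thr in grid:
        result = recursive_clean(X, y, thr, params, ids)
        n_clean = len(result.clean_ids)
        if n_clean < params.min_clean:
            warnings.warn(f"threshold {thr:.4g} leaves {n_clean} CLEAN molecules; skipped")
            rows.append((thr, n_clean, np.nan))
            continue
        mask = np.isin(ids, result.clean_ids)
        forest = _forest(params, derive_seed(params.seed, "objective-forest")).fit(X[mask], y[mask])
        rmse = float(np.sqrt(np.mean((forest.predict(X_reliable) - y_reliable) ** 2)))
        rows.append((thr, n_clean, rmse))
        if best is None or rmse < best[0] or (rmse == best[0] and thr > best[1]):
            best = (rmse, thr)
    objective = pd.DataFrame(rows, columns=["threshold", "n_clean", "rmse_reliable"])
    if best is None:
        raise CleaningError("every candidate threshold produced a degenerate CLEAN set")
    return best[1], objective


def clean_dataset(X, y, X_reliable=None, y_reliable=None, params: CleaningParams | None = None, ids=None) -> CleaningResult:
    """High-level entry: optimize the threshold if requested, then clean."""
    params = params or CleaningParams()
    if isinstance(params.pv_threshold, str):  # "optimize"
        if X_reliable is None or y_reliable is None:
            raise CleaningError("reliable test data required to optimize the threshold")
        threshold, objective = optimize_threshold(X, y, X_reliable, y_reliable, params, ids)
    else:
        threshold, objective = float(params.pv_threshold), None
    result = recursive_clean(X, y, threshold, params, ids)
    result.objective = objective
    return result
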