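"""End-to-end training pipeline on a numeric modelling table.

Wires the stages together in the workflow's canonical order:

1. reliability partition (RELIABLE molecules are the optimization
   yardstick and never enter cleaning);
2. shuffle-decoy variable selection on the full modelling set;
3. recursive PV cleaning of the UNRELIABLE molecules, restricted to the
   selected variables, with the threshold optimized against the RELIABLE
   set;
4. consensus training on CLEAN (optionally plus RELIABLE) molecules.

The numeric interface (ids, X, y, reliable mask) keeps the pipeline equally
usable from curated chemistry data and from synthetic benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .cleaning import CleaningParams, CleaningResult, clean_dataset
from .consensus import ConsensusModel, ConsensusParams, train_consensus
from .selection import SelectionParams, select_variables

__all__ = ["PipelineParams", "PipelineResult", "train_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    selection: SelectionParams = field(default_factory=SelectionParams)
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    include_reliable_in_training: bool = True
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineParams":
        """Re-derive all stage seeds from one base seed."""
        return PipelineParams(
            selection=SelectionParams(
                **{
                    **{k: getattr(self.selection, k) for k in self.selection.__dataclass_fields__},
                    "seed": derive_seed(seed, "selection"),
                }
            ),
            cleaning=CleaningParams(
                **{
                    **{k: getattr(self.cleaning, k) for k in self.cleaning.__dataclass_fields__},
                    "seed": derive_seed(seed, "cleaning"),
                }
            ),
            consensus=ConsensusParams(
                **{
                    **{k: getattr(self.consensus, k) for k in self.consensus.__dataclass_fields__},
                    "seed": derive_seed(seed, "consensus"),
                }
            ),
            include_reliable_in_training=self.include_reliable_in_training,
            seed=seed,
        )


@dataclass
class PipelineResult:
    model: ConsensusModel
    selected_variables: list
    selection_rounds: list
    cleaning: CleaningResult
    training_ids: list
    counts: dict


def train_pipeline(X: pd.DataFrame, y, reliable_mask, params: PipelineParams) -> PipelineResult:
    """Run selection, cleaning and consensus training.

    Parameters
    ----------
    X:
        Cleaned descriptor DataFrame indexed by molecule id (no decoys).
    y:
        Mean logS per molecule, aligned with ``X``.
    reliable_mask:
        Boolean array marking RELIABLE molecules (replicated, moderate
        inter-source SD).
    """
    y = np.asarray(y, dtype=float)
    reliable_mask = np.asarray(reliable_mask, dtype=bool)
    ids = list(X.index)
    if not (len(ids) == y.size == reliable_mask.size):
        raise ValueError("X, y and reliable_mask must agree in length")

    selected, rounds = select_variables(X, y, params.selection)

    X_sel = X[selected]
    X_unrel = X_sel.loc[~reliable_mask]
    y_unrel = y[~reliable_mask]
    unrel_ids = list(X_unrel.index)

    cleaning = clean_dataset(
        X_unrel.to_numpy(),
        y_unrel,
        X_reliable=X_sel.loc[reliable_mask].to_numpy(),
        y_reliable=y[reliable_mask],
        params=params.cleaning,
        ids=unrel_ids,
    )

    train_ids = list(cleaning.clean_ids)
    if params.include_reliable_in_training:
        train_ids += [i for i, rel in zip(ids, reliable_mask) if rel]
    pos = {mol_id: k for k, mol_id in enumerate(ids)}
    train_idx = [pos[i] for i in train_ids]

    model = train_consensus(X_sel.iloc[train_idx], y[train_idx], params.consensus)

    return PipelineResult(
        model=model,
        selected_variables=selected,
        selection_rounds=rounds,
        cleaning=cleaning,
        training_ids=train_ids,
        counts={
            "n_molecules": len(ids),
            "n_reliable": int(reliable_mask.sum()),
            "n_unreliable": int((~reliable_mask).sum()),
            "n_clean": len(cleaning.clean_ids),
            "n_unclean": len(cleaning.unclean_ids),
            "n_training": len(train_ids),
            "n_variables_in": X.shape[1],
            "n_variables_selected": len(selected),
            "pv_threshold": cleaning.threshold,
            "cleaning_converged": cleaning.converged,
        },
    )
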