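"""Reproducible benchmark runs on the standard synthetic presets.

These functions re-run the pipeline's stages under the standard study
conditions (see :func:`rrfsol.synthetic.standard_benchmarks`) and measure
the quantities that characterize the method: informative-variable recovery
under the decoy filter, injected-outlier recall of the PV cleaning, and the
consensus pipeline's RMSE against a single forest trained on the raw,
uncleaned table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import derive_seed
from .cleaning import CleaningParams, clean_dataset
from .consensus import ConsensusParams, predict, train_consensus
from .descriptors import DECOY_SUFFIX
from .forest import RegressionForest
from .pipeline import PipelineParams, train_pipeline
from .selection import SelectionParams, select_variables
from .synthetic import generate_descriptor_dataset, standard_benchmarks

__all__ = ["SelectionRun", "PipelineRun", "run_selection_benchmark", "run_pipeline_benchmark"]


@dataclass
class SelectionRun:
    seed: int
    selected: list
    n_informative_recovered: int
    n_decoys_selected: int
    max_abs_correlation: float


@dataclass
class PipelineRun:
    seed: int
    selected: list
    n_informative_recovered: int
    outlier_recall: float
    rmse_clean_forest: float
    rmse_uncleaned_forest: float
    cleaning_converged: bool
    cleaning_iterations: int
    rmse_consensus: float
    rmse_single_forest: float
    pv_threshold: float


def _reliable_mask(data) -> np.ndarray:
    sd = data.inter_source_sd()
    n = data.measurements.groupby("molecule_id", sort=False).size().reindex(data.X.index)
    return ((n > 1) & (sd > 0) & (sd < 1)).to_numpy()


def run_selection_benchmark(seed: int) -> SelectionRun:
    """One seeded run of variable selection on the SELECTION preset."""
    spec = standard_benchmarks()["SELECTION"]
    data = generate_descriptor_dataset(spec, seed=derive_seed(seed, "selection-data"))
    params = SelectionParams(seed=derive_seed(seed, "selection-run"))
    selected, _ = select_variables(data.X, data.y_true.to_numpy(), params)
    informative = set(data.informative_columns)
    corr = 0.0
    if len(selected) > 1:
        c = np.corrcoef(data.X[selected].to_numpy(), rowvar=False)
        corr = float(np.abs(c[~np.eye(len(selected), dtype=bool)]).max())
    return SelectionRun(
        seed=seed,
        selected=selected,
        n_informative_recovered=len(informative & set(selected)),
        n_decoys_selected=sum(name.endswith(DECOY_SUFFIX) for name in selected),
        max_abs_correlation=corr,
    )


def run_pipeline_benchmark(seed: int) -> PipelineRun:
    """One seeded end-to-end run on the CLEANING preset.

    Trains the full pipeline (selection -> PV cleaning at the optimized
    threshold -> consensus) on the UNRELIABLE molecules and compares it,
    on the untouched RELIABLE set, with a single regression forest trained
    on the raw uncleaned table with every descriptor column.
    """
    spec = standard_benchmarks()["CLEANING"]
    data = generate_descriptor_dataset(spec, seed=derive_seed(seed, "cleaning-data"))
    y = data.mean_logs().to_numpy()
    reliable = _reliable_mask(data)

    params = PipelineParams(include_reliable_in_training=False).with_seed(
        derive_seed(seed, "pipeline-run")
    )
    result = train_pipeline(data.X, y, reliable, params)

    ids = np.asarray(data.X.index)
    outliers = data.outlier.to_numpy()
    unclean = np.isin(ids, result.cleaning.unclean_ids)
    recall = float((unclean & outliers).sum() / outliers.sum())

    X_rel = data.X.loc[reliable]
    y_rel = y[reliable]

    # cleaning effect in isolation: same forest settings, CLEAN vs all-unreliable
    sel = result.selected_variables
    cp = params.cleaning
    clean_mask = np.isin(ids, result.cleaning.clean_ids)
    forest_clean = RegressionForest(
        n_trees=cp.n_trees, max_features=cp.max_features, seed=derive_seed(seed, "f-clean")
    ).fit(data.X.loc[clean_mask, sel].to_numpy(), y[clean_mask])
    forest_raw_sel = RegressionForest(
        n_trees=cp.n_trees, max_features=cp.max_features, seed=derive_seed(seed, "f-clean")
    ).fit(data.X.loc[~reliable, sel].to_numpy(), y[~reliable])
    rmse_clean = float(np.sqrt(np.mean((forest_clean.predict(X_rel[sel]) - y_rel) ** 2)))
    rmse_uncleaned = float(np.sqrt(np.mean((forest_raw_sel.predict(X_rel[sel]) - y_rel) ** 2)))

    # full pipeline vs a single forest on the raw table (all descriptors)
    consensus_pred = predict(result.model, X_rel[sel]).y_pred
    rmse_consensus = float(np.sqrt(np.mean((consensus_pred - y_rel) ** 2)))
    single = RegressionForest(
        n_trees=500, max_features=1 / 3, seed=derive_seed(seed, "single-forest")
    ).fit(data.X.loc[~reliable].to_numpy(), y[~reliable])
    rmse_single = float(np.sqrt(np.mean((single.predict(data.X.loc[reliable]) - y_rel) ** 2)))

    return PipelineRun(
        seed=seed,
        selected=sel,
        n_informative_recovered=len(set(sel) & set(data.informative_columns)),
        outlier_recall=recall,
        rmse_clean_forest=rmse_clean,
        rmse_uncleaned_forest=rmse_uncleaned,
        cleaning_converged=result.cleaning.converged,
        cleaning_iterations=result.cleaning.n_iterations,
        rmse_consensus=rmse_consensus,
        rmse_single_forest=rmse_single,
        pv_threshold=result.cleaning.threshold,
    )
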