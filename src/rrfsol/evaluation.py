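"""Regression metrics, repeated-run summaries and paired model comparison.

Six metrics characterize a set of solubility predictions:

- ``r2_validation`` = 1 - SSres/SStot (can be negative for a model worse
  than the mean predictor);
- ``r2_pearson`` = squared Pearson correlation (invariant to affine
  transforms of the predictions);
- ``rmse`` and ``mae`` in log units;
- ``bias`` = mean(predicted - observed), so negative bias reads as
  under-prediction;
- ``pct_within_half_log`` = percent of molecules with absolute error
  strictly below 0.5 log units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EvaluationReport",
    "RepeatedReport",
    "compute_metrics",
    "repeat_evaluation",
    "paired_model_comparison",
]

METRICS = ("r2_validation", "r2_pearson", "rmse", "mae", "bias", "pct_within_half_log")


@dataclass(frozen=True)
class EvaluationReport:
    r2_validation: float
    r2_pearson: float
    rmse: float
    mae: float
    bias: float
    pct_within_half_log: float
    n: int

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRICS} | {"n": self.n}


@dataclass
class RepeatedReport:
    mean: dict
    std: dict
    k: int
    seeds: list
    runs: pd.DataFrame     # long format: seed, metric, value


def compute_metrics(observed, predicted) -> EvaluationReport:
    """All six metrics for paired observed/predicted vectors."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be 1-d vectors of equal length")
    if observed.size < 2:
        raise ValueError("need at least 2 paired values")
    if not (np.isfinite(observed).all() and np.isfinite(predicted).all()):
        raise ValueError("inputs must be finite")

    residuals = predicted - observed
    rmse = float(np.sqrt(np.mean(residuals**2)))
    mae = float(np.mean(np.abs(residuals)))
    bias = float(np.mean(residuals))
    pct = float(100.0 * np.mean(np.abs(residuals) < 0.5))

    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant observed vector: r2 metrics are undefined")
        r2_val = float("nan")
        r2_pearson = float("nan")
    else:
        r2_val = 1.0 - float(np.sum(residuals**2)) / ss_tot
        if np.std(predicted) == 0.0:
            warnings.warn("constant predictions: Pearson r2 undefined")
            r2_pearson = float("nan")
        else:
            r2_pearson = float(np.corrcoef(observed, predicted)[0, 1] ** 2)

    return EvaluationReport(
        r2_validation=r2_val,
        r2_pearson=r2_pearson,
        rmse=rmse,
        mae=mae,
        bias=bias,
        pct_within_half_log=pct,
        n=int(observed.size),
    )


def repeat_evaluation(runner, data, k: int, base_seed: int) -> RepeatedReport:
    """Run a train/predict cycle ``k`` times and aggregate metrics.

    ``runner(data, seed)`` must return ``(observed, predicted)``. Seeds are
    derived deterministically from ``base_seed``; any failing run aborts
    with the failing seed identified.
    """
    from ._seeds import derive_seed

    if k < 2:
        raise ValueError("k must be >= 2 to report a standard deviation")
    rows, seeds = [], []
    for i in range(k):
        seed = derive_seed(base_seed, f"repeat-{i}")
        seeds.append(seed)
        try:
            observed, predicted = runner(data, seed)
        except Exception as exc:
            raise RuntimeError(f"repeat run with seed {seed} failed: {exc}") from exc
        report = compute_metrics(observed, predicted)
        for metric, value in report.as_dict().items():
            if metric != "n":
                rows.append((seed, metric, value))
    runs = pd.DataFrame(rows, columns=["seed", "metric", "value"])
    grouped = runs.groupby("metric")["value"]
    return RepeatedReport(
        mean=grouped.mean().to_dict(),
        std=grouped.std(ddof=1).to_dict(),
        k=k,
        seeds=seeds,
        runs=runs,
    )


def paired_model_comparison(errors_a, errors_b, on: str = "squared", alternative: str = "two-sided"):
    """Paired t-test between the per-molecule errors of two models.

    ``errors_a``/``errors_b`` are per-molecule prediction errors (signed or
    absolute), paired by molecule. By default the test is performed on the
    squared errors (comparing models on the RMSE scale); ``on="absolute"``
    uses absolute errors instead. All-zero pairwise differences return
    ``t = 0, p = 1`` by convention.

    Returns ``(t, p, n)``.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("error vectors must be 1-d and equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if on == "squared":
        a, b = a**2, b**2
    elif on == "absolute":
        a, b = np.abs(a), np.abs(b)
    elif on != "raw":
        raise ValueError("on must be 'squared', 'absolute' or 'raw'")
    if np.all(a - b == 0):
        return 0.0, 1.0, int(a.size)
    t, p = stats.ttest_rel(a, b, alternative=alternative)
    return float(t), float(p), int(a.size)
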