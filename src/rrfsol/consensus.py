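"""Classification-gated consensus solubility regressor.

Four sub-models share one selected-variable list: a gradient-boosting
classifier separating soluble from insoluble molecules at logS = -2
(boundary on the soluble side), two regression forests trained on the two
class subsets, and one regression forest trained on all molecules. Three
combination modes are offered; all are convex combinations of the
sub-model predictions, so the consensus always lies between the smallest
and largest sub-prediction:

``mean3``
    (yhat_high + yhat_low + yhat_all) / 3 — the classifier is unused.
``hard_route`` (default)
    (yhat_routed + yhat_all) / 2, routing through the class-specific forest
    chosen by the classifier's hard label.
``soft_route``
    (p * yhat_high + (1 - p) * yhat_low + yhat_all) / 2 with
    p = P(soluble).

The default is ``hard_route`` so the classifier is functionally part of the
consensus rather than dead weight.
"""

from __future__ import annotations

import json
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier

from . import __version__ as _pkg_version
from ._seeds import derive_seed
from .forest import RegressionForest

__all__ = [
    "ConsensusParams",
    "ConsensusModel",
    "PredictionResult",
    "DegenerateClassError",
    "ModelArchiveError",
    "train_consensus",
    "predict",
    "save_model",
    "load_model",
    "MODES",
]

MODES = ("mean3", "hard_route", "soft_route")


class DegenerateClassError(ValueError):
    pass


class ModelArchiveError(ValueError):
    pass


@dataclass(frozen=True)
class ConsensusParams:
    class_cutoff: float = -2.0
    mode: str = "hard_route"
    rf_n_trees: int = 300
    # the consensus operates on the post-selection space (a handful of
    # columns); fractional feature sampling there leaves 1-2 candidates per
    # split and cripples the trees, so sub-forests use bagging-only
    # randomization like the cleaning forests
    rf_max_features: float = 1.0
    rf_min_samples_leaf: int = 1
    gbm_n_estimators: int = 100
    gbm_learning_rate: float = 0.1
    gbm_max_depth: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not np.isfinite(self.class_cutoff):
            raise ValueError("class_cutoff must be finite")


@dataclass
class ConsensusModel:
    selected_variables: list
    class_cutoff: float
    classifier: GradientBoostingClassifier
    regressor_high: RegressionForest    # trained on logS >= cutoff
    regressor_low: RegressionForest     # trained on logS < cutoff
    regressor_all: RegressionForest
    combination_mode: str
    training_metadata: dict = field(default_factory=dict)


@dataclass
class PredictionResult:
    y_pred: np.ndarray
    p_soluble: np.ndarray
    pred_high: np.ndarray
    pred_low: np.ndarray
    pred_all: np.ndarray
    mode: str

    def frame(self, ids=None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "logS_pred": self.y_pred,
                "p_soluble": self.p_soluble,
                "pred_high": self.pred_high,
                "pred_low": self.pred_low,
                "pred_all": self.pred_all,
                "mode": self.mode,
            }
        )
        if ids is not None:
            frame.insert(0, "id", list(ids))
        return frame


def _check_matrix(X, variables) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [v for v in variables if v not in X.columns]
        if missing:
            raise ValueError(f"input is missing model variables: {missing}")
        return X[variables].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != len(variables):
        raise ValueError(
            f"input has {X.shape[1]} columns; model expects {len(variables)}"
        )
    return X


def train_consensus(X, y, params: ConsensusParams | None = None) -> ConsensusModel:
    """Train the classifier and the three regression forests.

    ``X`` is a DataFrame restricted to the selected variables (or a plain
    matrix). Class labels derive from the response: soluble iff
    ``y >= class_cutoff``. Each sub-model gets an independently derived
    seed; retraining with identical seeds and data is bit-reproducible.
    """
    params = params or ConsensusParams()
    variables = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"v{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xm = _check_matrix(X, variables)
    y = np.asarray(y, dtype=float)
    soluble = y >= params.class_cutoff
    if soluble.all() or (~soluble).all():
        raise DegenerateClassError(
            f"degenerate class split at cutoff {params.class_cutoff}: one side "
            "is empty; change the cutoff via configuration"
        )
    classifier = GradientBoostingClassifier(
        n_estimators=params.gbm_n_estimators,
        learning_rate=params.gbm_learning_rate,
        max_depth=params.gbm_max_depth,
        random_state=derive_seed(params.seed, "gbm"),
    ).fit(Xm, soluble.astype(int))

    def _rf(label, mask):
        return RegressionForest(
            n_trees=params.rf_n_trees,
            max_features=params.rf_max_features,
            min_samples_leaf=params.rf_min_samples_leaf,
            seed=derive_seed(params.seed, label),
        ).fit(Xm[mask], y[mask], feature_names=variables)

    model = ConsensusModel(
        selected_variables=variables,
        class_cutoff=params.class_cutoff,
        classifier=classifier,
        regressor_high=_rf("rf-high", soluble),
        regressor_low=_rf("rf-low", ~soluble),
        regressor_all=_rf("rf-all", np.ones_like(soluble, dtype=bool)),
        combination_mode=params.mode,
        training_metadata={
            "seed": params.seed,
            "params": {k: getattr(params, k) for k in params.__dataclass_fields__},
            "n_train": int(y.size),
            "n_soluble": int(soluble.sum()),
            "n_insoluble": int((~soluble).sum()),
        },
    )
    return model


def predict(model: ConsensusModel, X, mode: str | None = None) -> PredictionResult:
    """Consensus prediction with full per-submodel audit output."""
    mode = mode or model.combination_mode
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    Xm = _check_matrix(X, model.selected_variables)
    pred_high = model.regressor_high.predict(Xm)
    pred_low = model.regressor_low.predict(Xm)
    pred_all = model.regressor_all.predict(Xm)
    p_soluble = model.classifier.predict_proba(Xm)[:, list(model.classifier.classes_).index(1)]
    if mode == "mean3":
        y_pred = (pred_high + pred_low + pred_all) / 3.0
    elif mode == "hard_route":
        routed = np.where(p_soluble >= 0.5, pred_high, pred_low)
        y_pred = (routed + pred_all) / 2.0
    else:  # soft_route
        y_pred = (p_soluble * pred_high + (1.0 - p_soluble) * pred_low + pred_all) / 2.0
    return PredictionResult(
        y_pred=y_pred,
        p_soluble=p_soluble,
        pred_high=pred_high,
        pred_low=pred_low,
        pred_all=pred_all,
        mode=mode,
    )


# -- persistence --------------------------------------------------------

_ARCHIVE_FORMAT = 1


def save_model(model: ConsensusModel, path) -> None:
    """Persist the model as a directory archive.

    The archive holds the four sub-models, ``model.json`` (variables,
    cutoff, mode, metadata, library versions) and ``probe.csv`` — a small
    input matrix with the model's predictions, used to verify round-trips
    bit-exactly on load.
    """
    import sklearn

    path = Path(path)
    if path.exists():
        shutil.rmtree(path)
    path.mkdir(parents=True)
    joblib.dump(model.classifier, path / "classifier.joblib")
    joblib.dump(model.regressor_high, path / "regressor_high.joblib")
    joblib.dump(model.regressor_low, path / "regressor_low.joblib")
    joblib.dump(model.regressor_all, path / "regressor_all.joblib")

    rng = np.random.default_rng(0)
    probe_X = rng.standard_normal((5, len(model.selected_variables)))
    probe_pred = predict(model, probe_X).y_pred
    probe = pd.DataFrame(probe_X, columns=model.selected_variables)
    probe["expected_prediction"] = probe_pred
    # %.17g guarantees an exact float64 round trip through the CSV
    probe.to_csv(path / "probe.csv", index=False, float_format="%.17g")

    (path / "model.json").write_text(
        json.dumps(
            {
                "archive_format": _ARCHIVE_FORMAT,
                "package_version": _pkg_version,
                "sklearn_version": sklearn.__version__,
                "selected_variables": model.selected_variables,
                "class_cutoff": model.class_cutoff,
                "combination_mode": model.combination_mode,
                "training_metadata": model.training_metadata,
            },
            indent=2,
            default=str,
        )
    )


def load_model(path) -> ConsensusModel:
    """Load an archive, verifying the probe predictions bit-exactly."""
    path = Path(path)
    meta_path = path / "model.json"
    if not meta_path.exists():
        raise ModelArchiveError(f"{path} is not a model archive (model.json missing)")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelArchiveError(f"corrupted archive metadata: {exc}") from exc
    if meta.get("archive_format") != _ARCHIVE_FORMAT:
        raise ModelArchiveError(
            f"archive format {meta.get('archive_format')} not supported by "
            f"this library (expects {_ARCHIVE_FORMAT}, package {_pkg_version})"
        )
    try:
        model = ConsensusModel(
            selected_variables=list(meta["selected_variables"]),
            class_cutoff=float(meta["class_cutoff"]),
            classifier=joblib.load(path / "classifier.joblib"),
            regressor_high=joblib.load(path / "regressor_high.joblib"),
            regressor_low=joblib.load(path / "regressor_low.joblib"),
            regressor_all=joblib.load(path / "regressor_all.joblib"),
            combination_mode=meta["combination_mode"],
            training_metadata=meta.get("training_metadata", {}),
        )
    except (OSError, KeyError, EOFError, ValueError) as exc:
        raise ModelArchiveError(f"corrupted model archive at {path}: {exc}") from exc

    probe_path = path / "probe.csv"
    if not probe_path.exists():
        warnings.warn("model archive has no probe matrix; round-trip check skipped")
        return model
    # round_trip parsing: the default CSV float parser can be 1 ulp off,
    # which would fail the bit-exact probe comparison
    probe = pd.read_csv(probe_path, float_precision="round_trip")
    expected = probe.pop("expected_prediction").to_numpy()
    got = predict(model, probe).y_pred
    if not np.array_equal(got, expected):
        raise ModelArchiveError(
            "probe predictions changed after loading; the archive does not "
            "reproduce its own model"
        )
    return model
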