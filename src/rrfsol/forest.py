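"""Bagged regression forest with per-tree access.

The modelling procedure needs three things a stock random-forest wrapper does
not expose through public API: the bootstrap (in-bag) membership of every
tree, the individual per-tree predictions behind each ensemble prediction
(for the prediction-variance score), and the number of internal split nodes
that use each feature (the occurrence importance used by variable selection).
``RegressionForest`` therefore implements classic bootstrap aggregation over
scikit-learn ``DecisionTreeRegressor`` base learners and keeps that
bookkeeping explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeRegressor

__all__ = ["RegressionForest"]


def _as_matrix(X) -> np.ndarray:
    arr = np.asarray(X, dtype=np.float32)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    return arr


@dataclass
class RegressionForest:
    """Bagged ensemble of CART regression trees.

    Parameters
    ----------
    n_trees:
        Number of bootstrap trees.
    max_features:
        Fraction (or int count) of features examined per split. ``1/3`` is
        the conventional regression-forest choice; ``1.0`` yields
        bootstrap-only randomization.
    min_samples_leaf:
        Minimum leaf size of each tree.
    seed:
        Seed for the bootstrap draws and the per-tree split tie-breaking.
    """

    n_trees: int = 500
    max_features: float | int = 1 / 3
    min_samples_leaf: int = 1
    seed: int = 0

    trees_: list = field(default_factory=list, repr=False)
    inbag_: np.ndarray | None = field(default=None, repr=False)
    n_features_: int | None = None
    feature_names_: list | None = None

    def fit(self, X, y, feature_names=None) -> "RegressionForest":
        X = _as_matrix(X)
        y = np.asarray(y, dtype=np.float64)
        n, p = X.shape
        if n != y.shape[0]:
            raise ValueError(f"X has {n} rows but y has {y.shape[0]}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        rng = np.random.default_rng(self.seed)
        self.trees_ = []
        self.inbag_ = np.zeros((self.n_trees, n), dtype=bool)
        mf = self.max_features
        if isinstance(mf, float) and mf >= 1.0:
            mf = None  # sklearn convention: all features
        for t in range(self.n_trees):
            idx = rng.integers(0, n, n)
            self.inbag_[t, np.unique(idx)] = True
            tree = DecisionTreeRegressor(
                max_features=mf,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
        self.n_features_ = p
        self.feature_names_ = list(feature_names) if feature_names is not None else None
        return self

    @classmethod
    def from_estimators(cls, trees, n_features: int) -> "RegressionForest":
        """Wrap already-fitted regression trees (no in-bag bookkeeping)."""
        forest = cls(n_trees=len(trees))
        forest.trees_ = list(trees)
        forest.n_features_ = n_features
        forest.inbag_ = None
        return forest

    # -- prediction ------------------------------------------------------

    def _check_fitted(self):
        if not self.trees_:
            raise ValueError("forest is not fitted")

    def tree_predictions(self, X) -> np.ndarray:
        """Per-tree predictions, shape ``(n_trees, n_rows)``."""
        self._check_fitted()
        X = _as_matrix(X)
        return np.stack([t.predict(X) for t in self.trees_])

    def predict(self, X) -> np.ndarray:
        return self.tree_predictions(X).mean(axis=0)

    def prediction_variance(self, X) -> np.ndarray:
        """Variance (ddof=1) of the per-tree predictions at each row."""
        if len(self.trees_) < 2:
            raise ValueError(
                "prediction variance is undefined for a forest with fewer "
                "than 2 trees (n-1 denominator)"
            )
        return self.tree_predictions(X).var(axis=0, ddof=1)

    # -- occurrence importance ------------------------------------------

    def split_counts(self) -> np.ndarray:
        """Internal split nodes per feature, summed over all trees."""
        self._check_fitted()
        counts = np.zeros(self.n_features_, dtype=np.int64)
        for tree in self.trees_:
            feats = tree.tree_.feature
            feats = feats[feats >= 0]  # internal nodes only
            np.add.at(counts, feats, 1)
        return counts

    @property
    def n_internal_nodes(self) -> int:
        self._check_fitted()
        return int(sum((t.tree_.feature >= 0).sum() for t in self.trees_))
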