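"""Quantile regression forest for dose reconstruction.

Bagged scikit-learn decision trees whose leaves retain the bootstrap
training targets (Meinshausen-style quantile forest).  The mean prediction
is the average over trees of leaf means — exactly what a plain random
forest returns — while conditional quantiles come from the pooled,
bag-weighted empirical distribution of leaf targets.  Because every
prediction is a weighted average/quantile of training targets, the model
cannot extrapolate beyond the observed dose range.

Two split rules are supported:

* ``"variance"`` — classic CART best-split search (random forest);
* ``"random_threshold"`` — extremely-randomized thresholds, best of
  ``mtry`` candidate features by variance reduction (the "extratrees"
  rule of the ranger library, the configuration that performed best in
  the emulated study: 500 trees, mtry 6, min_node_size 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor, ExtraTreeRegressor

__all__ = ["QuantileForest", "train_quantile_forest", "predict_mean",
           "predict_quantiles", "DEFAULT_TAUS"]

DEFAULT_TAUS = (0.05, 0.1, 0.25, 0.5, 0.75, 0.9, 0.95)


@dataclass
class QuantileForest:
    """Fitted bagged-tree ensemble with leaf-target bookkeeping."""

    n_trees: int = 500
    mtry: int | None = 6
    min_node_size: int = 1
    split_rule: str = "random_threshold"
    bootstrap: bool = True
    seed: int = 0

    trees: list = field(default_factory=list, repr=False)
    bag_indices: list = field(default_factory=list, repr=False)
    oob_indices: list = field(default_factory=list, repr=False)
    feature_names: list | None = None
    y_train: np.ndarray | None = None
    y_min: float = np.nan
    y_max: float = np.nan
    # per-tree CSR-style leaf tables: leaf id -> bag training-row ids
    _leaf_members: list = field(default_factory=list, repr=False)

    def fit(self, X, y) -> "QuantileForest":
        X, self.feature_names = _as_array(X, None)
        y = np.asarray(y, dtype=float)
        if len(X) < 2:
            raise ValueError("need at least 2 training rows")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        n, p = X.shape
        mtry = self.mtry
        if mtry is not None and mtry > p:
            warnings.warn(f"mtry={mtry} exceeds feature count {p}; clamping")
            mtry = p
        max_features = mtry if mtry is not None else p
        if self.split_rule == "random_threshold":
            base_cls = ExtraTreeRegressor
        elif self.split_rule == "variance":
            base_cls = DecisionTreeRegressor
        else:
            raise ValueError(f"unknown split_rule {self.split_rule!r}")

        rng = np.random.default_rng(self.seed)
        self.trees, self.bag_indices, self.oob_indices = [], [], []
        self._leaf_members = []
        all_rows = np.arange(n)
        for _ in range(self.n_trees):
            bag = rng.integers(0, n, size=n) if self.bootstrap else all_rows
            tree = base_cls(
                max_features=max_features,
                min_samples_leaf=self.min_node_size,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[bag], y[bag])
            leaves = tree.apply(X[bag])
            order = np.argsort(leaves, kind="stable")
            uniq, starts = np.unique(leaves[order], return_index=True)
            members = bag[order]
            bounds = np.append(starts, len(members))
            leaf_means = np.add.reduceat(y[members], starts) / np.diff(bounds)
            self.trees.append(tree)
            self.bag_indices.append(bag)
            self.oob_indices.append(np.setdiff1d(all_rows, bag, assume_unique=False))
            self._leaf_members.append((uniq, bounds, members, leaf_means))
        self.y_train = y
        self.y_min, self.y_max = float(y.min()), float(y.max())
        return self

    # -- prediction ------------------------------------------------------

    def _check_schema(self, X) -> np.ndarray:
        arr, names = _as_array(X, self.feature_names)
        return arr

    def _weights(self, X: np.ndarray) -> np.ndarray:
        """Meinshausen weights: w[q, j] = average over trees of
        (bag multiplicity of train row j in the leaf of query q) / leaf size."""
        n_train = len(self.y_train)
        nq = len(X)
        W = np.zeros((nq, n_train))
        for tree, (uniq, bounds, members, _) in zip(self.trees, self._leaf_members):
            pos = np.searchsorted(uniq, tree.apply(X))
            sizes = bounds[pos + 1] - bounds[pos]
            qi_rep = np.repeat(np.arange(nq), sizes)
            # training rows of each query's leaf, concatenated query by query
            offsets = np.repeat(bounds[pos] - np.concatenate(([0], np.cumsum(sizes)[:-1])),
                                sizes)
            row_cat = members[np.arange(sizes.sum()) + offsets]
            np.add.at(W, (qi_rep, row_cat), 1.0 / np.repeat(sizes, sizes))
        return W / len(self.trees)

    def predict(self, X) -> np.ndarray:
        """Mean dose prediction: average over trees of leaf means (Gy)."""
        X = self._check_schema(X)
        preds = np.zeros(len(X))
        for tree, (uniq, _, _, leaf_means) in zip(self.trees, self._leaf_members):
            preds += leaf_means[np.searchsorted(uniq, tree.apply(X))]
        return preds / len(self.trees)

    def predict_quantiles(self, X, taus=DEFAULT_TAUS) -> pd.DataFrame:
        """Conditional dose quantiles from pooled bag-weighted leaf targets.

        Type-1 weighted empirical quantiles of the training targets, so the
        output is non-decreasing in tau and bounded by the training range.
        """
        taus = np.atleast_1d(np.asarray(taus, dtype=float))
        if np.any(taus <= 0) or np.any(taus >= 1):
            raise ValueError("taus must lie strictly inside (0, 1)")
        X = self._check_schema(X)
        W = self._weights(X)
        order = np.argsort(self.y_train, kind="stable")
        y_sorted = self.y_train[order]
        cum = np.cumsum(W[:, order], axis=1)
        cum /= cum[:, -1:]
        out = np.empty((len(X), len(taus)))
        for ti, tau in enumerate(taus):
            idx = np.argmax(cum >= tau - 1e-12, axis=1)
            out[:, ti] = y_sorted[idx]
        return pd.DataFrame(out, columns=[f"q{int(round(t * 100))}" for t in taus])

    # -- importance ------------------------------------------------------

    def permutation_importance(self, X, y, rng: np.random.Generator) -> np.ndarray:
        """Out-of-bag permutation importance per feature.

        For each tree: MSE of OOB predictions after permuting one feature
        minus baseline OOB MSE, averaged over trees.  Matches the
        "permutation" importance of ranger in spirit (per-tree OOB rows).
        """
        X, _ = _as_array(X, self.feature_names)
        y = np.asarray(y, dtype=float)
        p = X.shape[1]
        imp = np.zeros(p)
        n_used = 0
        for tree, oob in zip(self.trees, self.oob_indices):
            if len(oob) < 2:
                continue
            Xo = X[oob]
            base = np.mean((tree.predict(Xo) - y[oob]) ** 2)
            perm = rng.permutation(len(oob))
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = Xo[perm, j]
                imp[j] += np.mean((tree.predict(Xp) - y[oob]) ** 2) - base
            n_used += 1
        return imp / max(n_used, 1)


def _as_array(X, expected_names):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        if expected_names is not None and names != list(expected_names):
            raise ValueError(
                f"feature schema mismatch: expected {list(expected_names)}, got {names}")
        return X.to_numpy(dtype=float), names
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
    if expected_names is not None and arr.shape[1] != len(expected_names):
        raise ValueError("feature schema mismatch: wrong column count")
    return arr, expected_names


# -- functional surface ---------------------------------------------------

def train_quantile_forest(matrix, spec=None, **kwargs) -> QuantileForest:
    """Fit a quantile forest on a ModelMatrix (or (X, y) pair).

    ``spec`` may be a ModelSpec (family ``quantile_forest``) or a dict of
    QuantileForest fields; keyword arguments override.
    """
    params = {}
    if spec is not None:
        params.update(getattr(spec, "hyperparameters", None) or spec)
        if getattr(spec, "seed", None) is not None:
            params.setdefault("seed", spec.seed)
    params.update(kwargs)
    forest = QuantileForest(**params)
    if hasattr(matrix, "X"):
        return forest.fit(matrix.X, matrix.y)
    X, y = matrix
    return forest.fit(X, y)


def predict_mean(model: QuantileForest, rows) -> np.ndarray:
    return model.predict(rows)


def predict_quantiles(model: QuantileForest, rows, taus=DEFAULT_TAUS) -> pd.DataFrame:
    return model.predict_quantiles(rows, taus)
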