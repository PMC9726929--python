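"""Model zoo and cross-validation harness for dose reconstruction.

The quantile forest (see :mod:`cytodose.forest`) is the principal model;
the remaining families are baseline learners behind a single fit/predict
adapter so they can be compared under the same repeated k-fold protocol:

* ``linear`` / ``elastic_net`` / ``support_vector`` — scikit-learn
  LinearRegression, ElasticNetCV, SVR;
* ``boosted_trees`` — LightGBM gradient boosting;
* ``linear_tree`` — a small model tree: scikit-learn decision-tree
  partition with ridge models at the leaves.

Metrics follow the study's conventions: MAE, RMSE, and R^2 defined as the
*squared Pearson correlation* between actual and predicted doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV, LinearRegression, Ridge
from sklearn.model_selection import RepeatedKFold
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .forest import QuantileForest

__all__ = ["ModelSpec", "CVReport", "make_model", "repeated_cv", "grid_search",
           "MODEL_FAMILIES"]

MODEL_FAMILIES = ("quantile_forest", "boosted_trees", "linear", "elastic_net",
                  "support_vector", "linear_tree")


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")

    def replace(self, **hp) -> "ModelSpec":
        merged = {**self.hyperparameters, **hp}
        return ModelSpec(self.family, merged, self.seed)


class _SkAdapter:
    """Uniform fit/predict wrapper around an sklearn-style estimator."""

    def __init__(self, est):
        self.est = est

    def fit(self, X, y):
        self.est.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
        return self

    def predict(self, X):
        return self.est.predict(np.asarray(X, dtype=float))


class _LinearTree:
    """Model tree: shallow CART partition with ridge fits at the leaves."""

    def __init__(self, max_depth=3, min_samples_leaf=30, ridge_alpha=1.0, seed=0):
        self.tree = DecisionTreeRegressor(max_depth=max_depth,
                                          min_samples_leaf=min_samples_leaf,
                                          random_state=seed)
        self.ridge_alpha = ridge_alpha
        self.leaf_models: dict = {}

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.tree.fit(X, y)
        leaves = self.tree.apply(X)
        for leaf in np.unique(leaves):
            m = leaves == leaf
            self.leaf_models[leaf] = Ridge(alpha=self.ridge_alpha).fit(X[m], y[m])
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        leaves = self.tree.apply(X)
        out = np.empty(len(X))
        for leaf in np.unique(leaves):
            m = leaves == leaf
            out[m] = self.leaf_models[leaf].predict(X[m])
        return out


def make_model(spec: ModelSpec):
    """Instantiate an unfitted model from its spec."""
    hp = dict(spec.hyperparameters)
    if spec.family == "quantile_forest":
        hp.setdefault("seed", spec.seed)
        return QuantileForest(**hp)
    if spec.family == "linear":
        return _SkAdapter(LinearRegression(**hp))
    if spec.family == "elastic_net":
        hp.setdefault("cv", 5)
        return _SkAdapter(ElasticNetCV(random_state=spec.seed, **hp))
    if spec.family == "support_vector":
        return _SkAdapter(SVR(**hp))
    if spec.family == "linear_tree":
        hp.setdefault("seed", spec.seed)
        return _LinearTree(**hp)
    if spec.family == "boosted_trees":
        import lightgbm as lgb
        hp.setdefault("n_estimators", 200)
        hp.setdefault("verbose", -1)
        return _SkAdapter(lgb.LGBMRegressor(random_state=spec.seed,
                                            deterministic=True, n_jobs=1, **hp))
    raise ValueError(spec.family)  # pragma: no cover - guarded by ModelSpec


def _metrics(actual: np.ndarray, pred: np.ndarray) -> dict:
    err = actual - pred
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.std(actual) > 0 and np.std(pred) > 0:
        r2 = float(np.corrcoef(actual, pred)[0, 1] ** 2)
    else:
        r2 = np.nan
    return {"MAE": mae, "RMSE": rmse, "R2": r2}


@dataclass
class CVReport:
    model: str
    k: int
    repeats: int
    folds: pd.DataFrame               # one row per fold x repeat

    @property
    def mean(self) -> pd.Series:
        return self.folds[["MAE", "RMSE", "R2"]].mean()

    @property
    def sd(self) -> pd.Series:
        return self.folds[["MAE", "RMSE", "R2"]].std()


def repeated_cv(spec: ModelSpec, matrix, k: int = 5, repeats: int = 30,
                seed: int = 0) -> CVReport:
    """Repeated k-fold cross-validation; folds reshuffled every repeat."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = matrix.X.to_numpy(dtype=float) if hasattr(matrix, "X") else np.asarray(matrix[0], float)
    y = matrix.y if hasattr(matrix, "y") else np.asarray(matrix[1], float)
    if len(y) < k:
        raise ValueError("n must be >= k")
    splitter = RepeatedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    rows = []
    for fold_id, (tr, te) in enumerate(splitter.split(X)):
        model = make_model(ModelSpec(spec.family, spec.hyperparameters,
                                     seed=spec.seed + fold_id))
        model.fit(X[tr], y[tr])
        m = _metrics(y[te], model.predict(X[te]))
        m.update({"repeat": fold_id // k, "fold": fold_id % k})
        rows.append(m)
    return CVReport(model=spec.family, k=k, repeats=repeats,
                    folds=pd.DataFrame(rows))


def _model_size(hp: dict) -> tuple:
    # tie-break ordering: fewer trees, then shallower, then name order
    return (hp.get("n_trees", hp.get("n_estimators", 0)),
            hp.get("max_depth", hp.get("min_node_size", 0)))


def grid_search(spec_template: ModelSpec, grid: dict, train_matrix,
                eval_matrix) -> tuple[ModelSpec, pd.DataFrame]:
    """Exhaustive grid search; best spec by RMSE on the eval part.

    ``grid`` maps hyperparameter name -> list of values.  Ties are broken
    toward the smaller model (fewer trees, then shallower).
    Returns (best spec, table of all evaluated settings).
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    names = sorted(grid)
    combos = [{}]
    for name in names:
        combos = [{**c, name: v} for c in combos for v in grid[name]]
    Xtr = train_matrix.X.to_numpy(dtype=float)
    Xev = eval_matrix.X.to_numpy(dtype=float)
    results = []
    for hp in combos:
        spec = spec_template.replace(**hp)
        model = make_model(spec).fit(Xtr, train_matrix.y)
        m = _metrics(eval_matrix.y, model.predict(Xev))
        results.append({**hp, **m})
    table = pd.DataFrame(results)
    order = sorted(range(len(combos)),
                   key=lambda i: (results[i]["RMSE"], _model_size(combos[i])))
    best = spec_template.replace(**combos[order[0]])
    return best, table
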