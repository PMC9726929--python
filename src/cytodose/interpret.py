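"""Exact Shapley attribution and partial-dependence curves.

Shapley values are computed by full subset enumeration with an
*interventional* value function: v(S) is the model prediction averaged
over a background sample, with features in S taken from the explained row
and the rest from the background row.  For feature i,

    SHAP_i = sum over S subset of F\\{i} of
             |S|! (|F|-|S|-1)! / |F|!  *  (v(S u {i}) - v(S)).

This is exact (no sampling), satisfies local accuracy (base value plus the
SHAP values reproduces the prediction to machine precision), and is
feasible because the dose models here use at most ~10 features.  One-hot
blocks can be declared as *groups* so a categorical variable enters or
leaves a coalition as a unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

__all__ = ["ShapMatrix", "PDResult", "exact_shap", "mean_abs_shap",
           "ice_curves", "pd_surface_2d", "onehot_groups"]

MAX_EXACT_FEATURES = 10


@dataclass
class ShapMatrix:
    values: pd.DataFrame          # rows = explained samples, columns = features/groups
    base_value: float             # mean background prediction (Gy)
    predictions: np.ndarray       # model predictions for the explained rows

    def check_local_accuracy(self, atol: float = 1e-9) -> bool:
        recon = self.base_value + self.values.to_numpy().sum(axis=1)
        return bool(np.allclose(recon, self.predictions, atol=atol))


@dataclass
class PDResult:
    feature: object               # name or (name, name)
    grid: object                  # 1-D array or (grid_a, grid_b)
    ice: np.ndarray               # (n_rows, len(grid)) individual curves (Gy)
    pd: np.ndarray                # mean curve / surface (Gy)


def onehot_groups(feature_names) -> dict:
    """Group one-hot columns (prefix_<level>) of a categorical into one unit."""
    groups: dict = {}
    for name in feature_names:
        if "_" in name and name.rsplit("_", 1)[1].isdigit():
            prefix = name.rsplit("_", 1)[0]
            groups.setdefault(prefix, []).append(name)
        else:
            groups[name] = [name]
    return groups


def exact_shap(model, explain_rows: pd.DataFrame, background_rows: pd.DataFrame,
               feature_groups: dict | None = None) -> ShapMatrix:
    """Exact interventional Shapley values for every explained row.

    ``feature_groups`` maps group name -> list of columns toggled together
    (default: each column is its own group).  The number of groups must
    not exceed 10; beyond that, enumeration of 2^|F| coalitions is
    impractical and a sampling explainer should be used instead.
    """
    if len(background_rows) == 0:
        raise ValueError("background must be non-empty")
    cols = list(explain_rows.columns)
    if feature_groups is None:
        feature_groups = {c: [c] for c in cols}
    group_names = list(feature_groups)
    nf = len(group_names)
    if nf > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{nf} features/groups exceeds the exact-enumeration limit of "
            f"{MAX_EXACT_FEATURES}; use a sampling-based explainer instead")
    col_idx = {c: i for i, c in enumerate(cols)}
    group_cols = [np.array([col_idx[c] for c in feature_groups[g]])
                  for g in group_names]

    E = explain_rows.to_numpy(dtype=float)
    B = background_rows.to_numpy(dtype=float)
    ne, nb = len(E), len(B)

    # v[mask][row] = mean over background of f(x with groups-in-mask from E)
    v = np.empty((1 << nf, ne))
    for mask in range(1 << nf):
        Xm = np.repeat(B[None, :, :], ne, axis=0)          # (ne, nb, p)
        for gi in range(nf):
            if mask >> gi & 1:
                Xm[:, :, group_cols[gi]] = E[:, None, group_cols[gi]]
        flat = pd.DataFrame(Xm.reshape(ne * nb, -1), columns=cols)
        v[mask] = model.predict(flat).reshape(ne, nb).mean(axis=1)

    w = [factorial(s) * factorial(nf - s - 1) / factorial(nf) for s in range(nf)]
    shap = np.zeros((ne, nf))
    full = (1 << nf) - 1
    for gi in range(nf):
        others = [m for m in range(1 << nf) if not m >> gi & 1]
        for m in others:
            shap[:, gi] += w[bin(m).count("1")] * (v[m | 1 << gi] - v[m])

    return ShapMatrix(
        values=pd.DataFrame(shap, columns=group_names),
        base_value=float(v[0].mean()),
        predictions=v[full],
    )


def mean_abs_shap(shap: ShapMatrix) -> pd.Series:
    """Mean |SHAP| per feature (Gy), descending; ties broken by name."""
    if len(shap.values) == 0:
        raise ValueError("empty SHAP matrix")
    m = shap.values.abs().mean()
    return m.sort_index().sort_values(ascending=False, kind="stable")


def ice_curves(model, rows: pd.DataFrame, feature: str, grid) -> PDResult:
    """Individual conditional expectation curves for one feature.

    Each row's prediction is traced as ``feature`` sweeps the grid with
    everything else fixed; the partial-dependence curve is the pointwise
    mean of the individual curves.
    """
    if feature not in rows.columns:
        raise ValueError(f"unknown feature {feature!r}")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    ice = np.empty((len(rows), len(grid)))
    for gi, val in enumerate(grid):
        X = rows.copy()
        X[feature] = val
        ice[:, gi] = model.predict(X)
    return PDResult(feature=feature, grid=grid, ice=ice, pd=ice.mean(axis=0))


def pd_surface_2d(model, rows: pd.DataFrame, feature_pair, grids) -> PDResult:
    """Partial-dependence surface over a pair of features."""
    fa, fb = feature_pair
    for f in (fa, fb):
        if f not in rows.columns:
            raise ValueError(f"unknown feature {f!r}")
    ga = np.atleast_1d(np.asarray(grids[0], dtype=float))
    gb = np.atleast_1d(np.asarray(grids[1], dtype=float))
    surface = np.empty((len(ga), len(gb)))
    ice = np.empty((len(rows), len(ga) * len(gb)))
    for i, va in enumerate(ga):
        for j, vb in enumerate(gb):
            X = rows.copy()
            X[fa] = va
            X[fb] = vb
            preds = model.predict(X)
            surface[i, j] = preds.mean()
            ice[:, i * len(gb) + j] = preds
    return PDResult(feature=(fa, fb), grid=(ga, gb), ice=ice, pd=surface)
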