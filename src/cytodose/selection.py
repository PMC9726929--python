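"""Shadow-feature (Boruta-style) all-relevant feature selection.

Each iteration appends a shuffled "shadow" copy of every feature to the
design matrix, fits a random forest, and computes out-of-bag permutation
importances.  A real feature scores a *hit* when its importance exceeds
the maximum shadow importance in that iteration.  After ``n_iter``
iterations each feature's hit count is tested against the Binomial(n, 0.5)
null with two-sided tests at ``alpha`` Bonferroni-corrected across
features: significantly more hits than chance -> confirmed, significantly
fewer -> rejected, otherwise tentative.  Shadows are re-shuffled every
iteration.  Tentative features are retained by downstream stages; only
confirmed-worse-than-shadow features are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .forest import QuantileForest

__all__ = ["BorutaResult", "run_boruta"]


@dataclass
class BorutaResult:
    table: pd.DataFrame       # feature, hits, hit_fraction, p_value, decision
    n_iterations: int
    alpha: float
    correction: str = "bonferroni"

    @property
    def confirmed(self) -> list:
        return list(self.table.loc[self.table.decision == "confirmed", "feature"])

    @property
    def rejected(self) -> list:
        return list(self.table.loc[self.table.decision == "rejected", "feature"])

    @property
    def tentative(self) -> list:
        return list(self.table.loc[self.table.decision == "tentative", "feature"])

    def decision_for(self, feature: str) -> str:
        return self.table.set_index("feature").loc[feature, "decision"]


def run_boruta(matrix, n_iter: int = 100, alpha: float = 0.05, seed: int = 0,
               n_trees: int = 100, mtry: int | None = None) -> BorutaResult:
    """Run shadow-feature selection on a ModelMatrix (or (X, y) pair)."""
    if hasattr(matrix, "X"):
        X = matrix.X.to_numpy(dtype=float)
        names = list(matrix.X.columns)
        y = np.asarray(matrix.y, dtype=float)
    else:
        X = np.asarray(matrix[0], dtype=float)
        y = np.asarray(matrix[1], dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 features")
    if n_iter < 10:
        warnings.warn("n_iter < 10 gives very weak binomial evidence")

    rng = np.random.default_rng(seed)
    if mtry is None:
        mtry = max(2, int(round(np.sqrt(2 * p))))
    hits = np.zeros(p, dtype=int)
    for it in range(n_iter):
        shadows = np.empty_like(X)
        for j in range(p):
            shadows[:, j] = X[rng.permutation(len(X)), j]
        Xa = np.hstack([X, shadows])
        forest = QuantileForest(n_trees=n_trees, mtry=min(mtry, 2 * p),
                                min_node_size=5, split_rule="variance",
                                seed=int(rng.integers(0, 2**31 - 1)))
        forest.fit(Xa, y)
        imp = forest.permutation_importance(Xa, y, rng)
        hits += imp[:p] > imp[p:].max()

    rows = []
    for j, name in enumerate(names):
        test = binomtest(int(hits[j]), n_iter, 0.5, alternative="two-sided")
        p_val = test.pvalue
        significant = p_val < alpha / p  # Bonferroni across features
        if significant and hits[j] > n_iter / 2:
            decision = "confirmed"
        elif significant and hits[j] < n_iter / 2:
            decision = "rejected"
        else:
            decision = "tentative"
        rows.append({"feature": name, "hits": int(hits[j]),
                     "hit_fraction": hits[j] / n_iter,
                     "p_value": float(p_val), "decision": decision})
    return BorutaResult(pd.DataFrame(rows), n_iter, alpha)
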