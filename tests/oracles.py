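"""Independent reference implementations used to cross-check the package.

Each oracle computes the same quantity as a package operation by a
different (usually brute-force) route, and stays deliberately independent
of the implementation it checks.
"""

import itertools
import math

import numpy as np
import pandas as pd


class FunctionModel:
    """Wrap a plain function of a DataFrame as a predict-only model."""

    def __init__(self, fn):
        self.fn = fn

    def predict(self, X):
        return np.asarray(self.fn(X), dtype=float)


def brute_force_median_fit(dose, y, tau, degree):
    """Quantile-polynomial oracle: the optimum interpolates degree+1 points.

    Enumerate every subset, fit the interpolating polynomial exactly, and
    return (coefficients, loss) of the candidate with minimal pinball
    loss.  Only feasible for tiny n.
    """
    from cytodose.doseresponse import _design, pinball_loss

    dose = np.asarray(dose, float)
    y = np.asarray(y, float)
    p = degree + 1
    X = _design(dose, degree)
    best, best_loss = None, np.inf
    for subset in itertools.combinations(range(len(y)), p):
        A = X[list(subset)]
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        beta = np.linalg.solve(A, y[list(subset)])
        loss = pinball_loss(y - X @ beta, tau)
        if loss < best_loss - 1e-12:
            best, best_loss = beta, loss
    return best, best_loss


def permutation_oracle(model, x_row: pd.Series, background: pd.DataFrame):
    """Shapley oracle: average marginal contribution over all |F|! orders."""
    cols = list(background.columns)
    shap = {c: 0.0 for c in cols}

    def value(in_coalition):
        Xm = background.copy()
        for c in in_coalition:
            Xm[c] = x_row[c]
        return float(model.predict(Xm).mean())

    for order in itertools.permutations(cols):
        have = []
        prev = value(have)
        for c in order:
            have = have + [c]
            cur = value(have)
            shap[c] += cur - prev
            prev = cur
    n_perm = math.factorial(len(cols))
    return np.array([shap[c] / n_perm for c in cols])


def wilcoxon_enumeration_oracle(d):
    """Exact two-sided signed-rank p by enumerating all 2^n sign flips."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = ranks[d > 0].sum()
    stats = [sum(r for r, s in zip(ranks, signs) if s)
             for signs in itertools.product([0, 1], repeat=n)]
    stats = np.asarray(stats, dtype=float)
    mean = n * (n + 1) / 4
    p = np.mean(np.abs(stats - mean) >= abs(w_plus - mean) - 1e-12)
    return min(1.0, float(p))
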