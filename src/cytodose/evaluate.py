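"""Performance metrics, quantile coverage, and assay-ablation tests.

Conventions of the emulated study:

* MAE = (1/N) sum |D_i - Dhat_i|, RMSE = sqrt((1/N) sum (D_i - Dhat_i)^2);
* R^2 is the **squared Pearson correlation** between actual and
  reconstructed doses (scale/shift invariant), not 1 - SSres/SStot — both
  are reported, the Pearson form is the headline number;
* ablations *retrain* the model without the removed features (permutation
  mode is available) and compare paired squared errors on the held-out
  test rows with a two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .forest import QuantileForest
from .models import ModelSpec, make_model

__all__ = ["MetricsReport", "CoverageReport", "AblationResult",
           "regression_metrics", "quantile_coverage", "wilcoxon_signed_rank",
           "ablation_study"]


@dataclass
class MetricsReport:
    n: int
    mae: float
    rmse: float
    r2_pearson_sq: float | None
    r2_ss: float | None
    per_dose: dict = field(default_factory=dict)   # dose -> {MAE, RMSE, n}
    abs_error_quantiles: dict = field(default_factory=dict)
    r2_undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "n": self.n, "MAE": self.mae, "RMSE": self.rmse,
            "R2_pearson_sq": self.r2_pearson_sq, "R2_ss": self.r2_ss,
            "per_dose": self.per_dose,
            "abs_error_quantiles": self.abs_error_quantiles,
        }


@dataclass
class CoverageReport:
    tau_lo: float
    tau_hi: float
    n: int
    count: int

    @property
    def fraction(self) -> float:
        return self.count / self.n if self.n else np.nan


@dataclass
class AblationResult:
    removed: tuple
    statistic: float
    p_value: float
    full_metrics: MetricsReport
    reduced_metrics: MetricsReport
    degenerate: bool = False

    @property
    def delta(self) -> dict:
        return {
            "dRMSE": self.reduced_metrics.rmse - self.full_metrics.rmse,
            "dMAE": self.reduced_metrics.mae - self.full_metrics.mae,
            "dR2": ((self.reduced_metrics.r2_pearson_sq or np.nan)
                    - (self.full_metrics.r2_pearson_sq or np.nan)),
        }


def regression_metrics(actual, predicted) -> MetricsReport:
    """MAE, RMSE, Pearson-squared R^2, per-dose breakdown and |error|
    percentiles (median, 75th, 80th)."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    if len(actual) < 2:
        raise ValueError("need n >= 2")
    err = actual - predicted
    abs_err = np.abs(err)
    mae = float(abs_err.mean())
    rmse = float(np.sqrt(np.mean(err**2)))
    undefined = np.std(actual) == 0 or np.std(predicted) == 0
    if undefined:
        r2p = r2ss = None
    else:
        r2p = float(np.corrcoef(actual, predicted)[0, 1] ** 2)
        ss_res = float(np.sum(err**2))
        ss_tot = float(np.sum((actual - actual.mean()) ** 2))
        r2ss = 1.0 - ss_res / ss_tot
    per_dose = {}
    for d in np.unique(actual):
        m = actual == d
        per_dose[float(d)] = {
            "n": int(m.sum()),
            "MAE": float(abs_err[m].mean()),
            "RMSE": float(np.sqrt(np.mean(err[m] ** 2))),
        }
    q = {f"p{int(p)}": float(np.percentile(abs_err, p)) for p in (50, 75, 80)}
    return MetricsReport(n=len(actual), mae=mae, rmse=rmse, r2_pearson_sq=r2p,
                         r2_ss=r2ss, per_dose=per_dose, abs_error_quantiles=q,
                         r2_undefined=undefined)


def quantile_coverage(actual, quantile_matrix: pd.DataFrame, tau_lo: float,
                      tau_hi: float) -> CoverageReport:
    """Count actual doses inside [q_lo, q_hi] (inclusive)."""
    if tau_lo >= tau_hi:
        raise ValueError("tau_lo must be < tau_hi")
    lo_col = f"q{int(round(tau_lo * 100))}"
    hi_col = f"q{int(round(tau_hi * 100))}"
    for col in (lo_col, hi_col):
        if col not in quantile_matrix.columns:
            raise ValueError(f"quantile column {col} missing")
    actual = np.asarray(actual, dtype=float)
    lo = quantile_matrix[lo_col].to_numpy()
    hi = quantile_matrix[hi_col].to_numpy()
    inside = (actual >= lo) & (actual <= hi)
    return CoverageReport(tau_lo=tau_lo, tau_hi=tau_hi, n=len(actual),
                          count=int(inside.sum()))


def wilcoxon_signed_rank(errors_a, errors_b) -> tuple[float, float, bool]:
    """Two-sided paired Wilcoxon signed-rank test on errors_a vs errors_b.

    Zero differences are dropped (Wilcoxon's original treatment); the null
    distribution is exact for n <= 25 remaining pairs and a tie-corrected
    normal approximation with continuity correction otherwise.  Returns
    (statistic, p, degenerate) where degenerate marks an all-zero
    difference vector (p reported as 1).
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    nonzero = d != 0
    if not nonzero.any():
        return 0.0, 1.0, True
    if nonzero.sum() < 6:
        raise ValueError("need >= 6 non-zero paired differences")
    dnz = d[nonzero]
    has_ties = np.unique(np.abs(dnz)).size < dnz.size
    method = "exact" if (nonzero.sum() <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True,
                         method=method)
    return float(res.statistic), float(res.pvalue), False


def ablation_study(matrix, removal_sets, model_spec: ModelSpec, split,
                   seed: int = 0, mode: str = "retrain") -> list[AblationResult]:
    """Compare the full model against models with feature sets removed.

    ``split`` is a part-label Series (train/eval/test); the full and each
    reduced model are trained on identical train+eval rows and their paired
    squared errors compared on identical test rows.  ``mode='retrain'``
    refits without the features (the study's procedure); ``mode='permute'``
    keeps the full model and permutes the removed columns at test time.
    """
    if mode not in ("retrain", "permute"):
        raise ValueError("mode must be 'retrain' or 'permute'")
    part = np.asarray(split)
    train_mask = part != "test"
    test_mask = part == "test"
    train = matrix.select_rows(train_mask)
    test = matrix.select_rows(test_mask)

    spec = ModelSpec(model_spec.family, model_spec.hyperparameters, seed=seed)
    full_model = make_model(spec).fit(train.X, train.y)
    full_pred = full_model.predict(test.X)
    full_sq = (test.y - full_pred) ** 2
    full_metrics = regression_metrics(test.y, full_pred)

    results = []
    for removed in removal_sets:
        removed = tuple(removed)
        if set(removed) >= set(matrix.feature_names):
            raise ValueError("cannot remove every feature")
        if mode == "retrain":
            red_train = train.drop_features(removed)
            red_test = test.drop_features(removed)
            hp = dict(spec.hyperparameters)
            if hp.get("mtry"):
                hp["mtry"] = min(hp["mtry"], len(red_train.feature_names))
            red_model = make_model(ModelSpec(spec.family, hp, spec.seed)).fit(
                red_train.X, red_train.y)
            red_pred = red_model.predict(red_test.X)
        else:
            rng = np.random.default_rng(seed)
            Xp = test.X.copy()
            for colname in removed:
                Xp[colname] = rng.permutation(Xp[colname].to_numpy())
            red_pred = full_model.predict(Xp)
        red_sq = (test.y - red_pred) ** 2
        stat, p, degen = wilcoxon_signed_rank(red_sq, full_sq)
        results.append(AblationResult(
            removed=removed, statistic=stat, p_value=p,
            full_metrics=full_metrics,
            reduced_metrics=regression_metrics(test.y, red_pred),
            degenerate=degen))
    return results
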