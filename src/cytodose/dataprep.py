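"""Reading, filtering, index computation, feature encoding and splitting.

The per-aliquot table carries raw assay counts; this module applies the
low-count exclusion rule (aliquots with fewer than 20 binucleated cells or
fewer than 20 monocentric chromosomes are unreliable and removed), derives
the three assay indices

* ``yield`` = dicentrics / monocentric chromosomes (DCA),
* ``mi_bn`` = micronuclei / binucleated cells (CBMN),
* ``mi_bn_c`` = mi_bn + (1/k) * mononucleated / binucleated (linearized CBMN),

one-hot encodes the demographic categoricals and produces the 1/4 / 1/4 / 1/2
train / eval / test partition used by the model harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import COHORT_COLUMNS

__all__ = [
    "FilterLog", "ModelMatrix", "read_table", "filter_low_counts",
    "compute_indices", "encode_features", "split_data",
    "RACE_LEVELS", "ETHNICITY_LEVELS",
]

RACE_LEVELS = (0, 1, 2, 3, 4)
ETHNICITY_LEVELS = (0, 1, 2)

REQUIRED_COLUMNS = COHORT_COLUMNS
COUNT_COLUMNS = ["mc_count", "dic_count", "bn_count", "mn_count", "mono_count"]


@dataclass
class FilterLog:
    """Book-keeping for the low-count exclusion rule."""

    n_input: int
    n_retained: int
    n_excluded: int
    reasons: pd.DataFrame  # columns: row_id, reason
    counts_missing: bool = False

    def __post_init__(self) -> None:
        assert self.n_input == self.n_retained + self.n_excluded

    def to_frame(self) -> pd.DataFrame:
        return self.reasons.copy()


@dataclass
class ModelMatrix:
    """Numeric design matrix plus target doses and a column registry."""

    X: pd.DataFrame
    y: np.ndarray
    feature_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.feature_names = list(self.X.columns)
        if self.X.isna().any().any():
            raise ValueError("model matrix contains missing values")

    def drop_features(self, names) -> "ModelMatrix":
        names = list(names)
        unknown = [n for n in names if n not in self.feature_names]
        if unknown:
            raise ValueError(f"unknown features: {unknown}")
        keep = [c for c in self.feature_names if c not in names]
        if not keep:
            raise ValueError("cannot drop every feature")
        return ModelMatrix(self.X[keep].copy(), self.y.copy())

    def select_rows(self, mask) -> "ModelMatrix":
        return ModelMatrix(self.X.loc[mask].reset_index(drop=True),
                           np.asarray(self.y)[np.asarray(mask)])


def read_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a per-aliquot CSV, optionally remapping deposited-file headers.

    ``column_map`` maps *source* column names to the canonical schema
    (e.g. ``{"Age": "age", "Dose": "dose_gy"}``), supporting deposited
    files whose exact header spelling differs.  Rows whose required fields
    fail numeric parsing are dropped; the count of dropped rows is attached
    as ``df.attrs["n_unparseable"]``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = df[list(df.columns)]
    n0 = len(df)
    for col in REQUIRED_COLUMNS:
        if col != "donor_id":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=[c for c in REQUIRED_COLUMNS if c != "donor_id"])
    df = df.reset_index(drop=True)
    for col in ["age", "sex", "race", "ethnicity", "dose_rate_category"] + COUNT_COLUMNS:
        df[col] = df[col].astype(int)
    df.attrs["n_unparseable"] = n0 - len(df)
    return df


def filter_low_counts(records: pd.DataFrame, min_bn: int = 20,
                      min_mc: int = 20) -> tuple[pd.DataFrame, FilterLog]:
    """Remove aliquots with < ``min_bn`` binucleated cells or < ``min_mc``
    monocentric chromosomes (boundary inclusive: exactly 20 is retained).

    If the table lacks count columns (a pre-filtered deposited file), rows
    pass through untouched with ``counts_missing`` flagged on the log.
    """
    n = len(records)
    if "bn_count" not in records.columns or "mc_count" not in records.columns:
        log = FilterLog(n, n, 0, pd.DataFrame(columns=["row_id", "reason"]),
                        counts_missing=True)
        return records.copy(), log
    low_bn = records["bn_count"] < min_bn
    low_mc = records["mc_count"] < min_mc
    excluded = low_bn | low_mc
    reason = np.select(
        [low_bn & low_mc, low_bn, low_mc],
        ["BN+MC", "BN", "MC"], default="")
    reasons = pd.DataFrame({
        "row_id": records.index[excluded],
        "reason": reason[excluded.to_numpy()],
    }).reset_index(drop=True)
    retained = records.loc[~excluded].reset_index(drop=True)
    return retained, FilterLog(n, len(retained), int(excluded.sum()), reasons)


def compute_indices(records: pd.DataFrame, k: float,
                    yield_denominator: str = "mc") -> pd.DataFrame:
    """Attach yield, mi_bn and the linearized mi_bn_c (at constant ``k``).

    ``yield_denominator`` selects what the dicentric count is normalised
    by: ``"mc"`` (monocentric chromosomes, the default) or ``"total"``
    (all scored chromosomes, counting each dicentric as two) — source
    material uses both phrasings, so the choice is explicit here.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if (records["bn_count"] <= 0).any() or (records["mc_count"] <= 0).any():
        raise ValueError("zero BN or MC counts: apply filter_low_counts first")
    out = records.copy()
    if yield_denominator == "mc":
        out["yield"] = out["dic_count"] / out["mc_count"]
    elif yield_denominator == "total":
        out["yield"] = out["dic_count"] / (out["mc_count"] + 2 * out["dic_count"])
    else:
        raise ValueError("yield_denominator must be 'mc' or 'total'")
    out["mi_bn"] = out["mn_count"] / out["bn_count"]
    out["mi_bn_c"] = out["mi_bn"] + out["mono_count"] / (k * out["bn_count"])
    return out


def encode_features(records: pd.DataFrame, include_dose_rate: bool = False,
                    include_sex: bool = False) -> ModelMatrix:
    """Build the model matrix: age, one-hot race/ethnicity and the three
    assay indices; sex and dose-rate category join only on request.

    All declared category levels get a column (no reference level is
    dropped — tree ensembles are insensitive and the full set keeps the
    encoding invertible).  Unknown levels are an error.
    """
    for col, levels in (("race", RACE_LEVELS), ("ethnicity", ETHNICITY_LEVELS)):
        bad = set(records[col].unique()) - set(levels)
        if bad:
            raise ValueError(f"unknown {col} levels: {sorted(bad)}")
    cols = {"age": records["age"].to_numpy(float)}
    if include_sex:
        cols["sex"] = records["sex"].to_numpy(float)
    for lv in RACE_LEVELS:
        cols[f"race_{lv}"] = (records["race"] == lv).to_numpy(float)
    for lv in ETHNICITY_LEVELS:
        cols[f"ethnicity_{lv}"] = (records["ethnicity"] == lv).to_numpy(float)
    if include_dose_rate:
        cols["dose_rate_category"] = records["dose_rate_category"].to_numpy(float)
    for col in ("yield", "mi_bn", "mi_bn_c"):
        if col not in records.columns:
            raise ValueError("indices not computed: call compute_indices first")
        cols[col] = records[col].to_numpy(float)
    X = pd.DataFrame(cols)
    y = records["dose_gy"].to_numpy(float)
    return ModelMatrix(X, y)


def split_data(records: pd.DataFrame, fractions=(0.25, 0.25, 0.5),
               seed: int = 0, stratify_by_dose: bool = True) -> pd.Series:
    """Assign each row to {train, eval, test} with the given fractions.

    Stratified by dose level by default so that sparse dose groups are
    represented in every part; reproducible from ``seed``.  Returns a
    Series of labels aligned with ``records``.
    """
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != 3 or np.any(fractions < 0) or not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must be three non-negative values summing to 1")
    n = len(records)
    positive = fractions > 0
    if n < positive.sum():
        raise ValueError("too few rows for the requested non-empty parts")
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=object)
    groups = (records.groupby("dose_gy").indices.values()
              if stratify_by_dose else [np.arange(n)])
    for idx in groups:
        idx = np.asarray(idx)
        idx = idx[rng.permutation(len(idx))]
        m = len(idx)
        n_train = int(round(m * fractions[0]))
        n_eval = int(round(m * fractions[1]))
        n_eval = min(n_eval, m - n_train)
        labels[idx[:n_train]] = "train"
        labels[idx[n_train:n_train + n_eval]] = "eval"
        labels[idx[n_train + n_eval:]] = "test"
    return pd.Series(labels, index=records.index, name="part")
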