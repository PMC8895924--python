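"""Cohort statistics: descriptives with 95% CIs, normality-gated two-group
comparisons, correlation screens, and tabular report assembly.

Conventions: sample SD uses n-1; the CI uses the t quantile (not 1.96);
normality is gated per sample by Shapiro-Wilk at alpha = 0.05; group
comparisons use Welch's t-test when both groups pass the gate and the
Mann-Whitney U test (normal approximation with tie correction) otherwise;
correlations use Pearson when both vectors pass the gate, Spearman
otherwise.  No multiple-testing adjustment is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .model import MEASURE_FIELDS

SHAPIRO_ALPHA = 0.05


@dataclass
class Descriptive:
    variable: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    median: float
    iqr_low: float
    iqr_high: float
    normal_flag: bool


@dataclass
class GroupComparison:
    variable: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    test_used: str  # "t" (Welch) or "mann_whitney"
    statistic: float
    p_value: float


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    method: str  # "pearson" or "spearman"
    r: float
    p_value: float


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if not np.isfinite(arr).all():
        arr = arr[np.isfinite(arr)]
    return arr


def _is_normal(arr: np.ndarray) -> bool:
    if np.ptp(arr) == 0:  # constant sample: Shapiro is undefined
        return False
    return bool(sps.shapiro(arr).pvalue > SHAPIRO_ALPHA)


def describe(values, variable: str = "") -> Descriptive:
    """Mean, sample SD, t-based 95% CI, median/IQR, and a normality flag."""
    arr = _clean(values)
    n = arr.size
    if n < 2:
        raise ValidationError("describe requires at least 2 finite values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    half = float(sps.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
    q1, med, q3 = (float(q) for q in np.percentile(arr, [25, 50, 75]))
    return Descriptive(
        variable=variable,
        n=n,
        mean=mean,
        sd=sd,
        ci_low=mean - half,
        ci_high=mean + half,
        median=med,
        iqr_low=q1,
        iqr_high=q3,
        normal_flag=_is_normal(arr),
    )


def compare_groups(
    values_a, values_b, variable: str = "", label_a: str = "A", label_b: str = "B"
) -> GroupComparison:
    """Welch t-test if both groups pass the normality gate, else Mann-Whitney U."""
    a = _clean(values_a)
    b = _clean(values_b)
    if a.size < 3 or b.size < 3:
        raise ValidationError("compare_groups requires at least 3 values per group")
    if _is_normal(a) and _is_normal(b):
        res = sps.ttest_ind(a, b, equal_var=False)
        test = "t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        test = "mann_whitney"
    return GroupComparison(
        variable=variable,
        group_a=label_a,
        group_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def correlate(x, y, method: str = "auto") -> CorrelationResult:
    """Pearson or Spearman correlation with two-sided p-value.

    ``method="auto"`` selects Pearson when both vectors pass the normality
    gate and Spearman otherwise.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError("correlate requires paired vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValidationError("correlate requires at least 4 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlate requires non-constant vectors")
    if method == "auto":
        method = "pearson" if (_is_normal(x) and _is_normal(y)) else "spearman"
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(pair=("x", "y"), method=method, r=float(res.statistic), p_value=float(res.pvalue))


def build_tables(measurements, out_dir) -> dict[str, Path]:
    """Write descriptive, subgroup-comparison, and correlation CSVs.

    ``measurements`` is a measurement DataFrame or CSV path.  Outputs:
    ``descriptives.csv`` (one row per measure), ``subgroups.csv``
    (per measure x {sex, side} grouping), and ``correlations.csv``
    (age vs each measure plus all measure pairs).  Deterministic given the
    same input.
    """
    if isinstance(measurements, (str, Path)):
        frame = pd.read_csv(measurements)
    else:
        frame = measurements.copy()
    missing = [c for c in MEASURE_FIELDS if c not in frame.columns]
    if missing:
        raise ValidationError(f"measurements table missing columns: {missing}")
    if len(frame) < 2:
        raise ValidationError("build_tables requires at least 2 records")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    desc_rows = [describe(frame[m], m).__dict__ for m in MEASURE_FIELDS]
    desc = pd.DataFrame(desc_rows)

    comp_rows = []
    groupings = [("sex", "M", "F"), ("side", "L", "R")]
    for column, label_a, label_b in groupings:
        if column not in frame.columns:
            continue
        a_mask = frame[column] == label_a
        b_mask = frame[column] == label_b
        for m in MEASURE_FIELDS:
            try:
                cmp_res = compare_groups(
                    frame.loc[a_mask, m], frame.loc[b_mask, m], m, label_a, label_b
                )
            except ValidationError:
                continue
            row = {"grouping": column}
            row.update(cmp_res.__dict__)
            comp_rows.append(row)
    comps = pd.DataFrame(comp_rows)

    corr_rows = []
    if "age" in frame.columns and frame["age"].notna().sum() >= 4:
        for m in MEASURE_FIELDS:
            res = correlate(frame["age"], frame[m])
            corr_rows.append({"var_a": "age", "var_b": m, "method": res.method, "r": res.r, "p_value": res.p_value})
    for i, m1 in enumerate(MEASURE_FIELDS):
        for m2 in MEASURE_FIELDS[i + 1 :]:
            res = correlate(frame[m1], frame[m2])
            corr_rows.append({"var_a": m1, "var_b": m2, "method": res.method, "r": res.r, "p_value": res.p_value})
    corrs = pd.DataFrame(corr_rows)

    paths = {
        "descriptives": out_dir / "descriptives.csv",
        "subgroups": out_dir / "subgroups.csv",
        "correlations": out_dir / "correlations.csv",
    }
    desc.to_csv(paths["descriptives"], index=False)
    comps.to_csv(paths["subgroups"], index=False)
    corrs.to_csv(paths["correlations"], index=False)
    return paths
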