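"""Method-comparison statistics: correlation, Bland-Altman, ANOVA, Tukey.

Agreement between a candidate fat-mass method and the multi-compartment
reference is summarised by Pearson correlation and Bland-Altman mean
difference with 95% limits of agreement (mean +/- 1.96 SD of the paired
differences, reference minus method). Group comparisons of anthropometry
are computed directly from published (n, mean, SD) summary triples: one-way
ANOVA and the Tukey-Kramer studentized-range test, whose critical value is
obtained numerically from the studentized-range distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ModelDomainError
from .reference_data import GroupSummary

__all__ = [
    "AgreementSummary",
    "bland_altman",
    "pearson_r",
    "anova_oneway_from_summaries",
    "tukey_kramer_q",
    "build_comparison_report",
    "CALIBRATED_METHODS",
    "DIRECT_METHODS",
]

#: index methods are regression-calibrated to the 4C target on the training
#: set before evaluation; direct methods already output grams of fat
CALIBRATED_METHODS = ("NIR", "NIR_noL", "MUAC", "BMI", "W/A", "L/A", "W/L")
DIRECT_METHODS = ("DD", "DXA", "SFT")


@dataclass(frozen=True)
class AgreementSummary:
    """n, Pearson R, mean difference and 95% limits of agreement (grams)."""

    method: str
    n: int
    pearson_r: float
    mean_diff_g: float
    loa_low_g: float
    loa_high_g: float


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; zero variance in either input is flagged."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ModelDomainError("pearson_r requires paired vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return np.nan
    return float(sps.pearsonr(x, y).statistic)


def bland_altman(reference, method, name: str = "method", multiplier: float = 1.96) -> AgreementSummary:
    """Bland-Altman agreement of a method against the reference.

    Differences are reference - method; limits of agreement are
    mean +/- 1.96 SD (sample SD, n-1 denominator).
    """
    ref = np.asarray(reference, dtype=float)
    meth = np.asarray(method, dtype=float)
    if len(ref) != len(meth) or len(ref) < 3:
        raise ModelDomainError("bland_altman requires paired vectors with n >= 3")
    d = ref - meth
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementSummary(
        method=name,
        n=len(d),
        pearson_r=pearson_r(ref, meth) if np.std(meth) > 0 else np.nan,
        mean_diff_g=mean,
        loa_low_g=mean - multiplier * sd,
        loa_high_g=mean + multiplier * sd,
    )


def anova_oneway_from_summaries(groups: list[GroupSummary]) -> tuple[float, int, int]:
    """One-way ANOVA F and degrees of freedom from (n, mean, SD) triples.

    MSE pools the within-group variances; MSB uses deviations of group means
    about the weighted grand mean. Returns (F, df_between, df_within).
    """
    if len(groups) < 2:
        raise ModelDomainError("ANOVA requires at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    N, k = ns.sum(), len(groups)
    if N - k <= 0:
        raise ModelDomainError("no within-group degrees of freedom")
    grand = float(np.sum(ns * means) / N)
    msb = float(np.sum(ns * (means - grand) ** 2) / (k - 1))
    mse = float(np.sum((ns - 1) * sds**2) / (N - k))
    if mse == 0:
        return (np.inf if msb > 0 else 0.0), int(k - 1), int(N - k)
    return msb / mse, int(k - 1), int(N - k)


def tukey_kramer_q(
    group_i: GroupSummary,
    group_j: GroupSummary,
    mse: float,
    alpha: float = 0.05,
    k: int = 3,
    df: int | None = None,
) -> tuple[float, float, bool]:
    """Tukey-Kramer studentized-range statistic for one pair of groups.

    q = |mean_i - mean_j| / sqrt((MSE/2)(1/n_i + 1/n_j)); the critical value
    is the studentized-range quantile at (1-alpha, k, df). Valid for unequal
    group sizes.
    """
    if mse <= 0:
        raise ModelDomainError("mse must be > 0")
    if df is None or df < 1:
        raise ModelDomainError("df must be a positive integer")
    se = np.sqrt((mse / 2.0) * (1.0 / group_i.n + 1.0 / group_j.n))
    q = abs(group_i.mean - group_j.mean) / se
    q_crit = float(sps.studentized_range.ppf(1.0 - alpha, k, df))
    return float(q), q_crit, bool(q > q_crit)


def _calibrate(train_value: np.ndarray, train_ref: np.ndarray):
    """OLS slope/intercept mapping a raw index onto the 4C target."""
    X = np.column_stack([train_value, np.ones(len(train_value))])
    beta, *_ = np.linalg.lstsq(X, train_ref, rcond=None)
    return beta


def build_comparison_report(
    method_values: pd.DataFrame,
    reference: pd.Series,
    train_ids,
    test_ids,
    calibrated=CALIBRATED_METHODS,
    group_label: str = "3-24",
) -> pd.DataFrame:
    """Per-method train/test correlation and Bland-Altman agreement table.

    ``method_values`` has one column per method (raw index values for the
    calibrated methods, grams for direct methods) indexed by subject_id;
    ``reference`` is 4C fat mass (g) on the same index. Calibrated methods
    are regressed onto the reference on the training fold before evaluation
    (so their training mean difference is exactly zero); direct methods are
    evaluated raw. Rows are sorted by descending test R.
    """
    train_ids = [i for i in train_ids if i in method_values.index]
    test_ids = [i for i in test_ids if i in method_values.index]
    ref_tr = reference.loc[train_ids].to_numpy(dtype=float)
    ref_te = reference.loc[test_ids].to_numpy(dtype=float)
    rows = []
    for method in method_values.columns:
        vals = method_values[method]
        if vals.loc[train_ids].isna().any() or vals.loc[test_ids].isna().any():
            warnings.warn(f"method {method!r} missing values; excluded from report", stacklevel=2)
            continue
        v_tr = vals.loc[train_ids].to_numpy(dtype=float)
        v_te = vals.loc[test_ids].to_numpy(dtype=float)
        if method in calibrated:
            slope, icept = _calibrate(v_tr, ref_tr)
            v_tr = slope * v_tr + icept
            v_te = slope * v_te + icept
        tr = bland_altman(ref_tr, v_tr, name=method)
        te = bland_altman(ref_te, v_te, name=method)
        rows.append(
            {
                "group": group_label,
                "method": method,
                "calibrated": method in calibrated,
                "n_train": tr.n,
                "n_test": te.n,
                "train_r": tr.pearson_r,
                "train_mean_diff_g": tr.mean_diff_g,
                "train_loa_low_g": tr.loa_low_g,
                "train_loa_high_g": tr.loa_high_g,
                "test_r": te.pearson_r,
                "test_mean_diff_g": te.mean_diff_g,
                "test_loa_low_g": te.loa_low_g,
                "test_loa_high_g": te.loa_high_g,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("test_r", ascending=False, kind="mergesort").reset_index(drop=True)
    return out


def format_report(report: pd.DataFrame) -> str:
    """Aligned plain-text rendering of the comparison report."""
    lines = [
        f"{'group':>6} {'method':>8} {'train R':>8} {'train diff (LoA)':>28} "
        f"{'test R':>7} {'test diff (LoA)':>28}"
    ]
    for row in report.itertuples(index=False):
        tr = f"{row.train_mean_diff_g:.1f} ({row.train_loa_low_g:.1f}, {row.train_loa_high_g:.1f})"
        te = f"{row.test_mean_diff_g:.1f} ({row.test_loa_low_g:.1f}, {row.test_loa_high_g:.1f})"
        lines.append(
            f"{row.group:>6} {row.method:>8} {row.train_r:>8.3f} {tr:>28} "
            f"{row.test_r:>7.3f} {te:>28}"
        )
    return "\n".join(lines) + "\n"
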