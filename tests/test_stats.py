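"""Bland-Altman, Pearson, summary-statistics ANOVA and Tukey-Kramer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from nirfat.errors import ModelDomainError
from nirfat.reference_data import GroupSummary, group_summaries
from nirfat.stats import (
    anova_oneway_from_summaries,
    bland_altman,
    build_comparison_report,
    pearson_r,
    tukey_kramer_q,
)


def _with_moments(n, mean, sd, rng):
    """A vector with exactly the requested sample mean and SD (ddof=1)."""
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


# ------------------------------------------------------------ Bland-Altman

def test_bland_altman_reproduces_published_interval(rng):
    # the published NIR all-ages test row: -78.9 (-954.3, 796.6)
    ref = rng.normal(2000.0, 800.0, size=66)
    diffs = _with_moments(66, -78.85, 446.66, rng)
    summ = bland_altman(ref, ref - diffs)
    assert summ.mean_diff_g == pytest.approx(-78.85, abs=1e-9)
    assert summ.loa_low_g == pytest.approx(-954.3, abs=0.05)
    assert summ.loa_high_g == pytest.approx(796.6, abs=0.05)
    assert summ.mean_diff_g == pytest.approx((summ.loa_low_g + summ.loa_high_g) / 2, abs=0.1)


def test_bland_altman_identity():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    summ = bland_altman(x, x)
    assert summ.mean_diff_g == 0.0 and summ.loa_low_g == 0.0 and summ.loa_high_g == 0.0


@settings(deadline=None, derandomize=True)
@given(seed=st.integers(0, 1000))
def test_bland_altman_antisymmetry(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(2000, 500, size=12)
    b = a - rng.normal(100, 300, size=12)
    fwd = bland_altman(a, b)
    rev = bland_altman(b, a)
    assert fwd.mean_diff_g == pytest.approx(-rev.mean_diff_g, rel=1e-12, abs=1e-9)
    assert fwd.loa_low_g == pytest.approx(-rev.loa_high_g, rel=1e-12, abs=1e-9)
    assert fwd.loa_high_g == pytest.approx(-rev.loa_low_g, rel=1e-12, abs=1e-9)


# ------------------------------------------------------------ Pearson

def test_pearson_exact_lines():
    x = np.array([1.0, 2.0, 3.0, 5.0])
    assert pearson_r(x, 2 * x + 3) == pytest.approx(1.0)
    assert pearson_r(x, -x) == pytest.approx(-1.0)


def test_pearson_matches_manual_covariance(rng):
    x = rng.normal(size=5)
    y = rng.normal(size=5)
    manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    assert pearson_r(x, y) == pytest.approx(manual, abs=1e-12)


def test_pearson_zero_variance_flagged():
    with pytest.warns(UserWarning, match="variance"):
        assert np.isnan(pearson_r(np.ones(5), np.arange(5.0)))


# ------------------------------------------------------------ ANOVA / Tukey

def test_anova_identical_groups_zero():
    gs = [GroupSummary("a", 10, 5.0, 1.0), GroupSummary("b", 12, 5.0, 1.0),
          GroupSummary("c", 9, 5.0, 1.0)]
    F, dfb, dfw = anova_oneway_from_summaries(gs)
    assert F == pytest.approx(0.0)
    assert (dfb, dfw) == (2, 28)


def test_anova_published_muac_groups():
    F, dfb, dfw = anova_oneway_from_summaries(group_summaries("muac_cm"))
    assert (dfb, dfw) == (2, 325)
    assert F == pytest.approx(9.75, abs=0.01)  # printed 9.330 from unrounded data


def test_anova_sd_scale_property():
    gs = group_summaries("muac_cm")
    doubled = [GroupSummary(g.label, g.n, g.mean, 2 * g.sd) for g in gs]
    F1, *_ = anova_oneway_from_summaries(gs)
    F2, *_ = anova_oneway_from_summaries(doubled)
    assert F2 == pytest.approx(F1 / 4.0, rel=1e-12)


def test_anova_matches_raw_data_oracle(rng):
    groups = [rng.normal(10 + i, 2.0, size=n) for i, n in enumerate((8, 11, 9))]
    gs = [GroupSummary(f"g{i}", len(g), float(g.mean()), float(g.std(ddof=1)))
          for i, g in enumerate(groups)]
    F, dfb, dfw = anova_oneway_from_summaries(gs)
    assert F == pytest.approx(sps.f_oneway(*groups).statistic, rel=1e-9)


def test_tukey_published_muac_pair():
    gs = group_summaries("muac_cm")
    _, _, dfw = anova_oneway_from_summaries(gs)
    ns = np.array([g.n for g in gs])
    mse = float(np.sum((ns - 1) * np.array([g.sd for g in gs]) ** 2) / (ns.sum() - 3))
    q, q_crit, sig = tukey_kramer_q(gs[0], gs[2], mse, alpha=0.05, k=3, df=dfw)
    assert q == pytest.approx(4.19, abs=0.05)
    assert q_crit == pytest.approx(3.335, abs=0.01)
    assert sig


def test_tukey_equal_means_not_significant():
    a = GroupSummary("a", 20, 5.0, 1.0)
    b = GroupSummary("b", 25, 5.0, 1.2)
    q, _, sig = tukey_kramer_q(a, b, 1.0, df=43)
    assert q == 0.0 and not sig


def test_tukey_matches_statsmodels_on_raw_data(rng):
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = [rng.normal(m, 1.5, size=n) for m, n in ((10.0, 10), (12.0, 8), (10.5, 12))]
    values = np.concatenate(groups)
    labels = np.repeat(["a", "b", "c"], [len(g) for g in groups])
    sm = pairwise_tukeyhsd(values, labels, alpha=0.05)
    gs = [GroupSummary(lbl, len(g), float(g.mean()), float(g.std(ddof=1)))
          for lbl, g in zip("abc", groups)]
    _, _, dfw = anova_oneway_from_summaries(gs)
    ns = np.array([g.n for g in gs])
    mse = float(np.sum((ns - 1) * np.array([g.sd for g in gs]) ** 2) / (ns.sum() - 3))
    mine = [tukey_kramer_q(gs[i], gs[j], mse, df=dfw)[2]
            for i, j in ((0, 1), (0, 2), (1, 2))]
    np.testing.assert_array_equal(mine, sm.reject)


def test_tukey_invalid_inputs():
    a = GroupSummary("a", 5, 1.0, 1.0)
    with pytest.raises(ModelDomainError):
        tukey_kramer_q(a, a, 0.0, df=10)
    with pytest.raises(ModelDomainError):
        tukey_kramer_q(a, a, 1.0, df=None)


# ------------------------------------------------------------ report

def _toy_predictions(rng, n=40):
    ref = rng.normal(2000.0, 700.0, size=n)
    frame = pd.DataFrame(
        {
            "SELF": ref,
            "DD": ref + rng.normal(50.0, 30.0, size=n),
            "MUAC": 14.0 + 0.002 * ref + rng.normal(0, 1.0, size=n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    return frame, pd.Series(ref, index=frame.index)


def test_report_reference_vs_itself_ranked_first(rng):
    frame, ref = _toy_predictions(rng)
    train, test = list(frame.index[:24]), list(frame.index[24:])
    report = build_comparison_report(frame, ref, train, test, calibrated=("MUAC",))
    top = report.iloc[0]
    assert top["method"] == "SELF"
    assert top["test_r"] == pytest.approx(1.0)
    assert top["test_loa_low_g"] == pytest.approx(0.0, abs=1e-9)


def test_report_calibrated_train_mean_diff_zero(rng):
    frame, ref = _toy_predictions(rng)
    train, test = list(frame.index[:24]), list(frame.index[24:])
    report = build_comparison_report(frame, ref, train, test, calibrated=("MUAC",))
    row = report.set_index("method").loc["MUAC"]
    assert abs(row["train_mean_diff_g"]) < 1e-9
    # direct methods keep their bias
    assert report.set_index("method").loc["DD", "train_mean_diff_g"] != pytest.approx(0.0, abs=1.0)


def test_report_deterministic(rng):
    frame, ref = _toy_predictions(rng)
    train, test = list(frame.index[:20]), list(frame.index[20:])
    r1 = build_comparison_report(frame, ref, train, test)
    r2 = build_comparison_report(frame.copy(), ref.copy(), list(train), list(test))
    pd.testing.assert_frame_equal(r1, r2)
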