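"""Stratified split, LOOCV scoring, feature selection and the OLS model."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from nirfat.errors import ModelDomainError
from nirfat.nir_model import (
    FittedNirModel,
    NirFatMassRegressor,
    fit_model,
    loocv_error,
    predict_fm,
    select_features,
    stratified_split,
)


# ------------------------------------------------------------ split

def _cohort_frame(ages, sexes=None):
    n = len(ages)
    return pd.DataFrame({
        "subject_id": [f"s{i:03d}" for i in range(n)],
        "age_months": ages,
        "sex": sexes if sexes is not None else ["male"] * n,
    })


def test_split_single_stratum_counts():
    df = _cohort_frame([4.0] * 10)
    train, test = stratified_split(df, train_fraction=3 / 5, seed=1)
    assert len(train) == 6 and len(test) == 4
    assert sorted(train + test) == sorted(df["subject_id"])


def test_split_deterministic():
    df = _cohort_frame(np.linspace(3, 24, 50))
    assert stratified_split(df, seed=3) == stratified_split(df, seed=3)
    assert stratified_split(df, seed=3) != stratified_split(df, seed=4)


def test_split_largest_remainder_on_published_group_sizes():
    # 105 young + 59 older subjects; 3/5 quota -> 63 + 35 train subjects
    ages = list(np.linspace(3.0, 6.5, 105)) + list(np.linspace(7.0, 24.0, 59))
    df = _cohort_frame(ages)
    train, _ = stratified_split(df, train_fraction=3 / 5, seed=0,
                                age_bins=(3.0, 6.99, 24.0))
    train_ages = df.set_index("subject_id").loc[train, "age_months"]
    assert (train_ages < 7).sum() == 63
    assert (train_ages >= 7).sum() == 35


def test_split_tiny_stratum_goes_to_train():
    df = _cohort_frame([4.0] * 10 + [20.0], sexes=["male"] * 10 + ["female"])
    with pytest.warns(UserWarning, match="stratum"):
        train, test = stratified_split(df, seed=2)
    assert "s010" in train


# ------------------------------------------------------------ LOOCV

def _brute_force_loocv(X, y, metric="mae"):
    """Independent oracle: refit from scratch for every left-out subject."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xa = np.column_stack([X, np.ones(n)])
    errs = []
    for i in range(n):
        keep = np.arange(n) != i
        beta, *_ = np.linalg.lstsq(Xa[keep], y[keep], rcond=None)
        errs.append(y[i] - Xa[i] @ beta)
    errs = np.asarray(errs)
    return float(np.mean(np.abs(errs))) if metric == "mae" else float(np.mean(errs**2))


def test_loocv_zero_on_exact_linear(rng):
    X = rng.normal(size=(20, 3))
    y = X @ np.array([2.0, -1.0, 0.5]) + 3.0
    assert loocv_error(X, y) == pytest.approx(0.0, abs=1e-8)


@pytest.mark.parametrize("n, k", [(8, 2), (12, 5), (15, 12)])
@pytest.mark.parametrize("metric", ["mae", "mse"])
def test_loocv_matches_refit_oracle(rng, n, k, metric):
    for _ in range(5):
        X = rng.normal(size=(n, k))
        y = rng.normal(size=n) * 100.0
        fast = loocv_error(X, y, metric)
        slow = _brute_force_loocv(X, y, metric)
        assert fast == pytest.approx(slow, rel=1e-9, abs=1e-9)


def test_loocv_permutation_invariant(rng):
    X = rng.normal(size=(15, 4))
    y = rng.normal(size=15)
    perm = rng.permutation(15)
    assert loocv_error(X, y) == pytest.approx(loocv_error(X[perm], y[perm]), rel=1e-10)


def test_loocv_rank_deficient_scores_infinity(rng):
    x = rng.normal(size=12)
    X = np.column_stack([x, 2 * x])
    assert loocv_error(X, rng.normal(size=12)) == np.inf


# ------------------------------------------------------------ selection

def _feature_frame(rng, n=40, site="triceps"):
    grid = np.arange(850, 1091, 10)
    cols = {}
    for i, lo in enumerate(grid):
        for hi in grid[i + 1:]:
            cols[f"{site}_{lo}_{hi}"] = rng.normal(100.0, 1.0, size=n)
    return pd.DataFrame(cols)


def test_selection_finds_planted_linear_signal(rng):
    """Target linear in the 930/970 ratio must select exactly that feature."""
    F = _feature_frame(rng)
    cov = rng.normal(115.0, 10.0, size=len(F))
    y = 50.0 * F["triceps_930_970"].to_numpy() + 30.0 * cov - 2000.0
    sel = select_features(F, y, covariate=cov)
    assert sel.site == "triceps"
    assert sel.ratio_1 == (930, 970)


def test_selection_single_informative_among_noise(rng):
    F = _feature_frame(rng, n=80)
    y = 20.0 * F["triceps_890_1050"].to_numpy() + rng.normal(0, 1e-6, size=80)
    sel = select_features(F, y, covariate=None)
    assert sel.ratio_1 == (890, 1050)


def test_selection_tie_breaks_lexicographically(rng):
    F = _feature_frame(rng, n=30)
    F["triceps_900_910"] = F["triceps_990_1000"]  # duplicate of an informative column
    y = 10.0 * F["triceps_990_1000"].to_numpy()
    sel = select_features(F, y, covariate=None)
    assert sel.ratio_1 == (900, 910)


# ------------------------------------------------------------ fit / predict

def test_fit_recovers_generating_coefficients(rng):
    F = _feature_frame(rng, n=60)
    cov = rng.normal(115.0, 10.0, size=60)
    y = -300.0 * F["triceps_930_970"].to_numpy() + 700.0 * F["triceps_950_960"].to_numpy() \
        + 36.0 * cov - 46000.0
    sel = select_features(F, y, covariate=cov)
    model = fit_model(F, y, sel, covariate=cov)
    assert model.site == "triceps"
    assert {model.ratio_1, model.ratio_2} == {(930, 970), (950, 960)}
    betas = {model.ratio_1: model.beta_1, model.ratio_2: model.beta_2}
    assert betas[(930, 970)] == pytest.approx(-300.0, abs=1e-5)
    assert betas[(950, 960)] == pytest.approx(700.0, abs=1e-5)
    assert model.beta_3 == pytest.approx(36.0, abs=1e-6)
    assert model.intercept == pytest.approx(-46000.0, abs=1e-3)


def test_training_residual_mean_zero(small_features, small_methods):
    X = small_features.loc[small_methods.index].assign(w_over_l=small_methods["w_over_l"])
    est = NirFatMassRegressor().fit(X, small_methods["fm_4c_g"])
    resid = small_methods["fm_4c_g"].to_numpy() - est.predict(X)
    assert abs(resid.mean()) < 1e-9 * np.abs(small_methods["fm_4c_g"]).mean()


def test_predict_published_style_coefficients():
    model = FittedNirModel(site="subscapular", ratio_1=(930, 970), ratio_2=(950, 960),
                           beta_1=-300.58, beta_2=742.77, beta_3=36.53,
                           intercept=-46818.48, covariate="w_over_l")
    feats = pd.DataFrame({"subscapular_930_970": [100.0], "subscapular_950_960": [100.0]})
    fm = predict_fm(model, feats, covariate=np.array([114.9]))
    expected = -300.58 * 100 + 742.77 * 100 + 36.53 * 114.9 - 46818.48
    assert fm[0] == pytest.approx(expected, abs=1e-9)
    assert fm[0] == pytest.approx(1598.0, abs=0.5)


def test_predict_is_linear(rng):
    model = FittedNirModel(site="flank", ratio_1=(900, 950), ratio_2=None,
                           beta_1=2.0, beta_2=0.0, beta_3=5.0, intercept=7.0,
                           covariate="w_over_l")
    f1 = pd.DataFrame({"flank_900_950": rng.normal(size=4)})
    f2 = pd.DataFrame({"flank_900_950": rng.normal(size=4)})
    c1, c2 = rng.normal(size=4), rng.normal(size=4)
    lhs = predict_fm(model, f1 + f2, c1 + c2)
    rhs = predict_fm(model, f1, c1) + predict_fm(model, f2, c2) - model.intercept
    np.testing.assert_allclose(lhs, rhs, rtol=1e-12)


def test_predict_missing_feature_named():
    model = FittedNirModel(site="flank", ratio_1=(900, 950), ratio_2=None,
                           beta_1=1.0, beta_2=0.0, beta_3=0.0, intercept=0.0, covariate=None)
    with pytest.raises(ModelDomainError, match="flank_900_950"):
        predict_fm(model, pd.DataFrame({"flank_900_960": [1.0]}))


def test_model_json_roundtrip(tmp_path):
    model = FittedNirModel(site="thigh", ratio_1=(930, 970), ratio_2=(950, 960),
                           beta_1=1.5, beta_2=-2.5, beta_3=3.5, intercept=-10.0,
                           covariate="weight_g", split_seed=5)
    path = tmp_path / "model.json"
    model.to_json(path)
    assert FittedNirModel.from_json(path) == model


def test_estimator_sklearn_protocol(rng):
    est = NirFatMassRegressor(covariate="weight_g", metric="mse")
    params = est.get_params()
    assert params["covariate"] == "weight_g" and params["metric"] == "mse"
    cloned = clone(est)
    assert cloned.get_params() == params
    with pytest.raises(ModelDomainError):
        NirFatMassRegressor().predict(pd.DataFrame({"w_over_l": [1.0]}))
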