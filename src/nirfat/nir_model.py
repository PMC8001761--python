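"""NIR fat-mass model: stratified split, LOOCV feature selection, OLS fit.

The model is a linear predictor of multi-compartment fat mass (g):

    FM = beta_1 * (R_1/R_2) + beta_2 * (R_3/R_4) + beta_3 * W/L + intercept

where R_i/R_j are wavelength-ratio features (percent) from a single scan
site and W/L is weight-for-length in g/cm (replaced by weight in g for the
no-length variant, or dropped entirely for a purely spectral model). Up to
two ratio features are chosen by greedy forward selection, scored by
leave-one-out cross-validated mean absolute error on the training set, the
second kept only if it strictly improves the score; the winning site is
the one whose final score is lowest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ModelDomainError, SelectionError
from .spectra import SITES, feature_name

__all__ = [
    "DEFAULT_AGE_BINS",
    "stratified_split",
    "loocv_error",
    "select_features",
    "fit_model",
    "predict_fm",
    "FittedNirModel",
    "NirFatMassRegressor",
]

#: stratification age bins: 3-6, 7-12, 13-24 months
DEFAULT_AGE_BINS = (3.0, 6.99, 12.99, 24.0)


# ---------------------------------------------------------------- splitting

def stratified_split(
    cohort: pd.DataFrame,
    train_fraction: float = 3 / 5,
    seed: int = 0,
    age_bins=DEFAULT_AGE_BINS,
) -> tuple[list, list]:
    """Age-bin x sex stratified train/test split of subject ids.

    Per-stratum allocation uses largest-remainder rounding of
    ``n_stratum * train_fraction`` against the rounded overall train total,
    so the train share is within one subject of the target in every stratum.
    Deterministic for a fixed seed. Strata with a single subject go to train
    with a warning.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ModelDomainError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    edges = np.asarray(age_bins, dtype=float)
    binned = np.digitize(cohort["age_months"].to_numpy(dtype=float), edges[1:-1], right=True)
    keys = list(zip(cohort["sex"].to_numpy(), binned))
    ids = cohort["subject_id"].to_numpy()

    strata: dict = {}
    for sid, key in zip(ids, keys):
        strata.setdefault(key, []).append(sid)

    train: list = []
    test: list = []
    small = {k: v for k, v in strata.items() if len(v) < 2}
    for key, members in small.items():
        warnings.warn(f"stratum {key} has {len(members)} subject(s); assigned to train",
                      stacklevel=2)
        train.extend(members)
    big = {k: v for k, v in sorted(strata.items()) if k not in small}
    quotas = {k: len(v) * train_fraction for k, v in big.items()}
    total_train = int(round(sum(quotas.values())))
    base = {k: int(np.floor(q)) for k, q in quotas.items()}
    leftover = total_train - sum(base.values())
    by_remainder = sorted(big, key=lambda k: (-(quotas[k] - base[k]), k))
    for k in by_remainder[:leftover]:
        base[k] += 1
    for key, members in big.items():
        members = list(members)
        perm = rng.permutation(len(members))
        n_train = min(base[key], len(members))
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return sorted(train), sorted(test)


# ---------------------------------------------------------------- LOOCV

def _design(columns: list[np.ndarray], n: int) -> np.ndarray:
    return np.column_stack(columns + [np.ones(n)])


def loocv_error(X: np.ndarray, y: np.ndarray, metric: str = "mae") -> float:
    """Leave-one-out cross-validated error of an OLS fit (intercept added).

    Uses the exact hat-matrix identity e_loo_i = e_i / (1 - h_ii), which
    equals refitting with subject i removed; rank-deficient designs (or any
    fold with leverage 1) score infinity so selection skips them.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ModelDomainError("LOOCV requires at least 3 training subjects")
    Xa = np.column_stack([X, np.ones(n)])
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        return np.inf
    P = np.linalg.pinv(Xa)
    beta = P @ y
    resid = y - Xa @ beta
    h = np.einsum("ij,ji->i", Xa, P)
    if np.any(h >= 1.0 - 1e-12):
        return np.inf
    loo = resid / (1.0 - h)
    if metric == "mae":
        return float(np.mean(np.abs(loo)))
    if metric == "mse":
        return float(np.mean(loo**2))
    raise ModelDomainError(f"unknown metric {metric!r}; use 'mae' or 'mse'")


# ---------------------------------------------------------------- selection

def _site_columns(features: pd.DataFrame, site: str) -> dict[tuple[int, int], str]:
    """Map (lo, hi) -> column name for one site, in lexicographic pair order."""
    prefix = site + "_"
    pairs = {}
    for col in features.columns:
        if not col.startswith(prefix):
            continue
        parts = col[len(prefix):].split("_")
        if len(parts) == 2 and all(p.isdigit() for p in parts):
            pairs[(int(parts[0]), int(parts[1]))] = col
    return dict(sorted(pairs.items()))


@dataclass
class _SiteSelection:
    site: str
    ratio_1: tuple
    ratio_2: tuple | None
    score: float


def select_features(
    features: pd.DataFrame,
    y: np.ndarray,
    covariate: np.ndarray | None = None,
    sites=SITES,
    metric: str = "mae",
    include_covariate_in_selection: bool = True,
    max_ratios: int = 2,
) -> _SiteSelection:
    """Greedy forward selection of up to two ratio features within one site.

    Round 1 scores each ratio (with the covariate alongside, by default);
    round 2 scores each remaining ratio added to the round-1 winner and is
    kept only on strict improvement. Ties break lexicographically by
    (numerator_nm, denominator_nm), then by site name; the winning site has
    the lowest final score.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    cov_cols = []
    if covariate is not None and include_covariate_in_selection:
        cov_cols = [np.asarray(covariate, dtype=float)]

    best: _SiteSelection | None = None
    for site in sorted(sites):
        pairs = _site_columns(features, site)
        if not pairs:
            continue
        r1, s1 = None, np.inf
        for pair, col in pairs.items():
            x = features[col].to_numpy(dtype=float)
            score = loocv_error(np.column_stack([x] + cov_cols), y, metric)
            if score < s1:
                r1, s1 = pair, score
        if r1 is None or not np.isfinite(s1):
            continue
        r2, s2 = None, s1
        if max_ratios >= 2:
            x1 = features[pairs[r1]].to_numpy(dtype=float)
            for pair, col in pairs.items():
                if pair == r1:
                    continue
                x = features[col].to_numpy(dtype=float)
                score = loocv_error(np.column_stack([x1, x] + cov_cols), y, metric)
                if score < s2:
                    r2, s2 = pair, score
        cand = _SiteSelection(site=site, ratio_1=r1, ratio_2=r2, score=s2)
        if best is None or cand.score < best.score:
            best = cand
    if best is None:
        raise SelectionError("no usable candidate features (all rank-deficient or missing)")
    return best


# ---------------------------------------------------------------- fitting

@dataclass
class FittedNirModel:
    """Selected wavelengths and OLS coefficients of the NIR fat-mass model."""

    site: str
    ratio_1: tuple
    ratio_2: tuple | None
    beta_1: float
    beta_2: float
    beta_3: float
    intercept: float
    covariate: str | None  # "w_over_l" (g/cm), "weight_g" (g) or None
    target: str = "4C"
    loocv_error_g: float | None = None
    split_seed: int | None = None

    @property
    def uses_length(self) -> bool:
        return self.covariate == "w_over_l"

    def feature_columns(self) -> list[str]:
        cols = [feature_name(self.site, *self.ratio_1)]
        if self.ratio_2 is not None:
            cols.append(feature_name(self.site, *self.ratio_2))
        return cols

    def to_json(self, path) -> None:
        d = asdict(self)
        d["ratio_1"] = list(d["ratio_1"])
        if d["ratio_2"] is not None:
            d["ratio_2"] = list(d["ratio_2"])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "FittedNirModel":
        with open(path) as fh:
            d = json.load(fh)
        d["ratio_1"] = tuple(d["ratio_1"])
        if d.get("ratio_2") is not None:
            d["ratio_2"] = tuple(d["ratio_2"])
        return cls(**d)


def fit_model(
    features: pd.DataFrame,
    y: np.ndarray,
    selection: _SiteSelection,
    covariate: np.ndarray | None = None,
    covariate_name: str | None = "w_over_l",
) -> FittedNirModel:
    """OLS of the 4C fat-mass target on the selected ratios and covariate.

    The design always carries an intercept, so training residuals have mean
    exactly zero (to floating point).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    cols = [features[feature_name(selection.site, *selection.ratio_1)].to_numpy(dtype=float)]
    if selection.ratio_2 is not None:
        cols.append(features[feature_name(selection.site, *selection.ratio_2)].to_numpy(dtype=float))
    if covariate is not None:
        cols.append(np.asarray(covariate, dtype=float))
    Xa = _design(cols, n)
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise ModelDomainError("rank-deficient design in final fit")
    beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    k = 0
    b1 = float(beta[k]); k += 1
    b2 = float(beta[k]) if selection.ratio_2 is not None else 0.0
    if selection.ratio_2 is not None:
        k += 1
    b3 = float(beta[k]) if covariate is not None else 0.0
    if covariate is not None:
        k += 1
    return FittedNirModel(
        site=selection.site,
        ratio_1=selection.ratio_1,
        ratio_2=selection.ratio_2,
        beta_1=b1,
        beta_2=b2,
        beta_3=b3,
        intercept=float(beta[k]),
        covariate=covariate_name if covariate is not None else None,
        loocv_error_g=selection.score,
    )


def predict_fm(model: FittedNirModel, features: pd.DataFrame,
               covariate: np.ndarray | None = None) -> np.ndarray:
    """Fat mass (g) from a fitted model; linear in its inputs."""
    for col in model.feature_columns():
        if col not in features.columns:
            raise ModelDomainError(f"missing feature column {col!r}")
    out = model.beta_1 * features[model.feature_columns()[0]].to_numpy(dtype=float)
    if model.ratio_2 is not None:
        out = out + model.beta_2 * features[model.feature_columns()[1]].to_numpy(dtype=float)
    if model.covariate is not None:
        if covariate is None:
            raise ModelDomainError(f"model requires covariate {model.covariate!r}")
        out = out + model.beta_3 * np.asarray(covariate, dtype=float)
    return out + model.intercept


# ---------------------------------------------------------------- estimator

class NirFatMassRegressor(BaseEstimator, RegressorMixin):
    """sklearn-style estimator wrapping selection + OLS fit.

    Parameters
    ----------
    covariate : {"w_over_l", "weight_g", None}
        Anthropometric covariate column expected in X: weight-for-length in
        g/cm (the with-length model), bare weight in g (the no-length
        variant), or None for a purely spectral model.
    metric : {"mae", "mse"}
        LOOCV selection score.
    include_covariate_in_selection : bool
        Whether the covariate sits in the design while ratios are scored.
    max_ratios : int
        Maximum number of ratio terms (the model uses at most two).
    sites : tuple of str
        Candidate scan sites.

    ``X`` is a DataFrame holding ratio-feature columns named
    ``{site}_{lo}_{hi}`` plus the covariate column; ``y`` is 4C fat mass in
    grams. Fitted attributes: ``model_``, ``site_``, ``ratio_1_``,
    ``ratio_2_``, ``coef_``, ``intercept_``, ``loocv_error_``.
    """

    def __init__(self, covariate="w_over_l", metric="mae",
                 include_covariate_in_selection=True, max_ratios=2, sites=SITES):
        self.covariate = covariate
        self.metric = metric
        self.include_covariate_in_selection = include_covariate_in_selection
        self.max_ratios = max_ratios
        self.sites = sites

    def _cov(self, X: pd.DataFrame):
        if self.covariate is None:
            return None
        if self.covariate not in X.columns:
            raise ModelDomainError(f"covariate column {self.covariate!r} missing from X")
        return X[self.covariate].to_numpy(dtype=float)

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise ModelDomainError("X must be a DataFrame of named ratio-feature columns")
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ModelDomainError("X and y lengths differ")
        cov = self._cov(X)
        selection = select_features(
            X, y, covariate=cov, sites=self.sites, metric=self.metric,
            include_covariate_in_selection=self.include_covariate_in_selection,
            max_ratios=self.max_ratios,
        )
        self.model_ = fit_model(X, y, selection, covariate=cov, covariate_name=self.covariate)
        self.site_ = self.model_.site
        self.ratio_1_ = self.model_.ratio_1
        self.ratio_2_ = self.model_.ratio_2
        self.coef_ = np.array([self.model_.beta_1, self.model_.beta_2, self.model_.beta_3])
        self.intercept_ = self.model_.intercept
        self.loocv_error_ = selection.score
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ModelDomainError("estimator is not fitted")
        return predict_fm(self.model_, X, covariate=self._cov(X))
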