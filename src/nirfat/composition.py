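"""Body-composition models: multi-compartment reference and comparators.

The reference fat-mass estimate for infants aged 3-24 months is a mass-based
multi-compartment model that combines total body water (TBW, by deuterium
dilution), bone mineral content (BMC, by DXA) and total body potassium per kg
fat-free mass (TBK_FFM, predicted from age/sex polynomials because potassium
counting is rarely available):

    FFM (kg) = (1009.4108 * TBW + 1000 * BMC) / (994 - 2.87851 * TBK_FFM)
    FM  (g)  = weight_g - 1000 * FFM

Comparator predictors implemented here: deuterium-dilution FFM via hydration
factors, Slaughter skinfold body-fat percentage, and anthropometric indices
(BMI, weight/length, MUAC, empirical within-cohort percentiles).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ModelDomainError

__all__ = [
    "tbk_per_kg_ffm",
    "ffm_4c",
    "fat_mass_from_ffm",
    "HydrationTable",
    "DEFAULT_HYDRATION_TABLE",
    "ffm_dd",
    "slaughter_bf_pct",
    "anthropometric_indices",
    "fm_4c_from_summaries",
]

# cubic TBK (mEq/kg FFM) coefficients in age (months), highest power last
_TBK_COEF = {
    "male": (49.108, 1.1047, -0.0505, 0.0009),
    "female": (49.113, 1.2957, -0.0629, 0.0011),
}

METHODS = ("4C", "DD", "DXA", "NIR", "NIR_noL", "SFT", "BMI", "W/L", "W/A", "L/A", "MUAC")


def tbk_per_kg_ffm(age_months, sex: str):
    """Total body potassium per kg FFM (mEq/kg) from the sex-specific cubic.

    Valid for ages 0-24 months (the domain of the underlying polynomial fit).
    """
    if sex not in _TBK_COEF:
        raise ModelDomainError(f"sex must be 'male' or 'female', got {sex!r}")
    age = np.asarray(age_months, dtype=float)
    if np.any(age < 0) or np.any(age > 24):
        raise ModelDomainError("age_months outside the polynomial fit domain [0, 24]")
    c0, c1, c2, c3 = _TBK_COEF[sex]
    out = c0 + c1 * age + c2 * age**2 + c3 * age**3
    return float(out) if np.isscalar(age_months) else out


def ffm_4c(tbw_kg, bmc_kg, tbk_meq_per_kg):
    """Fat-free mass (kg) from the mass-based multi-compartment model.

    FFM = (1009.4108*TBW + 1000*BMC) / (994 - 2.87851*TBK_FFM), all masses kg.
    """
    tbw = np.asarray(tbw_kg, dtype=float)
    bmc = np.asarray(bmc_kg, dtype=float)
    tbk = np.asarray(tbk_meq_per_kg, dtype=float)
    denom = 994.0 - 2.87851 * tbk
    if np.any(denom <= 0):
        raise ModelDomainError("nonpositive denominator: TBK_FFM too large for the model")
    out = (1009.4108 * tbw + 1000.0 * bmc) / denom
    if all(np.isscalar(x) for x in (tbw_kg, bmc_kg, tbk_meq_per_kg)):
        return float(out)
    return out


def fat_mass_from_ffm(weight_g, ffm_kg):
    """FM (g) = weight (g) - 1000*FFM (kg); negative values are allowed
    (flagged downstream, not clipped, so QC can see them)."""
    return np.asarray(weight_g, dtype=float) - 1000.0 * np.asarray(ffm_kg, dtype=float)


class HydrationTable:
    """Age/sex-specific TBW-to-FFM hydration fractions, linearly interpolated.

    The study's own hydration factors are not published; this default declines
    from 0.81 at 3 months to 0.78 at 24 months with a +/-0.002 sex offset
    (male positive), which spans the range reported for infancy. The table is
    configurable wherever it is consumed.
    """

    def __init__(self, ages_months=(3.0, 24.0), fractions=(0.81, 0.78), sex_offset=0.002):
        self.ages_months = np.asarray(ages_months, dtype=float)
        self.fractions = np.asarray(fractions, dtype=float)
        if self.ages_months.shape != self.fractions.shape or self.ages_months.size < 1:
            raise ModelDomainError("hydration table: ages and fractions must align")
        self.sex_offset = float(sex_offset)

    def __call__(self, age_months, sex):
        age = np.asarray(age_months, dtype=float)
        lo, hi = self.ages_months[0], self.ages_months[-1]
        if np.any(age < lo) or np.any(age > hi):
            raise ModelDomainError(
                f"age_months outside hydration table domain [{lo}, {hi}]"
            )
        base = np.interp(age, self.ages_months, self.fractions)
        if isinstance(sex, str):
            off = self.sex_offset if sex == "male" else -self.sex_offset
        else:
            off = np.where(np.asarray(sex) == "male", self.sex_offset, -self.sex_offset)
        out = base + off
        return float(out) if np.isscalar(age_months) and isinstance(sex, str) else out


DEFAULT_HYDRATION_TABLE = HydrationTable()


def ffm_dd(tbw_kg, age_months, sex, hydration_table: HydrationTable = DEFAULT_HYDRATION_TABLE):
    """Deuterium-dilution FFM (kg): TBW divided by the hydration fraction."""
    h = hydration_table(age_months, sex)
    out = np.asarray(tbw_kg, dtype=float) / h
    return float(out) if np.isscalar(tbw_kg) and np.isscalar(h) else out


def slaughter_bf_pct(subscapular_mm, triceps_mm, sex: str):
    """Body-fat percent from the Slaughter skinfold quadratics.

    ``s`` is the sum of subscapular and triceps skinfolds in mm:
    male   BF% = 1.21*s - 0.008*s^2 - 1.7
    female BF% = 1.33*s - 0.013*s^2 - 2.5
    Values below ~10% are physiologically implausible in this age range and
    are returned as-is with a warning rather than clipped.
    """
    if sex not in ("male", "female"):
        raise ModelDomainError(f"sex must be 'male' or 'female', got {sex!r}")
    s = np.asarray(subscapular_mm, dtype=float) + np.asarray(triceps_mm, dtype=float)
    if sex == "male":
        bf = 1.21 * s - 0.008 * s**2 - 1.7
    else:
        bf = 1.33 * s - 0.013 * s**2 - 2.5
    if np.any(np.asarray(bf) < 0):
        warnings.warn("Slaughter BF% below 0: below-physiological input", stacklevel=2)
    return float(bf) if np.isscalar(subscapular_mm) else bf


def _empirical_percentile(values: np.ndarray) -> np.ndarray:
    """rank/(n+1) percentile in percent, average ranks for ties."""
    r = rankdata(values, method="average")
    return 100.0 * r / (len(values) + 1)


def anthropometric_indices(
    cohort: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    age_bins=(3.0, 6.99, 12.99, 24.0),
) -> pd.DataFrame:
    """BMI, weight/length and empirical percentile indices per subject.

    Percentiles for weight-for-age (W/A), length-for-age (L/A) and
    weight-for-length (W/L) are empirical rank/(n+1) percentiles within
    sex x age-bin strata of ``reference`` (default: the cohort itself),
    standing in for external growth-chart references. Empty strata yield
    NaN with a warning.
    """
    ref = cohort if reference is None else reference
    if np.any(cohort["weight_g"].to_numpy() <= 0) or np.any(cohort["length_cm"].to_numpy() <= 0):
        raise ModelDomainError("weight_g and length_cm must be positive")

    out = pd.DataFrame(index=cohort.index)
    out["subject_id"] = cohort["subject_id"].to_numpy()
    w = cohort["weight_g"].to_numpy(dtype=float)
    length = cohort["length_cm"].to_numpy(dtype=float)
    out["bmi"] = (w / 1000.0) / (length / 100.0) ** 2
    out["w_over_l"] = w / length
    out["muac_cm"] = cohort["muac_cm"].to_numpy(dtype=float)

    edges = np.asarray(age_bins, dtype=float)

    def stratum_key(df):
        binned = np.digitize(df["age_months"].to_numpy(dtype=float), edges[1:-1], right=True)
        return list(zip(df["sex"].to_numpy(), binned))

    ref_keys = stratum_key(ref)
    coh_keys = stratum_key(cohort)
    ref_wl = ref["weight_g"].to_numpy(dtype=float) / ref["length_cm"].to_numpy(dtype=float)
    coh_wl = out["w_over_l"].to_numpy()

    specs = {
        "pct_w_a": (ref["weight_g"].to_numpy(dtype=float), w),
        "pct_l_a": (ref["length_cm"].to_numpy(dtype=float), length),
        "pct_w_l": (ref_wl, coh_wl),
    }
    for col, (ref_vals, coh_vals) in specs.items():
        pct = np.full(len(cohort), np.nan)
        for key in set(coh_keys):
            in_ref = np.array([k == key for k in ref_keys])
            in_coh = np.array([k == key for k in coh_keys])
            if not in_ref.any():
                warnings.warn(f"empty reference stratum {key}: percentile undefined", stacklevel=2)
                continue
            if reference is None:
                # the cohort is its own reference pool
                pct[in_coh] = _empirical_percentile(coh_vals[in_coh])
            else:
                # rank each subject within the reference stratum pool + itself
                pool = ref_vals[in_ref]
                for i in np.flatnonzero(in_coh):
                    joint = np.concatenate([pool, [coh_vals[i]]])
                    pct[i] = _empirical_percentile(joint)[-1]
        out[col] = pct
    return out


def fm_4c_from_summaries(group_label: str, male_fraction: float | None = None) -> float:
    """4C fat mass (g) implied by a group's published mean TBW, BMC, weight
    and age, with TBK averaged over sexes — a consistency check of the
    multi-compartment reading against the printed group fat-mass means."""
    from .reference_data import COHORT_SUMMARIES, MALE_FRACTION

    tbw = COHORT_SUMMARIES["tbw_kg"][group_label][0]
    bmc = COHORT_SUMMARIES["bmc_kg"][group_label][0]
    weight = COHORT_SUMMARIES["weight_g"][group_label][0]
    age = COHORT_SUMMARIES["age_months"][group_label][0]
    frac_m = MALE_FRACTION[group_label] if male_fraction is None else male_fraction
    tbk = frac_m * tbk_per_kg_ffm(age, "male") + (1 - frac_m) * tbk_per_kg_ffm(age, "female")
    return float(fat_mass_from_ffm(weight, ffm_4c(tbw, bmc, tbk)))
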