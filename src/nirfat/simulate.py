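"""Synthetic infant cohorts with the statistical structure the analysis assumes.

The study data are not publicly available, so this module generates cohorts
whose anthropometry, body composition, deuterium-dilution records and NIR
spectra reproduce the published group summary statistics (two age groups,
3-6 and 7-24 months, mixed 105:59) and the fat/water absorption structure
at 930/970 nm that the downstream feature selection must recover.

Generative model, per subject:

* age from the 105:59 mixture of U(3,6) and U(7,24) months; sex Bernoulli;
* weight truncated-normal at the group target; length correlated with weight;
* body-fat fraction truncated-normal on [0.15, 0.40] at the group target
  (variance chosen so fat mass reproduces the target SD), fat mass = bf x
  weight, FFM the remainder (mass closure is exact by construction);
* TBW = hydration(age, sex) x FFM; BMC correlated with weight;
* deuterium record: ~1 g dose, basal ~U(0.5,3) mg/kg, two post-dose samples
  at the true plateau with 0.5% relative noise. A ``qc_failure_rate``
  fraction of subjects is planted with a failure: dribble loss multiplies
  the true enrichment by U(0.50, 0.65) (raising apparent TBW), basal
  contamination adds U(12, 30) mg/kg to the basal sample;
* spectra: constant per-scan baseline times (1 - d_fat*Gauss(930, sigma)
  - d_water*Gauss(970, sigma)) plus Gaussian reflectance noise, emitted as
  raw/dark/light intensity triples that calibrate back to this reflectance.
  d_fat grows with site-local adiposity (subject BF x site skinfold),
  d_water with the TBW fraction of body weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .composition import DEFAULT_HYDRATION_TABLE, HydrationTable
from .errors import ConfigurationError, ModelDomainError
from .reference_data import COHORT_SUMMARIES, GROUP_N, MALE_FRACTION
from .spectra import SITES, SpectralScan

__all__ = ["GeneratorConfig", "TrueComposition", "SyntheticCohort", "generate_cohort",
           "spectral_forward_model"]

_GROUPS = ("3-6", "7-24")
_SKINFOLD_VARS = {s: f"{s}_mm" for s in SITES}
# all-subject skinfold target means, used to normalise site-local adiposity
_SITE_MEAN_MM = {s: COHORT_SUMMARIES[f"{s}_mm"]["3-24"][0] for s in SITES}


def _default_targets() -> dict:
    vars_needed = ["weight_g", "length_cm", "fm_4c_g", "bmc_kg", "muac_cm"] + [
        f"{s}_mm" for s in SITES
    ]
    return {g: {v: COHORT_SUMMARIES[v][g] for v in vars_needed} for g in _GROUPS}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort generator."""

    n_subjects: int = 164
    seed: int = 0
    age_range_months: tuple = (3.0, 24.0)
    sex_ratio_male: float = MALE_FRACTION["3-24"]
    #: {group: {variable: (mean, sd)}} for groups "3-6" and "7-24"
    table1_targets: dict = field(default_factory=_default_targets)
    young_group_weight: float = GROUP_N["3-6"] / GROUP_N["3-24"]
    spectral_noise_sd: float = 1.0  # reflectance-percent units
    band_fat_nm: float = 930.0
    band_water_nm: float = 970.0
    band_sigma_nm: float = 15.0
    fat_depth_gain: float = 0.6
    water_depth_base: float = 0.10
    water_depth_gain: float = 0.5
    #: relative SD of per-subject-and-site tissue variation in band depths
    #: (superficial tissue composition only approximates whole-body values)
    fat_depth_jitter: float = 0.095
    water_depth_jitter: float = 0.030
    qc_failure_rate: float = 0.05
    n_replicates: int = 2
    wavelength_start_nm: float = 350.0
    wavelength_stop_nm: float = 1100.0
    wavelength_step_nm: float = 1.0
    bf_fraction_bounds: tuple = (0.15, 0.40)
    hydration_table: HydrationTable = field(default_factory=lambda: DEFAULT_HYDRATION_TABLE)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not (0.0 <= self.sex_ratio_male <= 1.0):
            raise ConfigurationError("sex_ratio_male must be in [0, 1]")
        if not (0.0 <= self.qc_failure_rate < 1.0):
            raise ConfigurationError("qc_failure_rate must be in [0, 1)")
        for name in ("band_fat_nm", "band_water_nm"):
            v = getattr(self, name)
            if not (850.0 <= v <= 1090.0):
                raise ConfigurationError(f"{name} must lie within the 850-1090 nm grid")
        if self.spectral_noise_sd < 0:
            raise ConfigurationError("spectral_noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        lo, hi = self.age_range_months
        if not (0 <= lo < hi <= 30):
            raise ConfigurationError("age_range_months must be an increasing pair in [0, 30]")

    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wavelength_start_nm, self.wavelength_stop_nm + 1e-9,
                         self.wavelength_step_nm)


@dataclass(frozen=True)
class TrueComposition:
    """Latent body composition of a generated subject."""

    ffm_kg: float
    fm_g: float
    tbw_kg: float
    bmc_kg: float
    hydration_fraction: float

    def __post_init__(self) -> None:
        weight_g = self.ffm_kg * 1000.0 + self.fm_g
        if abs(self.tbw_kg - self.hydration_fraction * self.ffm_kg) > 1e-6 * max(1.0, self.tbw_kg):
            raise ModelDomainError("tbw_kg must equal hydration_fraction * ffm_kg")
        if not (0.70 <= self.hydration_fraction <= 0.85):
            raise ModelDomainError("hydration_fraction outside [0.70, 0.85]")
        if weight_g <= 0:
            raise ModelDomainError("implied weight must be positive")

    @property
    def weight_g(self) -> float:
        return self.ffm_kg * 1000.0 + self.fm_g

    @property
    def bf_pct(self) -> float:
        return 100.0 * self.fm_g / self.weight_g


@dataclass
class SyntheticCohort:
    """Generated cohort: observed table, latent truth, optional spectra."""

    cohort: pd.DataFrame
    truth: pd.DataFrame
    spectra: pd.DataFrame | None
    config: GeneratorConfig

    @property
    def planted_failure_counts(self) -> dict:
        vc = self.truth["planted_failure"].value_counts().to_dict()
        return {k: int(vc.get(k, 0)) for k in ("none", "dribble", "basal")}

    def write(self, out_dir, write_spectra: bool = True) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cohort.to_csv(out / "cohort.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        if write_spectra and self.spectra is not None:
            self.spectra.to_csv(out / "spectra.csv", index=False, float_format="%.6f")


def _trunc(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _dark_and_headroom(wl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dark = 1200.0 + 0.05 * (wl - 350.0)
    headroom = 28000.0 * (1.0 - 0.3 * ((wl - 725.0) / 375.0) ** 2)
    return dark, headroom


def _depths(true_comp: TrueComposition, site: str, site_skinfold_mm, config: GeneratorConfig,
            jitter_fat: float = 0.0, jitter_water: float = 0.0):
    """Absorption depths at the fat and water bands for one subject x site.

    ``jitter_*`` are realised relative deviations of the superficial-tissue
    depths from the whole-body-driven values (0 = deterministic)."""
    bf = true_comp.fm_g / true_comp.weight_g
    sk = _SITE_MEAN_MM[site] if site_skinfold_mm is None else float(site_skinfold_mm)
    # site-local adiposity: subject BF modulated (damped) by the site skinfold
    site_adiposity = bf * (0.9 + 0.1 * sk / _SITE_MEAN_MM[site])
    d_fat = config.fat_depth_gain * site_adiposity * (1.0 + jitter_fat)
    tbw_frac = true_comp.tbw_kg * 1000.0 / true_comp.weight_g
    d_water = (config.water_depth_base + config.water_depth_gain * tbw_frac) * (1.0 + jitter_water)
    return d_fat, d_water


def _scan_reflectance(wl, d_fat, d_water, baseline, config: GeneratorConfig):
    g_fat = np.exp(-((wl - config.band_fat_nm) ** 2) / (2 * config.band_sigma_nm**2))
    g_water = np.exp(-((wl - config.band_water_nm) ** 2) / (2 * config.band_sigma_nm**2))
    return baseline * (1.0 - d_fat * g_fat - d_water * g_water)


def spectral_forward_model(
    true_comp: TrueComposition,
    site: str,
    noise_sd: float = 0.0,
    seed: int | None = None,
    site_skinfold_mm: float | None = None,
    config: GeneratorConfig | None = None,
    subject_id: str = "synthetic",
    d_fat: float | None = None,
    d_water: float | None = None,
    rng: np.random.Generator | None = None,
) -> SpectralScan:
    """Forward-simulate one raw NIR scan (with references) for one site.

    Absorption depths are derived from the latent composition unless given
    explicitly (``d_fat``/``d_water`` overrides support degenerate cases in
    tests). The returned raw/dark/light triples calibrate back to the model
    reflectance exactly when ``noise_sd`` is zero.
    """
    if site not in SITES:
        raise ModelDomainError(f"unknown site {site!r}; expected one of {SITES}")
    config = config or GeneratorConfig()
    rng = rng if rng is not None else np.random.default_rng(seed)
    wl = config.wavelengths()
    df, dw = _depths(true_comp, site, site_skinfold_mm, config)
    if d_fat is not None:
        df = d_fat
    if d_water is not None:
        dw = d_water
    baseline = rng.uniform(72.0, 78.0)
    refl = _scan_reflectance(wl, df, dw, baseline, config)
    if noise_sd > 0:
        refl = refl + rng.normal(0.0, noise_sd, size=wl.size)
    dark, headroom = _dark_and_headroom(wl)
    raw = dark + refl / 100.0 * headroom
    return SpectralScan(subject_id=subject_id, site=site, wavelengths=wl,
                        raw=raw, dark=dark, light=dark + headroom)


def _bf_sd(targets: dict, group: str) -> float:
    mu_w, sd_w = targets[group]["weight_g"]
    mu_fm, sd_fm = targets[group]["fm_4c_g"]
    bf_mean = mu_fm / mu_w
    resid_var = max(sd_fm**2 - (bf_mean * sd_w) ** 2, (0.02 * mu_w) ** 2)
    return np.sqrt(resid_var) / mu_w


def generate_cohort(config: GeneratorConfig, include_spectra: bool = True) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    targets = config.table1_targets

    young = rng.random(n) < config.young_group_weight
    lo_age, hi_age = config.age_range_months
    age = np.where(
        young,
        rng.uniform(max(3.0, lo_age), min(6.0, hi_age), size=n),
        rng.uniform(max(7.0, lo_age), min(24.0, hi_age), size=n),
    )
    sex = np.where(rng.random(n) < config.sex_ratio_male, "male", "female")
    group = np.where(young, "3-6", "7-24")

    def per_group(var):
        mu = np.where(young, targets["3-6"][var][0], targets["7-24"][var][0])
        sd = np.where(young, targets["3-6"][var][1], targets["7-24"][var][1])
        return mu, sd

    mu_w, sd_w = per_group("weight_g")
    weight = _trunc(rng, mu_w, sd_w, 2500.0, mu_w + 4 * sd_w, n)
    z_w = (weight - mu_w) / sd_w

    mu_l, sd_l = per_group("length_cm")
    length = np.maximum(mu_l + sd_l * (0.8 * z_w + 0.6 * rng.standard_normal(n)), 45.0)

    bf_mean = np.where(
        young,
        targets["3-6"]["fm_4c_g"][0] / targets["3-6"]["weight_g"][0],
        targets["7-24"]["fm_4c_g"][0] / targets["7-24"]["weight_g"][0],
    )
    bf_sd = np.where(young, _bf_sd(targets, "3-6"), _bf_sd(targets, "7-24"))
    blo, bhi = config.bf_fraction_bounds
    bf = _trunc(rng, bf_mean, bf_sd, blo, bhi, n)
    z_b = (bf - bf_mean) / bf_sd

    fm = bf * weight
    ffm_kg = (weight - fm) / 1000.0
    hydration = config.hydration_table(age, sex)
    tbw = hydration * ffm_kg

    mu_b, sd_b = per_group("bmc_kg")
    bmc = np.maximum(mu_b + sd_b * (0.7 * z_w + np.sqrt(1 - 0.49) * rng.standard_normal(n)), 0.02)

    skinfolds = {}
    for site in SITES:
        mu_s, sd_s = per_group(_SKINFOLD_VARS[site])
        skinfolds[site] = np.maximum(
            mu_s + sd_s * (0.6 * z_b + 0.8 * rng.standard_normal(n)), 2.0
        )

    mu_m, sd_m = per_group("muac_cm")
    muac = np.maximum(
        mu_m + sd_m * (0.5 * z_w + 0.4 * z_b + np.sqrt(1 - 0.41) * rng.standard_normal(n)), 8.0
    )

    dxa = np.maximum(fm + rng.normal(25.0, 650.0, size=n), 100.0)

    # deuterium-dilution records with planted QC failures
    dose = np.clip(rng.normal(1.0, 0.02, size=n), 0.9, 1.1)
    dilution_space = tbw * 1.041
    plateau_true = dose * 1000.0 / dilution_space
    basal_true = rng.uniform(0.5, 3.0, size=n)

    planted = np.full(n, "none", dtype=object)
    fail = rng.random(n) < config.qc_failure_rate
    mechanism = rng.random(n) < 0.5
    planted[fail & mechanism] = "dribble"
    planted[fail & ~mechanism] = "basal"

    dribble_factor = rng.uniform(0.50, 0.65, size=n)
    plateau_meas = np.where(planted == "dribble", plateau_true * dribble_factor, plateau_true)
    delta = rng.normal(0.0, 0.005, size=(2, n))
    post1 = basal_true + plateau_meas * (1.0 + delta[0])
    post2 = basal_true + plateau_meas * (1.0 + delta[1])
    basal_offset = rng.uniform(12.0, 30.0, size=n)
    basal_meas = np.maximum(basal_true + rng.normal(0.0, 0.2, size=n), 0.0)
    basal_meas = np.where(planted == "basal", basal_true + basal_offset, basal_meas)

    subject_id = np.array([f"S{i:04d}" for i in range(n)])
    cohort = pd.DataFrame(
        {
            "subject_id": subject_id,
            "age_months": age,
            "sex": sex,
            "group": group,
            "weight_g": weight,
            "length_cm": length,
            "muac_cm": muac,
            "triceps_mm": skinfolds["triceps"],
            "subscapular_mm": skinfolds["subscapular"],
            "thigh_mm": skinfolds["thigh"],
            "flank_mm": skinfolds["flank"],
            "bmc_kg": bmc,
            "dxa_adipose_g": dxa,
            "dose_g": dose,
            "basal_mg_kg": basal_meas,
            "post1_mg_kg": post1,
            "post2_mg_kg": post2,
        }
    )
    truth = pd.DataFrame(
        {
            "subject_id": subject_id,
            "ffm_kg": ffm_kg,
            "fm_g": fm,
            "tbw_kg": tbw,
            "bmc_kg": bmc,
            "hydration_fraction": hydration,
            "bf_pct": 100.0 * bf,
            "planted_failure": planted,
        }
    )

    spectra = _generate_spectra(cohort, truth, config, rng) if include_spectra else None
    return SyntheticCohort(cohort=cohort, truth=truth, spectra=spectra, config=config)


def _generate_spectra(cohort: pd.DataFrame, truth: pd.DataFrame,
                      config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    wl = config.wavelengths()
    m = wl.size
    n = len(cohort)
    n_scans = n * len(SITES) * config.n_replicates
    raw = np.empty(n_scans * m)
    sid_codes = np.empty(n_scans, dtype=np.int32)
    site_codes = np.empty(n_scans, dtype=np.int8)
    reps = np.empty(n_scans, dtype=np.int8)
    dark, headroom = _dark_and_headroom(wl)

    scan = 0
    for i in range(n):
        tc = TrueComposition(
            ffm_kg=truth["ffm_kg"].iat[i],
            fm_g=truth["fm_g"].iat[i],
            tbw_kg=truth["tbw_kg"].iat[i],
            bmc_kg=truth["bmc_kg"].iat[i],
            hydration_fraction=truth["hydration_fraction"].iat[i],
        )
        for s_idx, site in enumerate(SITES):
            # replicates probe the same tissue, so they share the jitter
            d_fat, d_water = _depths(
                tc, site, cohort[f"{site}_mm"].iat[i], config,
                jitter_fat=config.fat_depth_jitter * rng.standard_normal(),
                jitter_water=config.water_depth_jitter * rng.standard_normal(),
            )
            for rep in range(config.n_replicates):
                baseline = rng.uniform(72.0, 78.0)
                refl = _scan_reflectance(wl, d_fat, d_water, baseline, config)
                if config.spectral_noise_sd > 0:
                    refl = refl + rng.normal(0.0, config.spectral_noise_sd, size=m)
                raw[scan * m : (scan + 1) * m] = dark + refl / 100.0 * headroom
                sid_codes[scan] = i
                site_codes[scan] = s_idx
                reps[scan] = rep
                scan += 1

    sids = cohort["subject_id"].to_numpy()
    return pd.DataFrame(
        {
            "subject_id": pd.Categorical.from_codes(np.repeat(sid_codes, m), categories=list(sids)),
            "site": pd.Categorical.from_codes(np.repeat(site_codes, m), categories=list(SITES)),
            "replicate": np.repeat(reps, m),
            "wavelength_nm": np.tile(wl, n_scans),
            "raw": raw,
            "dark": np.tile(dark, n_scans),
            "light": np.tile(dark + headroom, n_scans),
        }
    )
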