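# Methods

This note documents the models, the synthetic-data generator, the numerical
conventions and the open design choices made in `nirfat`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Reference body-composition model

The criterion fat-mass estimate is a mass-based multi-compartment model
combining total body water (TBW, kg, by deuterium dilution), bone mineral
content (BMC, kg, by DXA) and total body potassium per kg fat-free mass
(TBK_FFM, mEq/kg):

```
FFM (kg) = (1009.4108 · TBW + 1000 · BMC) / (994 − 2.87851 · TBK_FFM)
FM  (g)  = weight − 1000 · FFM
BF%      = 100 · FM / weight
```

The equation is deliberately parsed as a single ratio — numerator
`1009.4108·TBW + 1000·BMC`, denominator `994 − 2.87851·TBK_FFM` — because
that is the only algebraic reading that reproduces the published group
fat-mass means from the same table's TBW, BMC and weight columns (the
cross-check in `fm_4c_from_summaries` lands within 5 % of all three printed
group means; see `tests/test_acceptance.py`). Because potassium counting is
not generally available for infants, TBK_FFM is predicted from sex-specific
cubic polynomials in age (months), valid on 0–24 months:

```
male:   TBK = 0.0009·mo³ − 0.0505·mo² + 1.1047·mo + 49.108
female: TBK = 0.0011·mo³ − 0.0629·mo² + 1.2957·mo + 49.113
```

Negative fat masses are returned (and flagged downstream), never clipped:
they are a QC signal, not a numerical artifact.

Two published-table readings are adopted and validated numerically rather
than taken at face value: skinfold columns labelled "(cm)" are treated as
mm (a 9.3 cm infant subscapular skinfold is anatomically impossible, and
the Slaughter equations are defined in mm), and the "bone mineral density"
column is treated as BMC in kg (the only unit consistent with the
multi-compartment equation and the cross-check above).

## Comparator predictors

* **Deuterium dilution (DD)**: `FFM = TBW / h(age, sex)`. The study's own
  hydration factors are unpublished; the default table interpolates
  linearly from 0.81 at 3 months to 0.78 at 24 months with a ±0.002 sex
  offset (male positive), spanning the range reported for infancy. The
  table is a constructor argument everywhere it is used and is therefore
  non-authoritative by design.
* **DXA**: the measured adipose-tissue mass is passed through untransformed.
* **Skinfolds (SFT)**: Slaughter quadratics on the sum of subscapular and
  triceps skinfolds (mm); BF % × weight gives grams. Below-physiological
  outputs are returned as-is with a warning.
* **Anthropometric indices**: BMI (kg/m²), weight/length (g/cm), MUAC (cm),
  and empirical percentiles for weight-for-age, length-for-age and
  weight-for-length. External growth-chart references (WHO/INTERGROWTH) are
  deliberately out of scope; percentiles are computed within the cohort as
  rank/(n+1) (average ranks for ties) inside sex × age-bin strata
  (bins 3–6, 7–12, 13–24 months). These are *relative* standings within the
  analysed cohort, not population percentiles.

## Deuterium-dilution QC

TBW is computed as `dose (mg) / plateau enrichment (mg/kg) / 1.041`, where
the plateau is the mean of the two post-dose saliva enrichments minus the
basal enrichment, and 1.041 is the configurable non-aqueous hydrogen
exchange correction. A record is rejected if any of the following hold
(all violated rules are reported):

* TBW outside 45–70 % of body weight — bounds **inclusive** (a "within
  45–70 %" reading, made explicit for bit-reproducibility);
* deuterium-derived BF % below 10 %;
* basal enrichment above 10 mg/kg (default; the underlying check is stated
  in the protocol, the numeric threshold is ours);
* the two post-dose samples differing by more than 5 % relative (same
  status: stated check, configurable default tolerance).

The filter is record-wise, hence idempotent and order-independent.

## Spectral processing

Reflectance is `100·(raw − dark)/(light − dark)` per wavelength; duplicate
scans of a subject × site are averaged *after* calibration, mirroring the
duplicate-measurement protocol. The analysis grid is 25 wavelengths,
850–1090 nm in 10 nm steps: the quoted 850–1100 nm range is reconciled with
the stated feature count of 300 by noting 300 = C(25, 2), which forces 25
grid points, and no published model wavelength exceeds 1090 nm. Binning
averages over half-open windows `[g−5, g+5)` nm (arithmetic mean; whether
the original analysis averaged or nearest-sampled is unstated, so the
convention is documented rather than inferred). Ratio features are
`100·R(lower)/R(higher)` for every unordered pair, numerator at the lower
wavelength as in every published model ratio. Scan content below 850 nm is
read and ignored.

## NIR model development

* **Split**: 3/5 train, stratified by sex × age bin with largest-remainder
  rounding of per-stratum quotas against the rounded overall train total;
  single-subject strata go to train with a warning. Deterministic per seed.
* **Scoring**: leave-one-out cross-validated mean absolute error of an OLS
  fit ("mean estimation error" is ambiguous between L1 and L2; MAE is the
  default and squared error is a config switch). The LOOCV score uses the
  exact hat-matrix identity `e_loo = e/(1 − h)`, verified in the tests
  against a brute-force per-fold refit to 1e-9. Rank-deficient candidates
  (or any fold with leverage 1) score infinity and drop out of selection.
* **Selection**: greedy forward search within each site — round 1 scores
  each of the 300 ratios with the anthropometric covariate alongside
  (whether the original round-1 scoring included the covariate is unstated;
  both orders are implemented, covariate-in is the default), round 2 scores
  each remaining ratio added to the winner and keeps it only on strict
  improvement. Both ratios are constrained to a single site, as in every
  published model. Ties break lexicographically by (numerator, denominator)
  wavelength, then by site name.
* **Fit**: OLS of 4C fat mass on the selected ratios plus the covariate —
  weight/length (g/cm) for the standard model, bare weight (g) for the
  no-length variant (length is the hard measurement in the field; weight is
  not), or nothing for a purely spectral model. The intercept guarantees
  exactly zero-mean training residuals, which is why every
  regression-calibrated row of the comparison report has a 0.0 training
  mean difference.
* Age-group models (3–24, 3–6, 7–24 months) filter the cohort before the
  split; the 6/7-month boundary follows the published grouping.

## Method-comparison statistics

Bland–Altman differences are **reference − method**; limits of agreement
are mean ± 1.96·SD with the n−1 SD. This sign convention reproduces the
published table's signs (skinfold fat mass sits several hundred grams below
the 4C reference, giving a positive mean difference). In the comparison
report, index methods that do not natively output grams (MUAC, BMI and the
percentile indices) — and the NIR predictions — are OLS-calibrated to the
4C target on the training fold before evaluation; DD, DXA and SFT are
evaluated raw. The calibrated/direct assignment matches which published
training-set mean differences are exactly 0.0. Rows sort by descending
test R (stable mergesort, so equal-R rows keep insertion order).

One-way ANOVA and Tukey–Kramer statistics are computed from (n, mean, SD)
summary triples: `MSE = Σ(nᵢ−1)sᵢ²/(N−k)`, MSB from group means about the
weighted grand mean, `q = |mᵢ−mⱼ|/√((MSE/2)(1/nᵢ+1/nⱼ))`. The studentized
range quantile comes from `scipy.stats.studentized_range`, not printed
tables. Note the published comparison treats the all-subjects group and its
two subgroups as three independent groups (N = 328, df = (2, 325)); the
same convention is used so the statistics are comparable. Computed from the
rounded published triples, F ≈ 9.75 and q(all vs 7–24) ≈ 4.18 against the
printed 9.330 and 4.19 — agreement is limited by the two-significant-figure
inputs, as the tests' tolerances reflect.

## Synthetic cohort generator

The generator defines the study conditions for all stochastic tests; its
defaults are fixed, not tuning knobs.

**What it emulates.** Ages follow the published group imbalance — a
105 : 59 mixture of U(3, 6) and U(7, 24) months — and sex a Bernoulli at
the published male fraction. Weight is truncated-normal at the group's
published mean ± SD; length is correlated with weight (loading 0.8).
Body-fat fraction is truncated-normal on [0.15, 0.40] with group means from
the published fat-mass/weight ratios and a dispersion chosen so fat-mass SD
reproduces the published value; fat mass = bf × weight and FFM the
remainder, so mass closure is exact by construction. TBW = h(age, sex)·FFM
with the default hydration table; BMC and MUAC are correlated with weight
(and MUAC with adiposity), skinfolds with adiposity. The bf bounds keep
every *clean* subject strictly inside the 45–70 % TBW window given the
hydration range, so QC rejections on clean records are ~impossible at the
default enrichment noise (0.5 % relative on post-dose samples).

**Deuterium records.** Dose ≈ 1 g; the true plateau is
dose/(1.041·TBW). A `qc_failure_rate` fraction of subjects (default 5 %)
receives a planted failure, split evenly between the two protocol-stated
mechanisms: *dribble loss* multiplies the true enrichment by U(0.50, 0.65)
(raising apparent TBW out of range and/or pushing DD-BF% below 10) and
*basal contamination* adds U(12, 30) mg/kg to the basal sample (tripping
the basal ceiling). The factor ranges guarantee the planted mechanism trips
its matching rule across the whole bf range, which is what the
planted-recovery tests check.

**Spectra.** Each scan is a constant per-scan baseline (U(72, 78) %) times
`1 − d_fat·G(λ; 930, 15) − d_water·G(λ; 970, 15)` plus Gaussian noise
(SD 1.0 reflectance-%), emitted as raw/dark/light intensity triples that
calibrate back to this reflectance exactly when noise is zero. A constant
baseline was chosen over a sloped one so that with zero absorption all 300
ratios are exactly 100 % — the ratio features are by construction invariant
to the baseline level. Depths are tied to composition:

```
d_fat   = 0.6 · bf · (0.9 + 0.1 · skinfold_site/site_mean) · (1 + η_f)
d_water = (0.10 + 0.5 · TBW/weight) · (1 + η_w)
```

with per-subject-and-site tissue jitters η_f ~ N(0, 0.095²),
η_w ~ N(0, 0.030²) shared by duplicate scans (they probe the same tissue).
The jitters model the fact that superficial tissue composition only
approximates whole-body values, and they are essential for identifiability:
the 4C target is itself built from TBW, so a *noiseless* water-band depth
would be an oracle of the target and feature selection would always prefer
pure water-band ratios over the planted fat/water contrast. The two jitter
magnitudes equalise the bands' noise-to-signal ratios, making the combined
930/970 contrast the optimal single feature; the spectral noise floor
penalises weak shoulder pairs whose depth signal and jitter noise would
otherwise scale together. No quantitative amplitudes are published for the
device, so these depths are calibrated only to make recovery feasible, not
to mimic hardware.

**What it does not emulate** — and hence what passing tests do not show
about real data: gestational-age and feeding effects, longitudinal growth,
non-normal skinfold distributions, scanner-specific DXA artifacts, probe
pressure/contact variation, wavelength miscalibration, and any real
relationship between skin-site NIR signal and whole-body composition. The
parameter-recovery results demonstrate that the *pipeline* recovers a
planted signal under realistic noise; they are not evidence about NIR
physiology.

## Numerical conventions and degenerate inputs

* OLS via `numpy.linalg.lstsq`/pseudo-inverse; explicit rank checks raise
  on deficient final designs.
* Calibration raises when the light and dark references coincide anywhere
  in the analysis range; binning raises naming the first empty bin.
* The QC filter never raises on bad measurements — rejection with reason
  codes is a result.
* Percentiles in empty reference strata are NaN with a warning.
* All pipeline stages derive randomness from the configured seed (the split
  seed defaults to seed + 1); the manifest records the config hash and
  artifact SHA-256 values, and reruns are byte-identical.

## Problem sizes

The default demo and the stochastic checks use n = 300 synthetic subjects
(~290 after QC), chosen as the same order as the 164-subject study with
enough test-fold subjects (~115) for stable correlation estimates. Moment
convergence is checked at n = 5000 without spectra. LOOCV-oracle
equivalence is checked up to n = 15 with 12 candidate features, matching
the scale at which brute-force refitting is exact and cheap.

## Known limitations

* The hydration table, basal threshold, post-dose tolerance and exchange
  correction are defensible defaults, not study values; all are config
  keys.
* The comparison of published ANOVA/Tukey values is bounded by the rounding
  of the printed summary statistics.
* Refitting the published model coefficients themselves is impossible
  without the study data and is a non-goal; the published coefficients are
  used only in prediction-arithmetic tests.
* CLI subcommands write CSV/JSON artifacts only; no plotting is bundled.
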