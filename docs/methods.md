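# Methods

## Model and procedure

The analysis treats one scored culture — a donor's blood sample processed on
one culture day under one treatment/exposure condition — as the replication
unit. Micronucleus (MN) counts in 500 binucleated cells (BC) are the damage
endpoint; all statistics run on the MN/500 BC scale without transformation
(a square-root variance-stabilizing option exists but is off by default,
since condition-level means of counts near 10-40 are close to normal).

**Calibration.** The dose-response over the calibrated range is a straight
line `y = c0 + c1 D` fitted by unweighted ordinary least squares (a
Poisson-weighted fit is available behind a flag). Its exact inverse
`D = a + b y` with `a = -c0/c1`, `b = 1/c1` is the dose estimator; the two
parameterizations are views of one fit and stay consistent by construction.
Goodness of fit is reported as R², or "percent reliability" = 100 R² in the
dosimetry convention. A linear-quadratic fit `y = c0 + c1 D + c2 D²` is
provided for comparison with the wider literature; it is never used by the
screening endpoints.

**Screening endpoints.** MP and DRF are computed from condition-level mean
frequencies (means over cultures). Two design choices matter:

- *The screening curve is an explicit input, not a refit.* The observed
  2 Gy irradiated control (26 MN/500 BC) does not lie on the published
  calibration line (which predicts ≈ 37.7 MN/500 BC at 2000 mGy) — a known
  feature of screening runs performed separately from the calibration
  series. Refitting the curve from screening controls would silently change
  every DRF, so the pipeline takes the curve (fitted or published inverse
  coefficients) as an argument.
- *The DRF numerator is the nominal delivered dose* (2000 mGy), not the
  interpolated dose of the irradiated control. Only this reading makes the
  endpoint set self-consistent: it yields DRF 7.2 together with MP 58% and
  an equivalent dose of 0.27 Gy for the strongest protector, whereas the
  control-interpolation reading (numerator 1244 mGy at y = 26) would not.

Frequencies below the curve's zero-dose intercept give a negative raw
inverse dose; these are clamped to 0 mGy with an explicit flag and the DRF
is reported as infinite ("complete protection at curve resolution") rather
than as a large number. Bootstrap dose intervals are percentile intervals
over resampled calibration points (2000 resamples, seeded).

**Display conventions.** Internal arithmetic is never rounded. At report
time MP is rounded to the nearest integer percent, DRF to one decimal, and
equivalent doses are converted to Gy and *truncated* (not rounded) to two
decimals — truncation is what maps 278.53 mGy to 0.27 Gy.

**Significance.** Arms are compared by classical one-way fixed-effects
ANOVA; pairwise comparisons use Tukey's HSD with the Tukey-Kramer harmonic
adjustment for unbalanced groups. Adjusted p-values come from the
studentized range distribution (scipy's implementation; the test suite
validates it against an independent double-quadrature evaluation of the
range CDF and against published q-table values). Protection tiers follow
the convention of screening figures: a significant decrease vs the
irradiated control at p < 0.001 is a strong protector, at p < 0.01 a
moderate one; a significant increase at p < 0.01 flags a radiosensitizer.
Genotoxicity of an unirradiated substance arm requires both an increase
over the untreated control and p < 0.05 (two-tailed).

**Donor pooling.** Donor is a random factor in the design; before pooling,
a fixed-factor two-way ANOVA (donor x treatment, statsmodels OLS) screens
for a donor-by-treatment interaction. Pooling is licensed iff the
interaction p >= 0.05; unreplicated designs return an explicit cannot-test
verdict with pooling disallowed.

**DMSO normalization.** For lipophilic compounds dissolved in DMSO, the
solvent-only arm's MP (same timing) is subtracted from the compound's MP.
The subtraction is exact and invertible; negative net values are legitimate
and flagged as net radiosensitizing.

## Quality control

CBPI = (M1 + 2 M2 + 3 M3+)/N is bounded in [1, 3]. The acceptance window is
1.3-1.7 with *inclusive* bounds, chosen so the typical control value
(1.65 ± 0.10) is self-consistently inside the window. Conditions outside
the window, or with fewer than 3000 BC scored in total, are flagged in
summaries but never silently dropped.

## Synthetic data generator

The generator emulates the screening study design, not real slides:

- 6 donors x 5 independent experiments per condition, 500 BC per culture;
- a 20-point calibration schedule: sham plus 19 log-spaced doses from
  13 mGy (1.3 cGy) to 16,362 mGy;
- zero-dose baseline 10 MN/500 BC (0.02 MN/BC) and forward slope
  1/64.37 MN/500 BC per mGy, matching the published inverse line;
- a 2 Gy screening arm with irradiated-control mean 26 MN/500 BC and a
  29-substance panel given pre or post exposure at one concentration.

Counts are Poisson by default; setting `dispersion > 0` switches to a
negative binomial parameterized as (r, p) = (mean/dispersion,
1/(1+dispersion)), i.e. variance = mean (1 + dispersion), which degenerates
continuously to Poisson. Donor heterogeneity is a mean-one multiplicative
log-normal factor (default SD 0.05 on the log scale — small, since the
design pools across donors), drawn once per donor and shared by all of that
donor's cultures, which keeps arm means and MP estimates unbiased.

Protection acts multiplicatively on the irradiated-control *total* mean:
effect f gives a treated mean of (1 - f) x 26, so the configured f and the
expected MP coincide exactly (f < 0 encodes radiosensitizers). The default
effects map carries the handful of panel members with published endpoints at
those values (0.58/0.08 pre/post for the top protector, 0.38 for the
clinical comparator, 0.50 and 0.38 for the two vitamins, a post-dominant
0.47 for the long-chain procyanidins, and negative effects for the two
radiosensitizers); the remaining panel slots are synthetic placeholders with
fixed effects spanning the same range, present only so the default dataset
has the full panel width. The DMSO solvent adds its own protection fraction
(default 0.10) in the pre-exposure arm only; no magnitude is published for
it, so the default is a plausible mid-single-digit-MN effect chosen once.
CBPI tallies are multinomial with class probabilities set so the expected
CBPI equals a target (default 1.65, multinucleate share capped at 5%).

One integer seed governs an entire dataset; the same config reproduces the
scoring table byte-identically. The ground-truth config is written as JSON
alongside generated data so recovery checks never re-derive truth from
outputs.

What the generator does *not* emulate: microdosimetric track structure,
cell-cycle kinetics, per-cell MN multiplicity, observer variation, or any
concentration-response structure. Passing recovery tests therefore shows
the estimators are correct under the assumed count model, not that the
model captures every feature of real slide data.

## Numerical choices and problem sizes

- Studentized-range tail probabilities and quantiles come from scipy; the
  independent quadrature oracle in the tests integrates the range density
  directly (inner integral over the normal kernel, outer over the
  chi-distributed residual SD) to absolute tolerance ~1e-6.
- Permutation checks of the ANOVA p use 20,000 seeded shuffles; on the tiny
  hand-decomposable fixture the permutation distribution is discrete with a
  large atom at the observed F, so agreement is asserted against the
  strict/non-strict permutation bracket and against exact enumeration of
  all 1680 partitions.
- Recovery studies in the tests use 200 seeded replicates of the default
  design (MP recovery, calibration-slope recovery) and 1000 replicates of a
  5-arm global null for family-wise error control (decision against the
  0.05 studentized-range critical value); these sizes give Monte-Carlo SEs
  well below the effects being checked while keeping the suite quick.
- Ties/degenerate inputs: zero within-group variance raises an explicit
  degenerate-variance error in the ANOVA; the screening scorer degrades to
  p = None (no tier claim) for unreplicated or zero-variance condition
  tables such as worked examples entered as condition-level means.

## Known limitations

- The donor screen is the fixed-factor interaction test; no REML/mixed
  model estimation of the donor variance component is attempted.
- Inverse-dose intervals are percentile bootstrap only; no Poisson-exact or
  regulatory-grade uncertainty machinery.
- A single concentration per substance is assumed throughout; there is no
  concentration-response modelling.
- The linear calibration is only valid inside the calibrated dose range;
  the inverse estimator extrapolates linearly outside it without warning
  beyond the negative-dose clamp.
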