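# Methods

## Problem and scope

Fasting insulin assays are expensive, poorly standardised and often
unavailable in primary care, which makes HOMA-IR — the routine surrogate
for insulin resistance — an awkward screening tool in exactly the settings
where metabolic-syndrome (MetS) screening matters most.  Lipid-based
surrogates (the TyG index, the TG:HDL-C ratio, the lipid accumulation
product LAP) need only a fasting lipid profile, glucose and a tape
measure.  This package implements the full evaluation pipeline for such
surrogates: compute the indices from raw measurements, classify MetS by
the NCEP ATP III rule as the reference standard, and derive
population-specific screening cutoffs by maximising Youden's J on
empirical ROC curves.

## Index definitions and unit handling

With TG, FPG, HDL-C and total cholesterol in mg/dL, insulin in μIU/mL,
waist in cm:

- HOMA-IR = insulin × (FPG/18.0) / 22.5.  The mg/dL→mmol/L divisor is the
  conventional 18.0 used by standard HOMA calculators; the molar-mass
  value 18.016 changes HOMA-IR by <0.1% and is available through the
  `glucose_divisor` parameter.
- TyG = ln(TG × FPG)/2, natural logarithm.
- TG:HDL = TG/HDL, both mg/dL.
- LAP = (waist − 65) × TG_mmol for men, (waist − 58) × TG_mmol for women,
  with TG_mmol = TG/88.57.  LAP is defined in the literature with TG in
  mmol/L, and only that choice puts the index on its published reference
  scale (tens, not thousands); the factor is exposed as `tg_mmol_factor`.
  A waist below the sex offset yields a negative LAP, which is *returned
  as computed* with a warning: clamping would collapse distinct low-risk
  subjects onto one value and distort ROC ranks.
- Friedewald: VLDL = TG/5, LDL = TC − HDL − VLDL, valid for TG < 400
  mg/dL; beyond that LDL is reported missing.
- BMI = kg/m² with the Southeast-Asian categories (<18.5 underweight,
  18.5–22.9 normal, 23–24.9 overweight, ≥25 obese; intervals closed on
  the left).  WHR flags at ≥0.9 (men) / ≥0.8 (women).

Missing or out-of-domain inputs propagate as missing values in the
affected panel fields only; nothing is imputed and nothing becomes zero.

## MetS classification

Five criteria (waist ≥ 90/80 cm by sex, SBP ≥ 130 or DBP ≥ 85 mmHg,
TG ≥ 150 mg/dL, HDL < 40/50 mg/dL by sex, FPG ≥ 100 mg/dL); MetS when at
least three hold.  The clinical wording "over" is ambiguous at the
boundary, so the inequality convention is a parameter: `gte` (default,
the canonical ATP III reading) or `strict`.  HDL remains strictly `<`
under both.  Blood pressure is a single criterion (SBP or DBP).  Subjects
with any required field missing are refused classification rather than
silently counted negative.

## ROC curves and cutoff selection

The decision rule is "positive iff score ≥ threshold" (all four indices
rise with risk).  Candidate thresholds are the midpoints between
consecutive distinct sorted score values plus sentinels below the minimum
and above the maximum, the convention of the major statistical packages;
ties in scores therefore never generate an interior threshold.  AUC is
the trapezoidal area under the empirical curve, which on this
construction equals the Mann-Whitney rank statistic exactly (pairs
correctly ordered, ties ½) — the test suite enforces the identity against
exhaustive pair counting.

The operating point maximises J = sensitivity + specificity − 1.  Ties in
J are broken toward the *smallest* threshold, favouring sensitivity,
which is the right bias for a screening instrument.  A degenerate curve
(all scores tied) yields J = 0 with a warning.  Youden's J is reported on
the 0–1 scale as sens + spec − 1, and PPV/NPV are computed from the
confusion counts at the selected threshold, so all reported metrics are
mutually consistent by construction.  Exact numeric reproduction of
cutoffs published from other cohorts is impossible in principle: a
selected cutoff is a midpoint of that cohort's observed values.

TG:HDL cutoffs are derived per sex (its HDL denominator differs
systematically between men and women); HOMA-IR, TyG and LAP on the pooled
cohort.  The stratification map is configurable.  A stratified percentile
bootstrap CI for the AUC is available but off by default; no CI is
reported otherwise.

## Statistical layer

Two-group comparisons are gated per group by Shapiro-Wilk at α = 0.05:
both groups pass → Welch's t-test (unequal variances is the safer default)
with mean ± SD summaries; otherwise Mann-Whitney U with median/IQR.
Degenerate samples (n < 3, constant) fail the gate.  Spearman correlation
uses average ranks and pairwise-complete observations; constant columns
are flagged undefined.  The sex × MetS association uses chi-square without
continuity correction at cohort sizes near 200 (switchable).

## Synthetic cohort generator

The generator emulates a 192-subject adult screening cohort with
70 men / 122 women and per-sex MetS rates 24/70 and 33/122 (overall
planted prevalence 57/192 ≈ 29.7%).  Group membership is planted first;
raw measurements are then drawn from that group's distribution.  Only raw
measurements are generated — indices are always recomputed downstream, so
the generator cannot encode the analysis answer.

Marginals are moment-matched to two-group means/SDs of the calibration
table embedded in `simulate.py` (waist and HDL sex-stratified, the rest
pooled).  Right-skewed labs (FPG, insulin, TG) use lognormal marginals
matched on the natural scale.  All other variables use lower-truncated
normals with physiologic floors (age ≥ 18 years matching the study's
inclusion criterion, waist ≥ 50 cm, HDL ≥ 10 mg/dL, ...); the underlying
(μ, σ) are solved numerically so the *truncated* moments equal the
targets — naive truncation would bias, e.g., the younger group's mean age
by ~3%, breaking the generator's 2%/5% calibration contract.

Dependence is a Gaussian copula.  The study data document only
correlation signs (insulin and the indices correlate positively with
adiposity, blood pressure, glucose and TG, negatively with HDL), so the
latent magnitudes are assumptions fixed at typical cross-sectional adult
values: waist–TG 0.40, TG–HDL −0.40, FPG–insulin 0.30, insulin–waist
0.50, insulin–weight 0.40, insulin–TG 0.40, insulin–HDL −0.30,
insulin–SBP 0.20, weight–waist/hip 0.65, SBP–DBP 0.65, and so on (full
list in `DEFAULT_CORRELATIONS`).  These were chosen so the generated
cohorts reproduce the documented qualitative behaviour — every index
separates the NCEP groups in the right direction, discrimination lands in
the published AUC band (~0.83–0.92) with LAP strongest and HOMA-IR
weakest, and NCEP classification agrees with the planted label for ~84%
of subjects — and then frozen; they are stated assumptions, not fitted
quantities.

Because labels are planted before measurements, planted and NCEP status
disagree for a minority of subjects.  This is intentional: the pipeline
is always evaluated against the NCEP status it computes itself (as the
reference analysis was), while planted labels serve only generator
validation and the analytic cutoff oracle `planted_cutoff` (the crossing
point of the two group densities, found by bisection on the log-density
difference — the population-level Youden optimum).

### What the generator does and does not emulate

It reproduces two-group location/scale structure, skewness of the lab
marginals, sex composition and stratification, physiologic floors, and a
plausible cross-sectional correlation structure.  It does not model
measurement error or assay rounding, medication effects, recruitment
bias, missing data, or any within-group non-ellipticity beyond the
marginal transforms.  Passing end-to-end tests therefore demonstrates
that the *pipeline* recovers the structure a cohort of this shape
carries; it does not validate the published cutoffs themselves against
new patients.

## Numerical choices

- Indices are computed in full double precision; rounding (cutoffs to 2
  decimals, percentages to 1) happens only in report artifacts.
- Truncated-normal moment matching solves a 2×2 nonlinear system with
  scipy's hybrid Powell method, seeded at the target moments; solutions
  are cached per spec.
- `gaussian_youden_cutoff` brackets the density crossing between the two
  group means and bisects the log-density difference to 1e-10.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical (config, seed) pairs give
  byte-identical cohort and report CSVs.  The run log line carries a
  wall-clock timestamp and is the one non-reproducible output.

## Problem sizes used in validation

Unit and property tests run on small synthetic instances (n ≤ 1,000).
The calibration checks use one shared cohort of n = 20,000; parameter
recovery uses 200 replicates of n = 20,000; the end-to-end qualitative
check uses 200 study-sized cohorts (n = 192); the type-I-error check uses
2,000 null replicates of n = 50 per group.  These sizes keep Monte-Carlo
error well below each test's decision margin.

## Known limitations

- Published Youden values of 0.98–0.99 alongside sensitivities and
  specificities near 80% are arithmetically impossible under
  J = sens + spec − 1; this package reports the consistent J and makes no
  attempt to reproduce such values, nor PPV/NPV figures that conflict
  with their own sensitivity/specificity at the stated prevalence.
- Cutoffs derived at n = 192 carry substantial sampling noise (the
  smoothed optimum of a step function); users comparing against published
  values should expect differences of the order the bootstrap CI shows.
- The generator's correlation magnitudes are assumptions; conclusions
  sensitive to them should be re-run across a sensitivity range via
  `CohortSimConfig.correlations`.
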