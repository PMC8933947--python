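# Methods

## Risk equations as data

Each model is a declarative spec: a list of strata (sex, plus ancestry
where the model is ancestry-stratified), each with a term list.  A term
contributes `coefficient × f(x − offset) × Π g(y − offset)` to the linear
predictor, with `f, g ∈ {identity, ln, ln², x²}`.  This covers all six
published forms: the PCE's `ln(age) × ln(TC)` interactions, the adjusted
PCE's `SBP²` and three-way ancestry interactions, Framingham's treated /
untreated `ln(SBP)` coefficients (encoded as products with mutually
exclusive treatment indicators), and the WHO models' covariates centered
at a reference profile (age 60 y, SBP 120 mmHg, TC 6 mmol/L, BMI
25 kg/m²).

Risk transforms: Cox baseline-survival `p = 1 − S₀^exp(LP − mean LP)`
(`S₀` = 10-year event-free probability at the centering profile) and
logistic `p = 1/(1 + e^(−LP))` (adjusted PCE only).  All arithmetic is
deterministic double precision.

Canonical internal units are mg/dL (lipids), mmHg (pressure) and kg/m²
(BMI).  A spec declares its native lipid unit; the engine converts once
at evaluation time (cholesterol factor 38.67 mg/dL per mmol/L), so no
value can be converted twice.

Configs carry a source citation, retrieval date and a SHA-256 checksum
over the coefficient block; the loader recomputes and compares it, so any
edit to a transcribed number must be deliberately re-signed.

### Provenance and verification of the transcriptions

* **PCE**: verified against the source guideline's four published worked
  examples (55-year-old reference profile → 2.1 / 3.0 / 5.3 / 6.1%); the
  engine reproduces all four within 0.1 percentage point (residual
  differences are the guideline's own intermediate rounding).  These are
  frozen test fixtures.
* **Framingham (lipid and BMI versions)**: lipid-version transcription
  verified against the source publication's worked example for women
  (10.5%).
* **Adjusted PCE**: transcription of the revised logistic equations; no
  public worked example was available to cross-check, so the config is
  flagged for audit in its `notes` field.
* **WHO models**: the log-hazard coefficients follow the ERFC-based
  derivation of the revised WHO charts.  The **baseline survivals are an
  implementation calibration, not a transcription**: they set the
  reference-profile risk to the Americas-region chart level (women 0.944,
  men 0.930 laboratory; 0.942 / 0.928 non-laboratory).  The
  non-laboratory BMI coefficients are derived from the published hazard
  ratios per 5 kg/m² (ln(1.26)/5 men, ln(1.24)/5 women) with age
  attenuation scaled in the same proportion as the cholesterol term.
  Both configs are flagged for audit; because equations are data, a
  corrected transcription is a config edit.

A second, independently typed transcription of all six models lives in
the test suite (`tests/_oracle.py`) as straight-line formula code;
engine and oracle must agree to 1e-6 relative on fixed reference
profiles.  This guards against typos in either transcription and against
engine defects, but it cannot detect an error present in both copies of
a remembered coefficient — hence the audit flags above.

### Ancestry stratum

The PCE is published with White and African-American coefficient sets and
the adjusted PCE with a Black-ancestry indicator; the cohort instrument
records no ancestry variable.  The engine therefore takes an explicit,
logged `ancestry` setting (default `black`, matching the majority-Black
study population) rather than hiding the choice.  All strata remain
evaluable and tested.

### Out-of-range ages

The published validity ranges differ (PCE 40–79, Framingham 30–74, WHO
40–74) while the analytic sample is everyone ≥ 40.  Participants outside
a model's range are scored anyway and the score row carries an
out-of-range warning flag; values are never clamped silently.

## Cohort preparation

Analysis SBP is the mean of the second and third seated readings; the
first reading is discarded.  DBP is assumed averaged the same way and is
consumed as a single pre-averaged column.  The exclusion cascade is
sequential with first-failure attribution — incomplete model inputs,
then age < 40, then current statin use, then prior MI/stroke — so step
counts are mutually exclusive and reconcile exactly with input and
output sizes.  Complete-case analysis only; no imputation.

The hypertension flag used by the Framingham risk-factor count is
`treatment OR SBP ≥ 140 OR DBP ≥ 90` (the study's own definitions table
is not public; this matches the cut-points its cohort description
reports).  A missing family-history field is treated as absent with a
logged warning, since the Framingham statin criteria need it but many
cohort instruments do not capture it.

## Categorization and discordance

Intervals are left-closed, right-open with the top category closed at its
cut: "5 to 7.5%" means [0.05, 0.075).  The source material prints "≥"
only for the high cut; the lower boundary convention is this package's
documented choice, applied at full floating-point precision (rounding
first would misclassify boundary-adjacent scores).  A participant is
discordant when some model calls them low risk and another calls them
high risk; intermediate never triggers discordance.

## Statin rules

Three families (PCE-type, Framingham, WHO) as disjunctions of published
criteria, evaluated in printed order with the first hit recorded as
reporting metadata.  The Framingham "10–20%" band is [0.10, 0.20), so its
criteria 3/4/5 partition the risk axis.  The WHO rule (risk ≥ 20%)
coincides by construction with the WHO high category under
model-specific thresholds; the suite asserts this identity exactly.
Participants on statins are excluded upstream and never reach the rules.

## Comparison statistics

* Spearman rank correlation with average ranks for ties (scipy); a
  constant score column yields NaN rather than an error.
* Pearson chi-square without continuity correction for all tables.
* Wilson score intervals without continuity correction.
* Quantiles by linear interpolation (numpy default).

The chi-square and Wilson variants were selected because, recomputed from
the published per-model count data, they reproduce the printed values at
printed precision (χ² = 1416 on the 6x3 category table; 95% CIs
39.2–44.5% for 563/1345 and 1.2–2.6% for 24/1345); the
continuity-corrected variants do not.  P-values are reported as computed;
published comparisons only state "< 0.001", so tests assert bounds.

## Synthetic cohorts

A Gaussian copula: one latent multivariate normal per participant over
(age, SBP, DBP, TC, HDL, LDL, BMI, female, treated, diabetes, smoker),
pushed through monotone marginal maps —

* age: piecewise-linear quantile function through (0 → 40, 0.25 → 47,
  0.5 → 54, 0.75 → 62, 0.9 → 70, 1 → 90); the generator emulates the
  analytic sample, so ages are bounded below at 40;
* SBP ~ N(133.1, 26.6²) and DBP ~ N(79.1, 16.8²), solved from the two
  published cut-point prevalences each (SBP ≥ 140: 39.8%, ≥ 130: 54.7%;
  DBP ≥ 90: 25.9%, ≥ 80: 47.9%);
* lipids and BMI log-normal, median and log-sd solved from one published
  cut-point prevalence each (TC ≥ 240: 14.9%; HDL < 40: 21.0%;
  LDL ≥ 130: 33.5%; BMI ≥ 30: 21.8%) plus a plausible median;
* binaries thresholded from their latent normals at the published
  prevalences.

Three SBP readings are emitted per participant (true SBP + N(0, 4²)
reading noise, +4 mmHg bias on the discarded first reading).  The latent
correlations are a modelling choice — the joint distribution is
unpublished — with modest positive age–SBP (0.35) and age–cholesterol
(0.20) dependence, strong TC–LDL (0.90) and SBP–DBP (0.65) coupling, and
treatment–pressure correlations (SBP 0.30, DBP 0.20) calibrated once so
the *derived* hypertension flag recovers its published 52.9% prevalence.
Prior-CVD and statin-use flags default to zero prevalence (the analytic
sample excludes them) and can be injected to exercise the exclusion
cascade.  All draws come from one seeded generator in a fixed order, so
a (marginals, seed, n) triple fully determines the cohort.

What passing marginal-recovery tests show: each published *marginal*
target is recovered within 3 binomial standard errors at n = 10 000.
What they do not show: that the joint distribution — and hence any
cohort-dependent result such as per-model medians, high-risk shares or
discordance counts — matches the real cohort.  Those quantities come out
qualitatively similar to the published ones (e.g. PCE median ≈ 6%,
highest high-risk share under PCE, discordance concentrated where one
family's threshold is crossed) but are not, and cannot be, reproductions.

## Problem sizes

The default test suite uses cohorts of 120–1000 participants (10 000 for
marginal recovery over 5 seeds) and the acceptance script simulates at
the published analytic-sample size, n = 1345; both complete in seconds on
one core.

## Known limitations

* **PCE non-monotonicity in age.**  With the true published coefficients,
  the African-American women stratum contains ln(age) × ln(SBP)
  interactions (−6.432 treated, −6.087 untreated) that make predicted
  risk *decrease* with age whenever ln(SBP) > (17.114 + 4.475 ln HDL) /
  6.432 — e.g. treated SBP ≳ 170 mmHg with HDL ≲ 40 mg/dL; the White
  strata have an analogous corner via the age × smoking and age × ln(TC)
  interactions.  Roughly 0.5–1% of cohort-like profiles fall in such a
  region.  The acceptance suite asserts age-monotonicity across random
  profiles for every model, and that assertion fails for the PCE — it is
  left failing deliberately, as a truthful property of the published
  equations (the independent transcription agrees on the violating
  profiles), documented here rather than worked around.  Monotonicity in
  SBP and smoking holds for all six models over the plausible domain, as
  does age-monotonicity for the other five.
* The adjusted-PCE and WHO transcriptions lack public worked examples to
  verify against; they are flagged for audit in their configs.
* The synthetic generator can emit a small fraction (~5%) of records
  whose LDL is incoherent with TC − HDL (lipid panels are generated
  marginally, constrained only by the latent TC–LDL correlation); no
  model uses LDL, only the statin rules do, and the effect on eligibility
  shares is within sampling noise.
* No calibration or discrimination against observed events: the package
  compares predictions with predictions, by design.
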