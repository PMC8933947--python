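# Pooled Cohort Equations (2013 ACC/AHA ASCVD risk estimator).
# Sex x ancestry stratified Cox baseline-survival form:
#   risk = 1 - S0 ^ exp(LP - mean_lp)
# Covariates enter as natural logs; treated and untreated SBP carry separate
# coefficients, implemented here as ln(SBP) x treatment-indicator products.
# Transcription cross-checked against the guideline's published worked
# examples (55-year-old reference profile: 2.1% / 3.0% / 5.3% / 6.1%).
model_id: pce
name: Pooled Cohort Equations
form: cox
source: >-
  Goff DC Jr, Lloyd-Jones DM, Bennett G, et al. 2013 ACC/AHA Guideline on the
  Assessment of Cardiovascular Risk. Circulation. 2014;129(25 Suppl 2):S49-S73.
  Appendix 7, Table A.
retrieved: "2026-09-28"
lipid_units: mg/dL
age_range: [40, 79]
strata:
  - sex: female
    ancestry: white
    baseline_survival: 0.9665
    mean_lp: -29.18
    terms:
      - {covariate: age, transform: log, coefficient: -29.799}
      - {covariate: age, transform: log_squared, coefficient: 4.884}
      - {covariate: total_cholesterol, transform: log, coefficient: 13.540}
      - {covariate: age, transform: log, coefficient: -3.114,
         interactions: [{covariate: total_cholesterol, transform: log}]}
      - {covariate: hdl, transform: log, coefficient: -13.578}
      - {covariate: age, transform: log, coefficient: 3.149,
         interactions: [{covariate: hdl, transform: log}]}
      - {covariate: sbp, transform: log, coefficient: 2.019,
         interactions: [{covariate: bp_treated}]}
      - {covariate: sbp, transform: log, coefficient: 1.957,
         interactions: [{covariate: bp_untreated}]}
      - {covariate: smoker, coefficient: 7.574}
      - {covariate: age, transform: log, coefficient: -1.665,
         interactions: [{covariate: smoker}]}
      - {covariate: diabetes, coefficient: 0.661}
  - sex: female
    ancestry: black
    baseline_survival: 0.9533
    mean_lp: 86.61
    terms:
      - {covariate: age, transform: log, coefficient: 17.114}
      - {covariate: total_cholesterol, transform: log, coefficient: 0.940}
      - {covariate: hdl, transform: log, coefficient: -18.920}
      - {covariate: age, transform: log, coefficient: 4.475,
         interactions: [{covariate: hdl, transform: log}]}
      - {covariate: sbp, transform: log, coefficient: 29.291,
         interactions: [{covariate: bp_treated}]}
      - {covariate: age, transform: log, coefficient: -6.432,
         interactions: [{covariate: sbp, transform: log},
                        {covariate: bp_treated}]}
      - {covariate: sbp, transform: log, coefficient: 27.820,
         interactions: [{covariate: bp_untreated}]}
      - {covariate: age, transform: log, coefficient: -6.087,
         interactions: [{covariate: sbp, transform: log},
                        {covariate: bp_untreated}]}
      - {covariate: smoker, coefficient: 0.691}
      - {covariate: diabetes, coefficient: 0.874}
  - sex: male
    ancestry: white
    baseline_survival: 0.9144
    mean_lp: 61.18
    terms:
      - {covariate: age, transform: log, coefficient: 12.344}
      - {covariate: total_cholesterol, transform: log, coefficient: 11.853}
      - {covariate: age, transform: log, coefficient: -2.664,
         interactions: [{covariate: total_cholesterol, transform: log}]}
      - {covariate: hdl, transform: log, coefficient: -7.990}
      - {covariate: age, transform: log, coefficient: 1.769,
         interactions: [{covariate: hdl, transform: log}]}
      - {covariate: sbp, transform: log, coefficient: 1.797,
         interactions: [{covariate: bp_treated}]}
      - {covariate: sbp, transform: log, coefficient: 1.764,
         interactions: [{covariate: bp_untreated}]}
      - {covariate: smoker, coefficient: 7.837}
      - {covariate: age, transform: log, coefficient: -1.795,
         interactions: [{covariate: smoker}]}
      - {covariate: diabetes, coefficient: 0.658}
  - sex: male
    ancestry: black
    baseline_survival: 0.8954
    mean_lp: 19.54
    terms:
      - {covariate: age, transform: log, coefficient: 2.469}
      - {covariate: total_cholesterol, transform: log, coefficient: 0.302}
      - {covariate: hdl, transform: log, coefficient: -0.307}
      - {covariate: sbp, transform: log, coefficient: 1.916,
         interactions: [{covariate: bp_treated}]}
      - {covariate: sbp, transform: log, coefficient: 1.809,
         interactions: [{covariate: bp_untreated}]}
      - {covariate: smoker, coefficient: 0.549}
      - {covariate: diabetes, coefficient: 0.645}
coefficient_checksum: "sha256:464d25d38aaa6a12f352873999b849adf543b91c23b7020e50c960f77d07d961"
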