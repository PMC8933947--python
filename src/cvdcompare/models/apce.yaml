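# Adjusted (revised) Pooled Cohort Equations: logistic-form equations refit
# on updated cohorts with a larger share of African-American participants.
# Sex-stratified; ancestry enters as a Black-indicator covariate with
# interaction terms rather than as a separate coefficient table.
#   risk = 1 / (1 + exp(-LP))
# Covariates in native units: age (y), SBP (mmHg, plus squared term and
# treatment interactions), total:HDL cholesterol ratio (dimensionless),
# diabetes / current-smoking indicators.
model_id: apce
name: Adjusted Pooled Cohort Equations (revised, updated cohorts)
form: logistic
source: >-
  Yadlowsky S, Hayward RA, Sussman JB, McClelland RL, Min YI, Basu S.
  Clinical implications of revised Pooled Cohort Equations for estimating
  atherosclerotic cardiovascular disease risk. Ann Intern Med.
  2018;169(1):20-29. Appendix equations.
retrieved: "2026-09-28"
notes: >-
  Transcribed without access to an independent worked example; flagged for
  audit against the original appendix. Encodes the revised equations as
  published, without any additional recalibration constants.
lipid_units: mg/dL
age_range: [40, 79]
strata:
  - sex: female
    terms:
      - {covariate: one, coefficient: -12.823110}
      - {covariate: age, coefficient: 0.106501}
      - {covariate: black, coefficient: 0.432440}
      - {covariate: sbp, transform: squared, coefficient: 0.000056}
      - {covariate: sbp, coefficient: 0.017666}
      - {covariate: bp_treated, coefficient: 0.731678}
      - {covariate: diabetes, coefficient: 0.943970}
      - {covariate: smoker, coefficient: 1.009790}
      - {covariate: chol_ratio, coefficient: 0.151318}
      - {covariate: age, coefficient: -0.008580,
         interactions: [{covariate: black}]}
      - {covariate: sbp, coefficient: -0.003647,
         interactions: [{covariate: bp_treated}]}
      - {covariate: sbp, coefficient: 0.006208,
         interactions: [{covariate: black}]}
      - {covariate: black, coefficient: 0.152968,
         interactions: [{covariate: bp_treated}]}
      - {covariate: age, coefficient: -0.000153,
         interactions: [{covariate: sbp}]}
      - {covariate: black, coefficient: 0.115232,
         interactions: [{covariate: diabetes}]}
      - {covariate: black, coefficient: -0.092231,
         interactions: [{covariate: smoker}]}
      - {covariate: black, coefficient: 0.070498,
         interactions: [{covariate: chol_ratio}]}
      - {covariate: black, coefficient: -0.000173,
         interactions: [{covariate: sbp}, {covariate: bp_treated}]}
      - {covariate: black, coefficient: -0.000094,
         interactions: [{covariate: age}, {covariate: sbp}]}
  - sex: male
    terms:
      - {covariate: one, coefficient: -11.679980}
      - {covariate: age, coefficient: 0.064200}
      - {covariate: black, coefficient: 0.482835}
      - {covariate: sbp, transform: squared, coefficient: -0.000061}
      - {covariate: sbp, coefficient: 0.038950}
      - {covariate: bp_treated, coefficient: 2.055533}
      - {covariate: diabetes, coefficient: 0.842209}
      - {covariate: smoker, coefficient: 0.895589}
      - {covariate: chol_ratio, coefficient: 0.193307}
      - {covariate: sbp, coefficient: -0.014207,
         interactions: [{covariate: bp_treated}]}
      - {covariate: sbp, coefficient: 0.011609,
         interactions: [{covariate: black}]}
      - {covariate: black, coefficient: -0.119460,
         interactions: [{covariate: bp_treated}]}
      - {covariate: age, coefficient: 0.000025,
         interactions: [{covariate: sbp}]}
      - {covariate: black, coefficient: -0.077214,
         interactions: [{covariate: diabetes}]}
      - {covariate: black, coefficient: -0.226771,
         interactions: [{covariate: smoker}]}
      - {covariate: black, coefficient: -0.117749,
         interactions: [{covariate: chol_ratio}]}
      - {covariate: black, coefficient: 0.004190,
         interactions: [{covariate: bp_treated}, {covariate: sbp}]}
      - {covariate: black, coefficient: -0.000199,
         interactions: [{covariate: age}, {covariate: sbp}]}
coefficient_checksum: "sha256:32469e14bc40b892929a04fed4122b59adc5cacf884d541d43225fc3e8b20645"
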