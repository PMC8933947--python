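# Framingham general cardiovascular disease risk function, laboratory
# (lipid) version.  Sex-stratified Cox baseline-survival form on natural
# logs of continuous covariates; treated and untreated SBP carry separate
# coefficients.  Transcription cross-checked against the publication's
# worked example for women (risk 10.5%).
model_id: framingham_lipids
name: Framingham general CVD risk score (lipids)
form: cox
source: >-
  D'Agostino RB Sr, Vasan RS, Pencina MJ, et al. General cardiovascular
  risk profile for use in primary care: the Framingham Heart Study.
  Circulation. 2008;117(6):743-753. Table 2.
retrieved: "2026-09-28"
lipid_units: mg/dL
age_range: [30, 74]
strata:
  - sex: female
    baseline_survival: 0.95012
    mean_lp: 26.1931
    terms:
      - {covariate: age, transform: log, coefficient: 2.32888}
      - {covariate: total_cholesterol, transform: log, coefficient: 1.20904}
      - {covariate: hdl, transform: log, coefficient: -0.70833}
      - {covariate: sbp, transform: log, coefficient: 2.76157,
         interactions: [{covariate: bp_untreated}]}
      - {covariate: sbp, transform: log, coefficient: 2.82263,
         interactions: [{covariate: bp_treated}]}
      - {covariate: smoker, coefficient: 0.52873}
      - {covariate: diabetes, coefficient: 0.69154}
  - sex: male
    baseline_survival: 0.88936
    mean_lp: 23.9802
    terms:
      - {covariate: age, transform: log, coefficient: 3.06117}
      - {covariate: total_cholesterol, transform: log, coefficient: 1.12370}
      - {covariate: hdl, transform: log, coefficient: -0.93263}
      - {covariate: sbp, transform: log, coefficient: 1.93303,
         interactions: [{covariate: bp_untreated}]}
      - {covariate: sbp, transform: log, coefficient: 1.99881,
         interactions: [{covariate: bp_treated}]}
      - {covariate: smoker, coefficient: 0.65451}
      - {covariate: diabetes, coefficient: 0.57367}
coefficient_checksum: "sha256:68ba6384ada2ed04e1a7956d61a4d9951a26fd4e5de29cebe5403c6015d5b886"
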