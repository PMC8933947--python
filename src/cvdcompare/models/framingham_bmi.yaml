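# Framingham general cardiovascular disease risk function, office-based
# (non-laboratory) version: BMI replaces the lipid measurements so the
# score can be computed without a blood draw.  Sex-stratified Cox
# baseline-survival form on natural logs.
model_id: framingham_bmi
name: Framingham general CVD risk score (BMI, office-based)
form: cox
source: >-
  D'Agostino RB Sr, Vasan RS, Pencina MJ, et al. General cardiovascular
  risk profile for use in primary care: the Framingham Heart Study.
  Circulation. 2008;117(6):743-753. Table 4 (office-based model).
retrieved: "2026-09-28"
lipid_units: mg/dL
age_range: [30, 74]
strata:
  - sex: female
    baseline_survival: 0.94833
    mean_lp: 26.0145
    terms:
      - {covariate: age, transform: log, coefficient: 2.72107}
      - {covariate: bmi, transform: log, coefficient: 0.51125}
      - {covariate: sbp, transform: log, coefficient: 2.81291,
         interactions: [{covariate: bp_untreated}]}
      - {covariate: sbp, transform: log, coefficient: 2.88267,
         interactions: [{covariate: bp_treated}]}
      - {covariate: smoker, coefficient: 0.61868}
      - {covariate: diabetes, coefficient: 0.77763}
  - sex: male
    baseline_survival: 0.88431
    mean_lp: 23.9388
    terms:
      - {covariate: age, transform: log, coefficient: 3.11296}
      - {covariate: bmi, transform: log, coefficient: 0.79277}
      - {covariate: sbp, transform: log, coefficient: 1.85508,
         interactions: [{covariate: bp_untreated}]}
      - {covariate: sbp, transform: log, coefficient: 1.92672,
         interactions: [{covariate: bp_treated}]}
      - {covariate: smoker, coefficient: 0.70953}
      - {covariate: diabetes, coefficient: 0.53160}
coefficient_checksum: "sha256:274f160c4117520c89d0a57e2dd76eccd1361a7c7878111766916949f91603a3"
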