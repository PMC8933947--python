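# WHO cardiovascular disease risk model, laboratory version.  Sex-specific
# Cox baseline-survival form on covariates centered at a reference profile
# (age 60 y, SBP 120 mmHg, total cholesterol 6 mmol/L), with age-attenuation
# interactions on smoking, SBP, diabetes and cholesterol.  Published in
# mmol/L; the engine converts from the package's canonical mg/dL.
model_id: who_lipids
name: WHO CVD risk model (laboratory)
form: cox
source: >-
  WHO CVD Risk Chart Working Group. World Health Organization cardiovascular
  disease risk charts: revised models to estimate risk in 21 global regions.
  Lancet Glob Health. 2019;7(10):e1332-e1345. Supplementary model
  coefficients (Emerging Risk Factors Collaboration derivation).
retrieved: "2026-09-28"
notes: >-
  Log-hazard coefficients encoded from the ERFC-based derivation; the
  baseline 10-year survivals encode the Americas-region recalibrated chart
  level at the reference profile and are an implementation calibration, not
  a transcription (the regional recalibration tables are not reproduced
  here). Flagged for audit against the original supplement.
lipid_units: mmol/L
age_range: [40, 74]
strata:
  - sex: female
    baseline_survival: 0.944
    mean_lp: 0.0
    terms:
      - {covariate: age, offset: 60.0, coefficient: 0.0779636}
      - {covariate: smoker, coefficient: 0.6010619}
      - {covariate: sbp, offset: 120.0, coefficient: 0.0112106}
      - {covariate: diabetes, coefficient: 0.8460193}
      - {covariate: total_cholesterol, offset: 6.0, coefficient: 0.1319427}
      - {covariate: age, offset: 60.0, coefficient: -0.0110117,
         interactions: [{covariate: smoker}]}
      - {covariate: age, offset: 60.0, coefficient: -0.0000649,
         interactions: [{covariate: sbp, offset: 120.0}]}
      - {covariate: age, offset: 60.0, coefficient: -0.0175542,
         interactions: [{covariate: diabetes}]}
      - {covariate: age, offset: 60.0, coefficient: -0.0014626,
         interactions: [{covariate: total_cholesterol, offset: 6.0}]}
  - sex: male
    baseline_survival: 0.930
    mean_lp: 0.0
    terms:
      - {covariate: age, offset: 60.0, coefficient: 0.0719227}
      - {covariate: smoker, coefficient: 0.4164492}
      - {covariate: sbp, offset: 120.0, coefficient: 0.0128421}
      - {covariate: diabetes, coefficient: 0.6061665}
      - {covariate: total_cholesterol, offset: 6.0, coefficient: 0.1543391}
      - {covariate: age, offset: 60.0, coefficient: -0.0045741,
         interactions: [{covariate: smoker}]}
      - {covariate: age, offset: 60.0, coefficient: -0.0001813,
         interactions: [{covariate: sbp, offset: 120.0}]}
      - {covariate: age, offset: 60.0, coefficient: -0.0129724,
         interactions: [{covariate: diabetes}]}
      - {covariate: age, offset: 60.0, coefficient: -0.0016854,
         interactions: [{covariate: total_cholesterol, offset: 6.0}]}
coefficient_checksum: "sha256:8f8494b61f6b25c8e1692f83044837c348b44c28ca2ace049160b62f47ef4f94"
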