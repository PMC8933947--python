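# WHO cardiovascular disease risk model, non-laboratory (office) version:
# BMI replaces cholesterol and the diabetes term is dropped, so the score
# needs no blood draw.  Same centered Cox form as the laboratory model
# (reference profile age 60 y, SBP 120 mmHg, BMI 25 kg/m^2).
model_id: who_bmi
name: WHO CVD risk model (non-laboratory, BMI)
form: cox
source: >-
  WHO CVD Risk Chart Working Group. World Health Organization cardiovascular
  disease risk charts: revised models to estimate risk in 21 global regions.
  Lancet Glob Health. 2019;7(10):e1332-e1345. Supplementary model
  coefficients (non-laboratory model).
retrieved: "2026-09-28"
notes: >-
  Age, smoking and SBP log-hazards shared with the laboratory model; BMI
  log-hazard derived from the published hazard ratios per 5 kg/m^2
  (ln(1.26)/5 men, ln(1.24)/5 women) with age attenuation scaled in the
  same proportion as the cholesterol term.  Baseline survivals encode the
  Americas-region chart level at the reference profile (implementation
  calibration). Flagged for audit against the original supplement.
lipid_units: mg/dL
age_range: [40, 74]
strata:
  - sex: female
    baseline_survival: 0.942
    mean_lp: 0.0
    terms:
      - {covariate: age, offset: 60.0, coefficient: 0.0779636}
      - {covariate: smoker, coefficient: 0.6010619}
      - {covariate: sbp, offset: 120.0, coefficient: 0.0112106}
      - {covariate: bmi, offset: 25.0, coefficient: 0.0430172}
      - {covariate: age, offset: 60.0, coefficient: -0.0110117,
         interactions: [{covariate: smoker}]}
      - {covariate: age, offset: 60.0, coefficient: -0.0000649,
         interactions: [{covariate: sbp, offset: 120.0}]}
      - {covariate: age, offset: 60.0, coefficient: -0.0004769,
         interactions: [{covariate: bmi, offset: 25.0}]}
  - sex: male
    baseline_survival: 0.928
    mean_lp: 0.0
    terms:
      - {covariate: age, offset: 60.0, coefficient: 0.0719227}
      - {covariate: smoker, coefficient: 0.4164492}
      - {covariate: sbp, offset: 120.0, coefficient: 0.0128421}
      - {covariate: bmi, offset: 25.0, coefficient: 0.0462304}
      - {covariate: age, offset: 60.0, coefficient: -0.0045741,
         interactions: [{covariate: smoker}]}
      - {covariate: age, offset: 60.0, coefficient: -0.0005048,
         interactions: [{covariate: bmi, offset: 25.0}]}
coefficient_checksum: "sha256:dc9e1f1d5a1df9b6dffa37d4b613c1eb7a3d768022543c39d2b3aea517880a6e"
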