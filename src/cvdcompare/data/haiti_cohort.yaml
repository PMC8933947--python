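# Marginal targets for synthetic-cohort generation, encoding the published
# demographic and clinical characteristics of the Haiti CVD Cohort analytic
# sample (N = 1345, adults >= 40 without prior CVD or statin use):
# 60.9% female; age median 54 [IQR 47, 62]; 18.7% on antihypertensive
# treatment; 7.8% diabetes; 4.0% current smokers; 21.8% BMI >= 30;
# 21.0% HDL < 40 mg/dL; 33.5% LDL >= 130 mg/dL; 39.8% SBP >= 140 mmHg
# (54.7% >= 130); 25.9% DBP >= 90 mmHg; 2.5% HIV.  Continuous shapes
# (log-normal lipids/BMI, normal blood pressures) and the latent
# correlations are modelling choices, documented in docs/methods.md; the
# treatment/blood-pressure correlations are calibrated so the derived
# hypertension flag recovers its published 52.9% prevalence.
n: 1345
p_female: 0.609
p_bp_treated: 0.187
p_diabetes: 0.078
p_smoker: 0.040
p_prior_mi: 0.0
p_prior_stroke: 0.0
p_on_statin: 0.0
p_fam_hx: 0.05
p_hiv: 0.025
age_quantiles: {0.0: 40.0, 0.25: 47.0, 0.5: 54.0, 0.75: 62.0, 0.9: 70.0, 1.0: 90.0}
sbp_mean: 133.1
sbp_sd: 26.6
dbp_mean: 79.1
dbp_sd: 16.8
reading_noise_sd: 4.0
first_reading_bias: 4.0
tc_median: 190.0       # with sigma 0.2245 -> 14.9% above 240 mg/dL
tc_sigma: 0.2245
hdl_median: 48.0       # 21.0% below 40 mg/dL
hdl_sigma: 0.2263
ldl_median: 115.0      # 33.5% at or above 130 mg/dL
ldl_sigma: 0.287
bmi_median: 26.0       # 21.8% at or above 30 kg/m^2
bmi_sigma: 0.1837
latent_correlations:
  "age,sbp": 0.35
  "age,dbp": 0.10
  "age,tc": 0.20
  "age,ldl": 0.18
  "age,bmi": -0.05
  "age,treated": 0.30
  "age,diabetes": 0.20
  "age,smoker": -0.05
  "sbp,dbp": 0.65
  "sbp,treated": 0.30
  "sbp,bmi": 0.15
  "sbp,diabetes": 0.10
  "dbp,treated": 0.20
  "dbp,bmi": 0.15
  "tc,ldl": 0.90
  "tc,hdl": 0.25
  "tc,bmi": 0.10
  "hdl,ldl": 0.05
  "hdl,bmi": -0.20
  "hdl,female": 0.15
  "hdl,smoker": -0.05
  "ldl,bmi": 0.10
  "bmi,female": 0.25
  "bmi,diabetes": 0.25
  "bmi,treated": 0.10
  "female,smoker": -0.20
  "female,treated": 0.10
  "diabetes,treated": 0.15
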