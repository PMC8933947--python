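# Published per-model category and statin-eligibility counts for the Haiti
# CVD Cohort analytic sample (N = 1345), model-specific thresholds.
# Used to recompute the between-model chi-square statistics and the
# one-sample proportion confidence intervals from printed count data.
model_id,low,intermediate,high,statin_eligible,n
pce,588,200,557,563,1345
apce,813,164,368,408,1345
framingham_lipids,776,327,242,344,1345
framingham_bmi,689,360,296,362,1345
who_lipids,685,627,33,33,1345
who_bmi,678,643,24,24,1345
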