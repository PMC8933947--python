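# cvdcompare

Compare 10-year cardiovascular disease (CVD) risk prediction models —
and the statin-eligibility rules built on them — on participant-level
cohort data.

## The problem

Primary prevention of CVD in low- and middle-income countries hinges on
risk prediction: who should be offered a statin or blood-pressure
treatment?  The widely used risk equations were derived in high-income,
largely white cohorts, and different equations can give the same person
very different 10-year risks.  `cvdcompare` implements six standard
models behind one engine so their predictions, risk categorizations and
treatment implications can be compared head-to-head on one cohort:

| model id | description | form |
|---|---|---|
| `pce` | Pooled Cohort Equations (ASCVD estimator), sex x ancestry strata | Cox |
| `apce` | revised/adjusted PCE refit on updated cohorts | logistic |
| `framingham_lipids` | Framingham general CVD score, laboratory version | Cox |
| `framingham_bmi` | Framingham general CVD score, office (BMI) version | Cox |
| `who_lipids` | WHO CVD risk model, laboratory version (mmol/L) | Cox |
| `who_bmi` | WHO CVD risk model, non-laboratory (BMI) version | Cox |

Every equation is shipped as a human-auditable YAML config (terms,
transforms, interactions, baseline survival, centering constant, source
citation, checksum) and evaluated by a single declarative engine:

* linear predictor: LP = Σⱼ βⱼ · fⱼ(xⱼ) · Πₖ gⱼₖ(xⱼₖ)
* Cox baseline-survival form: p = 1 − S₀^exp(LP − mean LP)
* logistic form: p = 1 / (1 + e^(−LP))

Around the engine sit the pieces of a complete comparison pipeline:
cohort ingestion with the seated-BP convention (mean of readings 2 and 3;
reading 1 discarded) and a sequential exclusion cascade (incomplete data,
age < 40, statin use, prior MI/stroke); low/intermediate/high
categorization under uniform (5% / 7.5%) and model-specific (PCE-type
5% / 7.5%, Framingham 10% / 20%, WHO 5% / 20%) thresholds; the three
statin rule families; and comparison statistics (Spearman rank
concordance, Pearson chi-square tests of independence, Wilson score
intervals, discordance counts, high-risk risk-factor profiles).

Because the motivating cohort's participant-level data are not public, a
seeded Gaussian-copula generator produces synthetic cohorts whose
marginals match the published characteristics of the Haiti CVD Cohort
analytic sample (n = 1345; 60.9% female; age median 54 [IQR 47–62];
52.9% hypertension; 39.8% SBP ≥ 140 mmHg; …), so every stage is testable
and every analysis reproducible from a seed.

## Worked example

```python
from cvdcompare import ParticipantRecord, load_registry, score_participant

rec = ParticipantRecord(participant_id="treated-HTN man, 58",
                        age=58, sex="male", total_cholesterol=205, hdl=42,
                        ldl=130, sbp2=148, sbp3=144, dbp_avg=92,
                        bp_treated=True, bmi=28)
for mid, spec in load_registry().items():
    print(mid, round(100 * score_participant(spec, rec).risk, 1))
```

prints (ancestry stratum: Black, the package default):

```
pce 16.6
apce 11.7
framingham_lipids 25.2
framingham_bmi 27.1
who_lipids 7.6
who_bmi 9.9
```

— the same man is "high risk" under every model-specific threshold for
the PCE and Framingham families (≥ 7.5% and ≥ 20% respectively) but well
below the WHO treatment threshold (20%): model choice decides his
treatment recommendation.  The scripts in `examples/` walk through the
other capabilities (synthetic cohorts, agreement statistics, statin
eligibility), and the CLI runs the whole pipeline:

```sh
cvdcompare run --simulate 1345 --seed 1 --out results/run1
```

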