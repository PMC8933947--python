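"""Score a handful of individual risk profiles under all six models.

Builds three participants spanning low to high risk, evaluates each model,
and prints the 10-year predicted CVD risk.  The spread across models for
the same person is the package's central subject: the equations disagree,
sometimes by a factor of two or more.
"""

from cvdcompare import ParticipantRecord, load_registry, score_participant

profiles = [
    ParticipantRecord(participant_id="low-risk woman, 45",
                      age=45, sex="female", total_cholesterol=175, hdl=60,
                      ldl=100, sbp2=112, sbp3=110, dbp_avg=72, bmi=23),
    ParticipantRecord(participant_id="treated-HTN man, 58",
                      age=58, sex="male", total_cholesterol=205, hdl=42,
                      ldl=130, sbp2=148, sbp3=144, dbp_avg=92,
                      bp_treated=True, bmi=28),
    ParticipantRecord(participant_id="diabetic smoker, 66",
                      age=66, sex="female", total_cholesterol=240, hdl=38,
                      ldl=155, sbp2=162, sbp3=158, dbp_avg=95,
                      diabetes=True, smoker=True, bmi=31),
]

registry = load_registry()
print(f"{'profile':<24}" + "".join(f"{m:>19}" for m in registry))
for rec in profiles:
    risks = [score_participant(spec, rec).risk for spec in registry.values()]
    print(f"{rec.participant_id:<24}"
          + "".join(f"{100 * r:>18.1f}%" for r in risks))
print("\nEach cell is the model's predicted 10-year CVD risk; rows show how "
      "much the six equations\ndisagree about the same person (ancestry "
      "stratum: Black, the package default).")
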