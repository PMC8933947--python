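"""Cohort preparation: BP averaging, ingest, exclusion cascade, flags."""

import io

import pytest

from cvdcompare import (apply_inclusion_filters, average_bp, derive_flags,
                        read_cohort, records_to_frame)
from conftest import make_record


@pytest.mark.parametrize("r1, r2, r3, expected", [
    (150, 120, 130, 125.0),   # first reading discarded
    (118, 118, 118, 118.0),   # identity
    (100, 131, 132, 131.5),   # plain mean of readings 2 and 3
    (None, 120, 130, 125.0),  # reading 1 optional
])
def test_average_bp_uses_readings_two_and_three(r1, r2, r3, expected):
    assert average_bp(r1, r2, r3) == expected


def test_average_bp_requires_readings_two_and_three():
    with pytest.raises(ValueError):
        average_bp(120, None, 130)
    with pytest.raises(ValueError):
        average_bp(120, -5, 130)


def _csv(rows, header=None):
    header = header or ("participant_id,age_years,sex,tc_mgdl,hdl_mgdl,"
                        "ldl_mgdl,sbp1_mmhg,sbp2_mmhg,sbp3_mmhg,dbp_avg_mmhg,"
                        "bp_treated,diabetes,smoker_current,bmi_kgm2,"
                        "prior_mi,prior_stroke,on_statin,"
                        "fam_hx_premature_chd,hiv")
    return io.StringIO("\n".join([header] + rows) + "\n")


VALID_ROW = "P{i},52,female,210,55,130,130,128,126,80,0,0,0,27,0,0,0,0,0"


def test_read_cohort_accepts_valid_rows_and_rejects_bad_ones():
    rows = [VALID_ROW.format(i=i) for i in range(5)]
    records, rejects = read_cohort(_csv(rows))
    assert len(records) == 5 and rejects.empty

    bad = "PX,52,female,210,55,130,130,-128,126,80,0,0,0,27,0,0,0,0,0"
    records, rejects = read_cohort(_csv([VALID_ROW.format(i=0), bad]))
    assert len(records) == 1
    assert len(rejects) == 1 and "positive" in rejects.iloc[0]["reason"]


def test_read_cohort_missing_required_column_fails():
    with pytest.raises(ValueError, match="required columns"):
        read_cohort(io.StringIO("participant_id,sex\nP1,female\n"))


def test_read_cohort_converts_mmoll_lipids():
    header = ("participant_id,age_years,sex,tc_mmoll,hdl_mgdl,ldl_mgdl,"
              "sbp1_mmhg,sbp2_mmhg,sbp3_mmhg,dbp_avg_mmhg,bp_treated,"
              "diabetes,smoker_current,bmi_kgm2,prior_mi,prior_stroke,"
              "on_statin,fam_hx_premature_chd,hiv")
    row = "P1,52,female,5.0,55,130,130,128,126,80,0,0,0,27,0,0,0,0,0"
    records, rejects = read_cohort(_csv([row], header=header))
    assert rejects.empty
    assert records[0].total_cholesterol == pytest.approx(5.0 * 38.67)


def test_exclusion_cascade_order_and_reconciliation():
    cohort = [
        make_record(participant_id="incomplete", total_cholesterol=None),
        make_record(participant_id="young_on_statin", age=35, on_statin=True),
        make_record(participant_id="statin", on_statin=True),
        make_record(participant_id="stroke", prior_stroke=True),
        make_record(participant_id="ok1"),
        make_record(participant_id="ok2", sex="male"),
        make_record(participant_id="ok3", age=71),
    ]
    kept, report = apply_inclusion_filters(cohort)
    assert [r.participant_id for r in kept] == ["ok1", "ok2", "ok3"]
    # a record failing several criteria is counted once, at its first step
    assert report.incomplete == 1
    assert report.age_under_40 == 1
    assert report.on_statin == 1
    assert report.prior_mi_stroke == 1
    assert report.n_final == 3
    assert report.reconciles()
    assert report.reasons["young_on_statin"] == "age_under_40"


def test_filters_idempotent_and_order_equivariant():
    cohort = [make_record(participant_id=f"P{i}", age=38 + i)
              for i in range(8)]
    cohort[3] = make_record(participant_id="P3", prior_mi=True)
    once, rep1 = apply_inclusion_filters(cohort)
    twice, rep2 = apply_inclusion_filters(once)
    assert [r.participant_id for r in twice] == [r.participant_id for r in once]
    assert rep2.n_input == rep2.n_final

    rev, _ = apply_inclusion_filters(list(reversed(cohort)))
    assert sorted(r.participant_id for r in rev) == \
        sorted(r.participant_id for r in once)
    assert [r.participant_id for r in rev] == \
        [r.participant_id for r in reversed(once)]


def test_empty_input_gives_empty_output():
    kept, report = apply_inclusion_filters([])
    assert kept == [] and report.n_input == report.n_final == 0


@pytest.mark.parametrize("kw, expect_htn", [
    (dict(sbp2=146, sbp3=144, bp_treated=False), True),   # SBP >= 140
    (dict(sbp2=120, sbp3=120, dbp_avg=80.0), False),
    (dict(sbp2=120, sbp3=120, bp_treated=True), True),    # via treatment
    (dict(sbp2=120, sbp3=120, dbp_avg=92.0), True),       # via DBP
])
def test_hypertension_flag(kw, expect_htn):
    rec = derive_flags(make_record(**kw))
    assert rec.hypertension is expect_htn


def test_roundtrip_frame_preserves_records(small_cohort):
    frame = records_to_frame(small_cohort)
    records, rejects = read_cohort(io.StringIO(frame.to_csv(index=False)))
    assert rejects.empty
    assert len(records) == len(small_cohort)
    for a, b in zip(records, small_cohort):
        assert a.participant_id == b.participant_id
        assert a.sbp_avg == pytest.approx(b.sbp_avg)
        assert a.total_cholesterol == pytest.approx(b.total_cholesterol)
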