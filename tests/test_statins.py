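"""Statin-eligibility rules: per-criterion decision tables, the WHO
high-category identity, and monotonicity in risk."""

import pandas as pd
import pytest

from cvdcompare import (count_framingham_risk_factors, statin_decisions,
                        statin_eligible_framingham, statin_eligible_pce_family,
                        statin_eligible_who)
from cvdcompare.statins import DecisionError, eligibility_table, \
    who_identity_holds
from cvdcompare import derive_flags
from conftest import make_record


def rec(**kw):
    return derive_flags(make_record(**kw))


@pytest.mark.parametrize("kw, risk, eligible, criterion", [
    (dict(ldl=200), 0.01, True, "ldl_ge_190"),
    (dict(ldl=80, diabetes=True), 0.02, True, "diabetes_ldl_ge_70"),
    (dict(ldl=80), 0.08, True, "risk_ge_7.5_ldl_ge_70"),
    (dict(ldl=60, diabetes=True), 0.30, False, None),  # all need LDL >= 70
    (dict(ldl=75), 0.074, False, None),
])
def test_pce_family_criteria_fire_in_printed_order(kw, risk, eligible,
                                                   criterion):
    d = statin_eligible_pce_family(rec(**kw), risk)
    assert d.eligible is eligible and d.criterion == criterion


@pytest.mark.parametrize("kw, risk, eligible, criterion", [
    (dict(ldl=195), 0.01, True, "ldl_ge_190"),
    (dict(ldl=105, diabetes=True), 0.01, True, "diabetes_ldl_ge_100"),
    (dict(ldl=105), 0.25, True, "risk_ge_20_ldl_ge_100"),
    # criterion 4 needs >= 2 risk factors; male 55 smoker has age + smoking
    (dict(ldl=135, sex="male", smoker=True), 0.15, True,
     "risk_10_20_ldl_ge_130_rf_ge_2"),
    (dict(ldl=165, sex="male", smoker=True), 0.05, True,
     "risk_lt_10_ldl_ge_160_rf_ge_2"),
    (dict(ldl=165, sex="female"), 0.05, False, None),  # only 1 factor (age)
    (dict(ldl=135, sex="female"), 0.15, False, None),
    (dict(ldl=95), 0.25, False, None),
])
def test_framingham_criteria_fire_in_printed_order(kw, risk, eligible,
                                                   criterion):
    d = statin_eligible_framingham(rec(age=56, **kw), risk)
    assert d.eligible is eligible and d.criterion == criterion


def test_framingham_band_boundaries():
    # 10-20% band is [0.10, 0.20): criteria 3/4/5 partition the risk axis
    base = dict(ldl=135, sex="male", smoker=True)
    assert statin_eligible_framingham(rec(age=56, **base), 0.10).criterion \
        == "risk_10_20_ldl_ge_130_rf_ge_2"  # left-closed at 10%
    d = statin_eligible_framingham(rec(age=56, **base), 0.20)
    assert d.criterion == "risk_ge_20_ldl_ge_100"  # 20% belongs to criterion 3
    d2 = statin_eligible_framingham(rec(age=56, ldl=95, sex="male",
                                        smoker=True), 0.20)
    assert d2.criterion is None  # at 20% the band criteria no longer apply


@pytest.mark.parametrize("risk, eligible", [
    (0.21, True), (0.19, False), (0.20, True)])
def test_who_rule_threshold(risk, eligible):
    assert statin_eligible_who("P1", risk).eligible is eligible


@pytest.mark.parametrize("kw, expected", [
    (dict(sex="male", age=50, smoker=True, hdl=35), 3),
    (dict(sex="female", age=50), 0),     # female age cut is 55
    (dict(sex="male", age=50, smoker=True, hdl=35, sbp2=150, sbp3=150,
          fam_hx_premature_chd=True), 5),  # all factors, male: max is 5
    (dict(sex="female", age=60, smoker=True, hdl=35, sbp2=150, sbp3=150,
          fam_hx_premature_chd=True), 5),
])
def test_framingham_risk_factor_count(kw, expected):
    assert count_framingham_risk_factors(rec(**kw)) == expected


def test_missing_ldl_is_a_decision_error():
    with pytest.raises(DecisionError, match="LDL"):
        statin_eligible_pce_family(rec(ldl=None), 0.1)


def test_decisions_monotone_in_risk():
    """Raising risk never flips eligible -> ineligible in any family."""
    grid = [i / 100 for i in range(0, 100, 3)]
    for fn, r in [
        (statin_eligible_pce_family, rec(ldl=120)),
        (statin_eligible_framingham, rec(ldl=135, sex="male", age=60,
                                         smoker=True)),
        (statin_eligible_who, rec()),
    ]:
        flags = [fn(r, g).eligible for g in grid]
        assert flags == sorted(flags)


def test_cohort_decisions_match_per_participant_evaluation(small_cohort,
                                                           small_scores):
    decisions = statin_decisions(small_cohort, small_scores)
    assert len(decisions) == len(small_scores)
    # brute-force re-evaluation per cell
    from cvdcompare.statins import RULE_FAMILY, _FAMILY_FN
    by_id = {r.participant_id: r for r in small_cohort}
    for _, row in small_scores.iterrows():
        d = _FAMILY_FN[RULE_FAMILY[row["model_id"]]](
            by_id[row["participant_id"]], row["risk10y"],
            model_id=row["model_id"])
        got = decisions[
            (decisions["participant_id"] == row["participant_id"])
            & (decisions["model_id"] == row["model_id"])].iloc[0]
        assert bool(got["eligible"]) == d.eligible

    # WHO eligibility coincides exactly with the WHO high category
    assert who_identity_holds(decisions, small_scores)

    table = eligibility_table(decisions)
    assert (table["eligible"] <= table["n"]).all()
    assert (table["ci_low_pct"] <= table["pct"]).all()
    assert (table["pct"] <= table["ci_high_pct"]).all()


def test_pce_high_category_with_ldl_ge_70_is_always_eligible(small_cohort,
                                                             small_scores):
    from cvdcompare import MODEL_SPECIFIC, categorize
    decisions = statin_decisions(small_cohort, small_scores)
    by_id = {r.participant_id: r for r in small_cohort}
    sub = small_scores[small_scores["model_id"] == "pce"]
    dec = decisions[decisions["model_id"] == "pce"].set_index("participant_id")
    for _, row in sub.iterrows():
        if categorize(row["risk10y"], "pce", MODEL_SPECIFIC) == "high" \
                and by_id[row["participant_id"]].ldl >= 70:
            assert dec.loc[row["participant_id"], "eligible"] == 1
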