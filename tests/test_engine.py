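"""Risk engine: closed forms, published worked examples, determinism,
monotonicity over the plausible covariate domain, and known quirks."""

import math

import numpy as np
import pytest

from cvdcompare import ScoringError, cox_risk, logistic_risk, score_cohort
from cvdcompare.engine import linear_predictor, score_participant
from cvdcompare.registry import ModelSpec, coefficient_checksum

import _oracle
from conftest import make_record


def _single_term_spec(**term):
    raw = {
        "model_id": "pce", "name": "toy", "form": "cox",
        "source": "synthetic single-term spec for unit tests",
        "retrieved": "2026-09-28", "age_range": [40, 79],
        "strata": [{"sex": "female", "baseline_survival": 0.95,
                    "mean_lp": 0.0, "terms": [term]}],
    }
    raw["coefficient_checksum"] = coefficient_checksum(raw)
    return ModelSpec.model_validate(raw)


def test_linear_predictor_single_log_term():
    spec = _single_term_spec(covariate="age", transform="log", coefficient=1.0)
    rec = make_record(age=60)
    lp = linear_predictor(spec, spec.strata[0], rec)
    assert lp == pytest.approx(math.log(60))


def test_linear_predictor_zero_coefficients_give_zero():
    spec = _single_term_spec(covariate="age", transform="log", coefficient=0.0)
    rec = make_record()
    assert linear_predictor(spec, spec.strata[0], rec) == 0.0


def test_missing_covariate_names_model_and_covariate(registry):
    rec = make_record(total_cholesterol=None)
    with pytest.raises(ScoringError, match="total_cholesterol.*pce"):
        score_participant(registry["pce"], rec)


def test_cox_risk_closed_forms():
    assert cox_risk(1.7, 0.95, 1.7) == pytest.approx(0.05)
    assert cox_risk(math.log(2), 0.95, 0.0) == pytest.approx(1 - 0.95 ** 2)
    with pytest.raises(ValueError):
        cox_risk(0.0, 1.2, 0.0)


def test_logistic_risk_closed_forms_and_limit():
    assert logistic_risk(0.0) == 0.5
    assert logistic_risk(math.log(1 / 3)) == pytest.approx(0.25)
    vals = [logistic_risk(lp) for lp in (-1, -5, -20, -100)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert vals[-1] < 1e-40


# The ACC/AHA guideline publishes four worked examples at a common
# reference profile (age 55, TC 213, HDL 50, SBP 120 untreated, nonsmoker,
# nondiabetic): 2.1% / 3.0% white/African-American women, 5.3% / 6.1%
# white/African-American men.  Small differences come from the guideline's
# rounding of intermediate sums.
@pytest.mark.parametrize("sex, ancestry, printed", [
    ("female", "white", 0.021),
    ("female", "black", 0.030),
    ("male", "white", 0.053),
    ("male", "black", 0.061),
])
def test_pce_reproduces_published_worked_examples(registry, sex, ancestry,
                                                  printed):
    rec = make_record(sex=sex, age=55, total_cholesterol=213, hdl=50,
                      sbp1=120, sbp2=120, sbp3=120)
    s = score_participant(registry["pce"], rec, ancestry=ancestry)
    assert s.risk == pytest.approx(printed, abs=1e-3)


def test_framingham_reproduces_published_worked_example(registry):
    # 61-year-old woman, TC 180, HDL 47, SBP 124 untreated, smoker,
    # nondiabetic -> 10.5% in the source publication.
    rec = make_record(age=61, total_cholesterol=180, hdl=47,
                      sbp1=124, sbp2=124, sbp3=124, smoker=True)
    s = score_participant(registry["framingham_lipids"], rec)
    assert s.risk == pytest.approx(0.105, abs=1e-3)


def test_who_lipid_model_converts_units(registry):
    # evaluating with TC given in mg/dL must match the oracle computed in
    # the model's native mmol/L
    rec = make_record(total_cholesterol=232.02)  # exactly 6.0 mmol/L
    s = score_participant(registry["who_lipids"], rec)
    assert s.risk == pytest.approx(_oracle.evaluate("who_lipids", rec),
                                   rel=1e-9)


def test_sex_switches_stratum(registry):
    for mid, spec in registry.items():
        f = score_participant(spec, make_record(sex="female"))
        m = score_participant(spec, make_record(sex="male"))
        assert f.risk != m.risk, mid


def test_out_of_range_age_warns_but_scores(registry):
    rec = make_record(age=78)  # inside PCE range, outside Framingham's 30-74
    s = score_participant(registry["framingham_lipids"], rec)
    assert 0 < s.risk < 1
    assert any("outside model range" in w for w in s.warnings)
    assert not score_participant(registry["pce"], rec).warnings


def test_score_cohort_shape_range_and_determinism(small_cohort, registry):
    scores = score_cohort(small_cohort[:20], specs=registry)
    assert len(scores) == 20 * 6
    assert (scores["error"] == "").all()
    assert scores["risk10y"].between(0, 1).all()
    again = score_cohort(small_cohort[:20], specs=registry)
    assert scores.equals(again)  # bitwise-identical purity
    # identical twin records give identical rows
    twin = small_cohort[0].model_copy(update={"participant_id": "TWIN"})
    two = score_cohort([small_cohort[0], twin], specs=registry)
    a = two[two["participant_id"] == small_cohort[0].participant_id]
    b = two[two["participant_id"] == "TWIN"]
    assert np.allclose(a["risk10y"].values, b["risk10y"].values)


def _risk(spec, rec, **overrides):
    return score_participant(spec, rec.model_copy(update=overrides)).risk


def test_risk_monotone_in_sbp_and_smoking_over_plausible_domain(registry):
    """Raising SBP (90->200) or switching smoking on never lowers risk."""
    rng = np.random.default_rng(7)
    for mid, spec in registry.items():
        for _ in range(150):
            rec = make_record(
                participant_id="m",
                sex=("female", "male")[rng.integers(2)],
                age=float(rng.uniform(40, 79)),
                total_cholesterol=float(rng.uniform(130, 320)),
                hdl=float(rng.uniform(20, 100)),
                bmi=float(rng.uniform(18, 45)),
                bp_treated=bool(rng.integers(2)),
                diabetes=bool(rng.integers(2)),
                smoker=bool(rng.integers(2)),
            )
            sbps = np.linspace(90, 200, 6)
            risks = [_risk(spec, rec, sbp1=s, sbp2=s, sbp3=s) for s in sbps]
            assert all(b >= a - 1e-12 for a, b in zip(risks, risks[1:])), mid
            assert _risk(spec, rec, smoker=True) >= \
                _risk(spec, rec, smoker=False) - 1e-12, mid


def test_pce_age_nonmonotonicity_quirk_is_real(registry):
    """The published PCE coefficients are non-monotone in age for treated
    high-SBP low-HDL profiles in the African-American women stratum (the
    ln(age) x ln(SBP) interaction dominates).  Documented model property;
    both transcriptions must agree on it."""
    rec = make_record(sbp1=180, sbp2=180, sbp3=180, bp_treated=True, hdl=30,
                      total_cholesterol=200)
    young = _risk(registry["pce"], rec, age=50.0)
    old = _risk(registry["pce"], rec, age=70.0)
    assert old < young
    assert _oracle.evaluate("pce", rec.model_copy(update={"age": 70.0})) < \
        _oracle.evaluate("pce", rec.model_copy(update={"age": 50.0}))
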