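import pandas as pd
import pytest

from cvdcompare import (CohortMarginals, ParticipantRecord, generate_cohort,
                        load_registry, prepare_cohort, score_cohort)


def make_record(**overrides) -> ParticipantRecord:
    """A plausible middle-aged participant; override any field."""
    base = dict(
        participant_id="P1", age=55.0, sex="female",
        total_cholesterol=200.0, hdl=50.0, ldl=120.0,
        sbp1=130.0, sbp2=126.0, sbp3=124.0, dbp_avg=78.0,
        bp_treated=False, diabetes=False, smoker=False, bmi=26.0,
        prior_mi=False, prior_stroke=False, on_statin=False,
        fam_hx_premature_chd=False, hiv=False,
    )
    base.update(overrides)
    return ParticipantRecord(**base)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def small_cohort():
    """120 prepared synthetic participants (flags derived)."""
    records = generate_cohort(CohortMarginals(), seed=42, n=120)
    analytic, _ = prepare_cohort(records)
    return analytic


@pytest.fixture(scope="session")
def small_scores(small_cohort, registry) -> pd.DataFrame:
    return score_cohort(small_cohort, specs=registry)
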