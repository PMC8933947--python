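"""Statin-eligibility decision rules for primary prevention.

Three rule families, matched to the model that produced the risk estimate:

* PCE family (PCE, adjusted PCE): LDLc >= 190 mg/dL; or diabetes with
  LDLc >= 70; or 10-year risk >= 7.5% with LDLc >= 70.
* Framingham family (both Framingham versions): LDLc >= 190; or diabetes
  with LDLc >= 100; or risk >= 20% with LDLc >= 100; or risk in [10%, 20%)
  with LDLc >= 130 and >= 2 risk factors; or risk < 10% with LDLc >= 160
  and >= 2 risk factors.  Risk factors: current smoking, hypertension,
  HDLc < 40 mg/dL, MI/angina in a first-degree relative before age 50,
  and age >= 45 (men) / >= 55 (women).
* WHO family (both WHO versions): risk >= 20%.

Criteria are evaluated in their printed order and the first criterion that
fires is recorded; eligibility itself is order-invariant (a disjunction).
The 10–20% band of Framingham criterion 4 is [0.10, 0.20) so criteria
3/4/5 partition the risk axis.  Participants already on statins are
excluded upstream and never reach these rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .categorize import MODEL_SPECIFIC, categorize
from .cohort import ParticipantRecord
from .stats import wilson_ci

log = logging.getLogger(__name__)

#: rule family per model id
RULE_FAMILY = {
    "pce": "pce",
    "apce": "pce",
    "framingham_lipids": "framingham",
    "framingham_bmi": "framingham",
    "who_lipids": "who",
    "who_bmi": "who",
}


class DecisionError(ValueError):
    """A statin decision cannot be made (missing LDL cholesterol)."""


@dataclass(frozen=True)
class StatinDecision:
    participant_id: str
    model_id: str
    eligible: bool
    criterion: Optional[str]  # first criterion fired, None if ineligible

    def __post_init__(self):
        assert self.eligible == (self.criterion is not None)


def _require_ldl(record: ParticipantRecord, model_id: str) -> float:
    if record.ldl is None:
        raise DecisionError(
            f"{record.participant_id}: LDL cholesterol required for "
            f"{model_id} statin rule")
    return record.ldl


def statin_eligible_pce_family(record: ParticipantRecord, risk: float,
                               model_id: str = "pce") -> StatinDecision:
    ldl = _require_ldl(record, model_id)
    crit = None
    if ldl >= 190:
        crit = "ldl_ge_190"
    elif record.diabetes and ldl >= 70:
        crit = "diabetes_ldl_ge_70"
    elif risk >= 0.075 and ldl >= 70:
        crit = "risk_ge_7.5_ldl_ge_70"
    return StatinDecision(record.participant_id, model_id, crit is not None, crit)


def count_framingham_risk_factors(record: ParticipantRecord) -> int:
    """Count of the Framingham treatment-rule risk factors (0..5).

    The two age criteria are sex-specific, so at most one contributes.
    Missing family history counts as absent (warned upstream); a missing
    hypertension flag means :func:`~cvdcompare.cohort.derive_flags` was not
    applied and is an error.
    """
    if record.hypertension is None:
        raise DecisionError(
            f"{record.participant_id}: hypertension flag not derived")
    n = 0
    n += record.smoker
    n += record.hypertension
    n += record.hdl is not None and record.hdl < 40
    n += bool(record.fam_hx_premature_chd)
    if record.sex == "male":
        n += record.age >= 45
    else:
        n += record.age >= 55
    return int(n)


def statin_eligible_framingham(record: ParticipantRecord, risk: float,
                               model_id: str = "framingham_lipids"
                               ) -> StatinDecision:
    ldl = _require_ldl(record, model_id)
    rf = count_framingham_risk_factors(record)
    crit = None
    if ldl >= 190:
        crit = "ldl_ge_190"
    elif record.diabetes and ldl >= 100:
        crit = "diabetes_ldl_ge_100"
    elif risk >= 0.20 and ldl >= 100:
        crit = "risk_ge_20_ldl_ge_100"
    elif 0.10 <= risk < 0.20 and ldl >= 130 and rf >= 2:
        crit = "risk_10_20_ldl_ge_130_rf_ge_2"
    elif risk < 0.10 and ldl >= 160 and rf >= 2:
        crit = "risk_lt_10_ldl_ge_160_rf_ge_2"
    return StatinDecision(record.participant_id, model_id, crit is not None, crit)


def statin_eligible_who(record_or_id, risk: float,
                        model_id: str = "who_lipids") -> StatinDecision:
    """WHO rule: eligible iff 10-year risk >= 20% (boundary included)."""
    pid = (record_or_id.participant_id
           if isinstance(record_or_id, ParticipantRecord) else str(record_or_id))
    crit = "risk_ge_20" if risk >= 0.20 else None
    return StatinDecision(pid, model_id, crit is not None, crit)


_FAMILY_FN = {
    "pce": statin_eligible_pce_family,
    "framingham": statin_eligible_framingham,
    "who": statin_eligible_who,
}


def statin_decisions(records: Iterable[ParticipantRecord],
                     scores: pd.DataFrame) -> pd.DataFrame:
    """Apply each model's rule family to its own risk estimates.

    Tidy output: participant_id, model_id, eligible (0/1), criterion.
    """
    by_id = {r.participant_id: r for r in records}
    rows = []
    for _, row in scores.iterrows():
        rec = by_id[row["participant_id"]]
        fam = RULE_FAMILY[row["model_id"]]
        d = _FAMILY_FN[fam](rec, row["risk10y"], model_id=row["model_id"])
        rows.append({"participant_id": d.participant_id,
                     "model_id": d.model_id,
                     "eligible": int(d.eligible),
                     "criterion": d.criterion or ""})
    return pd.DataFrame(rows, columns=["participant_id", "model_id",
                                       "eligible", "criterion"])


def eligibility_table(decisions: pd.DataFrame, level: float = 0.95
                      ) -> pd.DataFrame:
    """Per-model eligible counts, proportions and Wilson intervals."""
    order = decisions["model_id"].drop_duplicates().tolist()
    out = []
    for mid in order:
        sub = decisions[decisions["model_id"] == mid]
        n = len(sub)
        k = int(sub["eligible"].sum())
        lo, hi = wilson_ci(k, n, level=level)
        out.append({"model_id": mid, "eligible": k, "n": n,
                    "pct": 100.0 * k / n,
                    "ci_low_pct": 100.0 * lo, "ci_high_pct": 100.0 * hi})
    return pd.DataFrame(out).set_index("model_id")


def who_identity_holds(decisions: pd.DataFrame, scores: pd.DataFrame) -> bool:
    """WHO eligibility coincides with the WHO high category under
    model-specific thresholds (both are risk >= 20%); true by construction,
    checked exactly."""
    for mid in ("who_lipids", "who_bmi"):
        sub = scores[scores["model_id"] == mid]
        dec = decisions[decisions["model_id"] == mid].set_index("participant_id")
        for _, row in sub.iterrows():
            high = categorize(row["risk10y"], mid, MODEL_SPECIFIC) == "high"
            if bool(dec.loc[row["participant_id"], "eligible"]) != high:
                return False
    return True
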