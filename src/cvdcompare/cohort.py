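"""Cohort ingestion and preparation.

Implements the study's measurement conventions and analytic-sample rules:
the blood-pressure value used everywhere is the mean of the second and
third seated readings (the first reading is discarded), and the analytic
sample is built by a sequential exclusion cascade — incomplete model
inputs, then age < 40, then current statin use, then prior myocardial
infarction or stroke — with each participant counted once at the first
step that removes them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .units import convert_units

log = logging.getLogger(__name__)

#: Cohort CSV schema, version 1.  Booleans are 0/1.
COHORT_COLUMNS = [
    "participant_id",
    "age_years",
    "sex",
    "tc_mgdl",
    "hdl_mgdl",
    "ldl_mgdl",
    "sbp1_mmhg",
    "sbp2_mmhg",
    "sbp3_mmhg",
    "dbp_avg_mmhg",
    "bp_treated",
    "diabetes",
    "smoker_current",
    "bmi_kgm2",
    "prior_mi",
    "prior_stroke",
    "on_statin",
    "fam_hx_premature_chd",
    "hiv",
]

#: Alternative lipid columns a file may declare instead of the mg/dL ones.
_MMOLL_LIPIDS = {"tc_mmoll": "tc_mgdl", "hdl_mmoll": "hdl_mgdl", "ldl_mmoll": "ldl_mgdl"}

_REQUIRED_COLUMNS = {"participant_id", "age_years", "sex"}

SCHEMA_VERSION = 1


class ParticipantRecord(BaseModel):
    """One adult's risk-factor profile — the covariate vector every model reads.

    Continuous measurements are canonical units: lipids mg/dL, pressures
    mmHg, BMI kg/m^2.  ``sbp_avg`` is derived (mean of readings 2 and 3),
    never supplied.  ``hypertension`` is set by :func:`derive_flags`.
    """

    model_config = ConfigDict(validate_assignment=True)

    participant_id: str
    age: float
    sex: Literal["female", "male"]
    total_cholesterol: Optional[float] = None
    hdl: Optional[float] = None
    ldl: Optional[float] = None
    sbp1: Optional[float] = None
    sbp2: Optional[float] = None
    sbp3: Optional[float] = None
    dbp_avg: Optional[float] = None
    bp_treated: bool = False
    diabetes: bool = False
    smoker: bool = False
    bmi: Optional[float] = None
    prior_mi: bool = False
    prior_stroke: bool = False
    on_statin: bool = False
    fam_hx_premature_chd: Optional[bool] = None
    hiv: bool = False
    hypertension: Optional[bool] = None

    @model_validator(mode="after")
    def _invariants(self) -> "ParticipantRecord":
        if not self.age > 0:
            raise ValueError("age must be positive")
        for name in ("total_cholesterol", "hdl", "ldl", "sbp1", "sbp2", "sbp3",
                     "dbp_avg", "bmi"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        return self

    @property
    def sbp_avg(self) -> Optional[float]:
        """Mean of the second and third SBP readings (first discarded)."""
        if self.sbp2 is None or self.sbp3 is None:
            return None
        return average_bp(self.sbp1, self.sbp2, self.sbp3)

    @property
    def chol_ratio(self) -> Optional[float]:
        if self.total_cholesterol is None or self.hdl is None:
            return None
        return self.total_cholesterol / self.hdl

    def is_complete(self) -> bool:
        """All covariates any of the six models or statin rules need."""
        needed = (self.total_cholesterol, self.hdl, self.ldl,
                  self.sbp2, self.sbp3, self.bmi)
        return all(v is not None for v in needed)


@dataclass
class ExclusionReport:
    """Counts removed at each step of the sequential exclusion cascade."""

    n_input: int = 0
    incomplete: int = 0
    age_under_40: int = 0
    on_statin: int = 0
    prior_mi_stroke: int = 0
    n_final: int = 0
    reasons: dict[str, str] = field(default_factory=dict)  # participant_id -> step

    def reconciles(self) -> bool:
        removed = (self.incomplete + self.age_under_40
                   + self.on_statin + self.prior_mi_stroke)
        return self.n_input - removed == self.n_final


def average_bp(reading1: Optional[float], reading2: float, reading3: float) -> float:
    """Analysis blood pressure: arithmetic mean of readings 2 and 3.

    The first reading is discarded (it is systematically elevated); it may
    be passed for interface symmetry but never enters the average.
    """
    if reading2 is None or reading3 is None:
        raise ValueError("BP readings 2 and 3 are required")
    if not (reading2 > 0 and reading3 > 0):
        raise ValueError("BP readings must be positive")
    return (reading2 + reading3) / 2.0


def read_cohort(path: "str | Path", schema_version: int = SCHEMA_VERSION
                ) -> tuple[list[ParticipantRecord], pd.DataFrame]:
    """Read a cohort CSV into validated records plus a reject table.

    Rows violating record invariants are returned in the reject frame with
    a ``reason`` column rather than raised.  Unknown columns warn; missing
    required columns fail.  Lipid columns declared in mmol/L (``tc_mmoll``
    etc.) are converted to mg/dL on load.
    """
    if schema_version != SCHEMA_VERSION:
        raise ValueError(f"unsupported cohort schema version: {schema_version}")
    df = pd.read_csv(path)
    missing = _REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing required columns: {sorted(missing)}")
    for mmoll_col, mgdl_col in _MMOLL_LIPIDS.items():
        if mmoll_col in df.columns:
            df[mgdl_col] = df[mmoll_col].map(
                lambda v: convert_units(v, "cholesterol", "mmol/L", "mg/dL")
                if pd.notna(v) else v
            )
            df = df.drop(columns=[mmoll_col])
    unknown = set(df.columns) - set(COHORT_COLUMNS)
    if unknown:
        warnings.warn(f"ignoring unknown cohort columns: {sorted(unknown)}",
                      stacklevel=2)
        df = df.drop(columns=sorted(unknown))

    records: list[ParticipantRecord] = []
    rejects: list[dict] = []
    for idx, row in df.iterrows():
        try:
            records.append(_row_to_record(row))
        except (ValueError, TypeError) as exc:
            rejects.append({"row": idx,
                            "participant_id": row.get("participant_id"),
                            "reason": str(exc)})
    return records, pd.DataFrame(rejects, columns=["row", "participant_id", "reason"])


def _opt(row: pd.Series, col: str) -> Optional[float]:
    v = row.get(col)
    if v is None or pd.isna(v):
        return None
    return float(v)


def _optbool(row: pd.Series, col: str, default: Optional[bool] = False
             ) -> Optional[bool]:
    v = row.get(col)
    if v is None or pd.isna(v):
        return default
    return bool(int(v))


def _row_to_record(row: pd.Series) -> ParticipantRecord:
    sex = str(row["sex"]).strip().lower()
    if sex in ("f", "0"):
        sex = "female"
    elif sex in ("m", "1"):
        sex = "male"
    return ParticipantRecord(
        participant_id=str(row["participant_id"]),
        age=float(row["age_years"]),
        sex=sex,
        total_cholesterol=_opt(row, "tc_mgdl"),
        hdl=_opt(row, "hdl_mgdl"),
        ldl=_opt(row, "ldl_mgdl"),
        sbp1=_opt(row, "sbp1_mmhg"),
        sbp2=_opt(row, "sbp2_mmhg"),
        sbp3=_opt(row, "sbp3_mmhg"),
        dbp_avg=_opt(row, "dbp_avg_mmhg"),
        bp_treated=_optbool(row, "bp_treated"),
        diabetes=_optbool(row, "diabetes"),
        smoker=_optbool(row, "smoker_current"),
        bmi=_opt(row, "bmi_kgm2"),
        prior_mi=_optbool(row, "prior_mi"),
        prior_stroke=_optbool(row, "prior_stroke"),
        on_statin=_optbool(row, "on_statin"),
        fam_hx_premature_chd=_optbool(row, "fam_hx_premature_chd", default=None),
        hiv=_optbool(row, "hiv"),
    )


def apply_inclusion_filters(records: Iterable[ParticipantRecord]
                            ) -> tuple[list[ParticipantRecord], ExclusionReport]:
    """Build the analytic sample via the sequential exclusion cascade.

    Order: incomplete model inputs, then age < 40, then current statin use,
    then prior MI/stroke.  A record failing several criteria is counted
    once, at the first failing step, so the step counts are mutually
    exclusive and reconcile with the input and output sizes.
    """
    records = list(records)
    report = ExclusionReport(n_input=len(records))
    kept: list[ParticipantRecord] = []
    for rec in records:
        if not rec.is_complete():
            report.incomplete += 1
            report.reasons[rec.participant_id] = "incomplete"
        elif rec.age < 40:
            report.age_under_40 += 1
            report.reasons[rec.participant_id] = "age_under_40"
        elif rec.on_statin:
            report.on_statin += 1
            report.reasons[rec.participant_id] = "on_statin"
        elif rec.prior_mi or rec.prior_stroke:
            report.prior_mi_stroke += 1
            report.reasons[rec.participant_id] = "prior_mi_stroke"
        else:
            kept.append(rec)
    report.n_final = len(kept)
    assert report.reconciles()
    return kept, report


def derive_flags(record: ParticipantRecord) -> ParticipantRecord:
    """Return a copy with the hypertension flag set.

    Hypertension = on antihypertensive treatment OR averaged SBP >= 140
    mmHg OR averaged DBP >= 90 mmHg.  The treated/untreated SBP split the
    models need is resolved at scoring time from ``bp_treated``.
    """
    if record.sbp_avg is None:
        raise ValueError(f"{record.participant_id}: averaged SBP required "
                         f"before deriving flags")
    htn = bool(
        record.bp_treated
        or record.sbp_avg >= 140
        or (record.dbp_avg is not None and record.dbp_avg >= 90)
    )
    if record.fam_hx_premature_chd is None:
        log.warning("%s: family history missing; treated as absent",
                    record.participant_id)
    return record.model_copy(update={"hypertension": htn})


def prepare_cohort(records: Iterable[ParticipantRecord]
                   ) -> tuple[list[ParticipantRecord], ExclusionReport]:
    """Filters + derived flags in one step (the usual entry point)."""
    kept, report = apply_inclusion_filters(records)
    return [derive_flags(r) for r in kept], report


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Records in the cohort CSV schema (round-trips through read_cohort)."""
    rows = []
    for r in records:
        rows.append({
            "participant_id": r.participant_id,
            "age_years": r.age,
            "sex": r.sex,
            "tc_mgdl": r.total_cholesterol,
            "hdl_mgdl": r.hdl,
            "ldl_mgdl": r.ldl,
            "sbp1_mmhg": r.sbp1,
            "sbp2_mmhg": r.sbp2,
            "sbp3_mmhg": r.sbp3,
            "dbp_avg_mmhg": r.dbp_avg,
            "bp_treated": int(r.bp_treated),
            "diabetes": int(r.diabetes),
            "smoker_current": int(r.smoker),
            "bmi_kgm2": r.bmi,
            "prior_mi": int(r.prior_mi),
            "prior_stroke": int(r.prior_stroke),
            "on_statin": int(r.on_statin),
            "fam_hx_premature_chd": ("" if r.fam_hx_premature_chd is None
                                     else int(r.fam_hx_premature_chd)),
            "hiv": int(r.hiv),
        })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
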