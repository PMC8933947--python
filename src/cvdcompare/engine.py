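"""Risk-equation evaluation engine.

Evaluates a declarative :class:`~cvdcompare.registry.ModelSpec` on a
:class:`~cvdcompare.cohort.ParticipantRecord`:

* linear predictor  LP = sum_j beta_j * f_j(x_j) * prod_k g_jk(x_jk)
* Cox baseline-survival risk  p = 1 - S0 ** exp(LP - mean LP)
* logistic risk  p = 1 / (1 + exp(-LP))

Evaluation is deterministic double-precision arithmetic; there are no
stochastic elements.  Participants outside a model's published age range
are scored anyway and flagged, never silently clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .cohort import ParticipantRecord
from .registry import ModelSpec, StratumSpec, TermSpec, load_registry
from .units import convert_units

#: Ancestry stratum applied when a model is ancestry-stratified (PCE) or
#: carries an ancestry indicator (adjusted PCE).  The default follows the
#: study population (majority Black); it is a required, logged run setting,
#: overridable per call.
DEFAULT_ANCESTRY = "black"


class ScoringError(ValueError):
    """A record cannot be scored under a model; names covariate and model."""


@dataclass
class RiskScore:
    """10-year predicted risk of one participant under one model."""

    participant_id: str
    model_id: str
    lp: float
    risk: float
    warnings: tuple[str, ...] = field(default_factory=tuple)


def _covariate_value(record: ParticipantRecord, name: str, spec: ModelSpec,
                     ancestry: str) -> float:
    if name == "one":
        return 1.0
    if name == "age":
        return record.age
    if name == "sbp":
        v = record.sbp_avg
        if v is None:
            raise ScoringError(
                f"{record.participant_id}: averaged SBP missing for model "
                f"{spec.model_id}")
        return v
    if name == "bp_treated":
        return 1.0 if record.bp_treated else 0.0
    if name == "bp_untreated":
        return 0.0 if record.bp_treated else 1.0
    if name == "smoker":
        return 1.0 if record.smoker else 0.0
    if name == "diabetes":
        return 1.0 if record.diabetes else 0.0
    if name == "black":
        return 1.0 if ancestry == "black" else 0.0
    if name in ("total_cholesterol", "hdl", "ldl"):
        v = getattr(record, name if name != "total_cholesterol" else "total_cholesterol")
        if v is None:
            raise ScoringError(
                f"{record.participant_id}: {name} missing for model {spec.model_id}")
        return convert_units(v, "cholesterol", "mg/dL", spec.lipid_units)
    if name == "chol_ratio":
        v = record.chol_ratio
        if v is None:
            raise ScoringError(
                f"{record.participant_id}: cholesterol ratio missing for model "
                f"{spec.model_id}")
        return v
    if name == "bmi":
        if record.bmi is None:
            raise ScoringError(
                f"{record.participant_id}: bmi missing for model {spec.model_id}")
        return record.bmi
    raise ScoringError(f"unknown covariate {name!r}")  # pragma: no cover


def _apply_transform(value: float, transform: str, offset: float,
                     context: str) -> float:
    value = value - offset
    if transform == "identity":
        return value
    if transform == "squared":
        return value * value
    # log transforms
    if value <= 0:
        raise ScoringError(f"non-positive value {value} passed to {transform} "
                           f"transform ({context})")
    lv = math.log(value)
    return lv * lv if transform == "log_squared" else lv


def _term_value(term: TermSpec, record: ParticipantRecord, spec: ModelSpec,
                ancestry: str) -> float:
    ctx = f"model {spec.model_id}, covariate {term.covariate}"
    x = _covariate_value(record, term.covariate, spec, ancestry)
    val = term.coefficient * _apply_transform(x, term.transform, term.offset, ctx)
    for f in term.interactions:
        y = _covariate_value(record, f.covariate, spec, ancestry)
        val *= _apply_transform(y, f.transform, f.offset,
                                f"model {spec.model_id}, covariate {f.covariate}")
    return val


def linear_predictor(spec: ModelSpec, stratum: StratumSpec,
                     record: ParticipantRecord,
                     ancestry: str = DEFAULT_ANCESTRY) -> float:
    """Evaluate one stratum's linear predictor for a participant."""
    return sum(_term_value(t, record, spec, ancestry) for t in stratum.terms)


def cox_risk(lp: float, baseline_survival: float, mean_lp: float) -> float:
    """10-year risk under the Cox baseline-survival form.

    p = 1 - S0 ** exp(LP - mean LP), with S0 the 10-year event-free
    probability at the centering covariate profile.
    """
    if not 0.0 < baseline_survival < 1.0:
        raise ValueError("baseline survival must be in (0, 1)")
    return 1.0 - baseline_survival ** math.exp(lp - mean_lp)


def logistic_risk(lp: float) -> float:
    """10-year risk under the logistic form: p = 1 / (1 + exp(-LP))."""
    if lp >= 0:
        return 1.0 / (1.0 + math.exp(-lp))
    e = math.exp(lp)
    return e / (1.0 + e)


def score_participant(spec: ModelSpec, record: ParticipantRecord,
                      ancestry: str = DEFAULT_ANCESTRY) -> RiskScore:
    """Score one participant under one model."""
    stratum = spec.stratum(record.sex, ancestry)
    lp = linear_predictor(spec, stratum, record, ancestry)
    if spec.form == "cox":
        risk = cox_risk(lp, stratum.baseline_survival, stratum.mean_lp)
    else:
        risk = logistic_risk(lp)
    warn: list[str] = []
    lo, hi = spec.age_range
    if not lo <= record.age <= hi:
        warn.append(f"age {record.age:g} outside model range [{lo:g}, {hi:g}]")
    return RiskScore(record.participant_id, spec.model_id, lp, risk, tuple(warn))


def score_cohort(records: Iterable[ParticipantRecord],
                 model_ids: "list[str] | None" = None,
                 specs: "dict[str, ModelSpec] | None" = None,
                 ancestry: str = DEFAULT_ANCESTRY) -> pd.DataFrame:
    """Score every (participant, model) pair.

    Returns a tidy frame ``participant_id, model_id, lp, risk10y, warnings``
    in input row order (participants) x registry order (models).  Scoring
    failures are recorded per cell in the ``error`` column, never silently
    dropped.
    """
    if specs is None:
        specs = load_registry(model_ids=model_ids)
    rows = []
    for rec in records:
        for mid, spec in specs.items():
            try:
                s = score_participant(spec, rec, ancestry)
                rows.append({"participant_id": rec.participant_id,
                             "model_id": mid, "lp": s.lp, "risk10y": s.risk,
                             "warnings": ";".join(s.warnings), "error": ""})
            except ScoringError as exc:
                rows.append({"participant_id": rec.participant_id,
                             "model_id": mid, "lp": float("nan"),
                             "risk10y": float("nan"), "warnings": "",
                             "error": str(exc)})
    return pd.DataFrame(
        rows, columns=["participant_id", "model_id", "lp", "risk10y",
                       "warnings", "error"])


def scores_wide(scores: pd.DataFrame, value: str = "risk10y") -> pd.DataFrame:
    """Pivot the tidy score table to participants x models (input order)."""
    wide = scores.pivot(index="participant_id", columns="model_id", values=value)
    order = scores["participant_id"].drop_duplicates()
    cols = scores["model_id"].drop_duplicates()
    return wide.loc[order, cols]
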