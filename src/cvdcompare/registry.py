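"""Declarative registry of risk-equation specifications.

Each of the six 10-year CVD risk models is shipped as a human-auditable
YAML file: one document per model carrying its strata (sex, and ancestry
where the model is ancestry-stratified), the term list (coefficient x
transformed covariate, with optional interaction partners), the functional
form (Cox baseline-survival or logistic), and provenance metadata (source
citation, retrieval date, and a checksum over the coefficient block).
Equations are therefore data, not code: a corrected transcription is a
config edit, not a release.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

#: Closed vocabulary of symbolic covariate names a term may reference.
COVARIATES = frozenset(
    {
        "one",  # constant 1.0 (logistic intercepts)
        "age",
        "total_cholesterol",
        "hdl",
        "ldl",
        "chol_ratio",  # total cholesterol / HDL
        "sbp",
        "bp_treated",
        "bp_untreated",
        "smoker",
        "diabetes",
        "bmi",
        "black",  # ancestry indicator (run-time configuration, see engine)
    }
)

TRANSFORMS = frozenset({"identity", "log", "log_squared", "squared"})

MODEL_IDS = (
    "pce",
    "apce",
    "framingham_lipids",
    "framingham_bmi",
    "who_lipids",
    "who_bmi",
)


class SpecError(ValueError):
    """A model config violates the schema; the message names the field."""


class Factor(BaseModel):
    """One multiplicative factor of a term: transform(covariate - offset)."""

    model_config = ConfigDict(extra="forbid")

    covariate: str
    transform: Literal["identity", "log", "log_squared", "squared"] = "identity"
    offset: float = 0.0

    @model_validator(mode="after")
    def _check_vocab(self) -> "Factor":
        if self.covariate not in COVARIATES:
            raise ValueError(f"unknown covariate name: {self.covariate!r}")
        return self


class TermSpec(BaseModel):
    """One additive term of a linear predictor.

    Contributes ``coefficient * f(x) * prod(g(y) for partners)`` where f, g
    are the declared transforms.  Interaction partners cover products such
    as ln(age) x ln(total cholesterol) in the PCE or age x SBP in the
    adjusted PCE.
    """

    model_config = ConfigDict(extra="forbid")

    covariate: str
    transform: Literal["identity", "log", "log_squared", "squared"] = "identity"
    offset: float = 0.0
    interactions: list[Factor] = Field(default_factory=list)
    coefficient: float

    @model_validator(mode="after")
    def _check(self) -> "TermSpec":
        if self.covariate not in COVARIATES:
            raise ValueError(f"unknown covariate name: {self.covariate!r}")
        if not _finite(self.coefficient):
            raise ValueError(f"coefficient for {self.covariate!r} is not finite")
        return self


class StratumSpec(BaseModel):
    """Coefficient set for one sex (x ancestry) stratum of a model."""

    model_config = ConfigDict(extra="forbid")

    sex: Literal["female", "male"]
    ancestry: Optional[Literal["white", "black"]] = None
    baseline_survival: Optional[float] = None  # S0, Cox form only
    mean_lp: Optional[float] = None  # centering constant, Cox form only
    terms: list[TermSpec]

    @model_validator(mode="after")
    def _check(self) -> "StratumSpec":
        if not self.terms:
            raise ValueError(f"stratum {self.key()} has an empty term list")
        return self

    def key(self) -> str:
        return self.sex if self.ancestry is None else f"{self.sex}/{self.ancestry}"


class ModelSpec(BaseModel):
    """Complete declarative description of one 10-year CVD risk equation."""

    model_config = ConfigDict(extra="forbid")

    model_id: str
    name: str
    form: Literal["cox", "logistic"]
    source: str
    retrieved: str
    lipid_units: Literal["mg/dL", "mmol/L"] = "mg/dL"
    sbp_units: Literal["mmHg"] = "mmHg"
    bmi_units: Literal["kg/m^2"] = "kg/m^2"
    age_range: tuple[float, float]
    notes: str = ""
    strata: list[StratumSpec]
    coefficient_checksum: str

    @model_validator(mode="after")
    def _check(self) -> "ModelSpec":
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id: {self.model_id!r}")
        if not self.strata:
            raise ValueError("model has no strata")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be (low, high) with low < high")
        for stratum in self.strata:
            if self.form == "cox":
                s0 = stratum.baseline_survival
                if s0 is None or not 0.0 < s0 < 1.0:
                    raise ValueError(
                        f"baseline_survival must be in (0, 1) for cox stratum "
                        f"{stratum.key()}; got {s0!r}"
                    )
                if stratum.mean_lp is None or not _finite(stratum.mean_lp):
                    raise ValueError(
                        f"mean_lp (centering constant) required for cox stratum "
                        f"{stratum.key()}"
                    )
            else:  # logistic
                if not any(t.covariate == "one" for t in stratum.terms):
                    raise ValueError(
                        f"logistic stratum {stratum.key()} lacks an intercept "
                        f"term (covariate 'one')"
                    )
        keys = [s.key() for s in self.strata]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate stratum keys")
        expected = coefficient_checksum(self)
        if self.coefficient_checksum != expected:
            raise ValueError(
                f"coefficient_checksum mismatch for {self.model_id}: config says "
                f"{self.coefficient_checksum}, coefficient block hashes to {expected}"
            )
        return self

    def stratum(self, sex: str, ancestry: Optional[str] = None) -> StratumSpec:
        """Return the coefficient stratum for a participant.

        Models stratified only by sex ignore ``ancestry``; ancestry-stratified
        models (the PCE) require it.
        """
        candidates = [s for s in self.strata if s.sex == sex]
        if not candidates:
            raise SpecError(f"model {self.model_id} has no stratum for sex={sex!r}")
        if all(s.ancestry is None for s in candidates):
            return candidates[0]
        if ancestry is None:
            raise SpecError(
                f"model {self.model_id} is ancestry-stratified; an ancestry "
                f"setting is required"
            )
        for s in candidates:
            if s.ancestry == ancestry:
                return s
        raise SpecError(
            f"model {self.model_id} has no stratum for sex={sex!r}, "
            f"ancestry={ancestry!r}"
        )


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


def coefficient_checksum(spec: "ModelSpec | dict") -> str:
    """SHA-256 over the canonical JSON of the coefficient block.

    Covers strata keys, S0/centering constants and every term, so any edit
    to a transcribed number invalidates the recorded checksum and forces a
    deliberate re-sign-off.
    """
    if isinstance(spec, ModelSpec):
        strata = [s.model_dump() for s in spec.strata]
    else:
        strata = [StratumSpec.model_validate(s).model_dump() for s in spec["strata"]]
    canonical = json.dumps(strata, sort_keys=True, separators=(",", ":"))
    return "sha256:" + hashlib.sha256(canonical.encode()).hexdigest()


def default_registry_path() -> Path:
    """Directory of the model configs shipped with the package."""
    return Path(str(resources.files("cvdcompare").joinpath("models")))


def load_model_spec(path: "str | Path", model_id: Optional[str] = None) -> ModelSpec:
    """Load and validate one model config file.

    Parameters
    ----------
    path : path-like
        YAML file containing a single model document.
    model_id : str, optional
        If given, the loaded spec must carry this id.

    Raises
    ------
    FileNotFoundError
        Missing config file.
    SpecError
        Schema violation; the message names the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model config not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SpecError(f"{path}: config must be a mapping")
    try:
        spec = ModelSpec.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError or ValueError
        raise SpecError(f"{path}: {exc}") from exc
    if model_id is not None and spec.model_id != model_id:
        raise SpecError(
            f"{path}: expected model id {model_id!r}, file declares "
            f"{spec.model_id!r}"
        )
    return spec


def list_models(registry_path: "str | Path | None" = None) -> list[dict]:
    """List available models with metadata, in stable (index) order.

    Returns a list of dicts with keys ``model_id``, ``name``, ``form``,
    ``strata`` (list of stratum keys) and ``lipid_units``.
    """
    root = Path(registry_path) if registry_path is not None else default_registry_path()
    if not root.is_dir():
        raise FileNotFoundError(f"registry directory not readable: {root}")
    index = root / "index.yaml"
    if index.exists():
        with open(index) as fh:
            files = yaml.safe_load(fh)["models"]
        paths = [root / f for f in files]
    else:
        paths = sorted(root.glob("*.yaml"))
    out = []
    for p in paths:
        spec = load_model_spec(p)
        out.append(
            {
                "model_id": spec.model_id,
                "name": spec.name,
                "form": spec.form,
                "strata": [s.key() for s in spec.strata],
                "lipid_units": spec.lipid_units,
                "path": str(p),
            }
        )
    return out


def load_registry(
    registry_path: "str | Path | None" = None,
    model_ids: "list[str] | None" = None,
) -> dict[str, ModelSpec]:
    """Load all (or selected) model specs keyed by model id, index order."""
    entries = list_models(registry_path)
    specs: dict[str, ModelSpec] = {}
    for e in entries:
        if model_ids is None or e["model_id"] in model_ids:
            specs[e["model_id"]] = load_model_spec(e["path"])
    if model_ids is not None:
        missing = [m for m in model_ids if m not in specs]
        if missing:
            raise SpecError(f"unknown model id(s): {missing}")
        specs = {m: specs[m] for m in model_ids}
    return specs
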