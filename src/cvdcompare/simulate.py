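"""Seeded synthetic cohorts emulating the Haiti CVD Cohort's marginals.

The study's participant-level data are not deposited, so every pipeline
stage is exercised on synthetic cohorts drawn from a Gaussian copula: a
latent multivariate normal is pushed through per-variable monotone maps
(piecewise-linear quantile functions, normal or log-normal marginals,
threshold indicators) chosen so the published marginal summaries are
recovered — proportion female, the age median/IQR (bounded below at 40,
since the generator emulates the analytic sample), and the prevalences of
treatment, diabetes, smoking, obesity, low HDL, high LDL and elevated
blood pressure.  The latent correlations are a modelling choice (the joint
distribution is unpublished): modest positive age–SBP and age–cholesterol
dependence, a strong SBP–DBP and TC–LDL coupling, and
treatment–blood-pressure dependence calibrated once so the derived
hypertension flag (treated OR SBP>=140 OR DBP>=90) matches its published
prevalence.

Three seated SBP readings are emitted per participant: reading noise is
added around a participant-level true SBP, with a small positive bias on
the first reading (which the analysis discards).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import stats as sps

from .cohort import COHORT_COLUMNS, ParticipantRecord, read_cohort

#: draw order of the latent normal components
LATENT_VARS = ["age", "sbp", "dbp", "tc", "hdl", "ldl", "bmi",
               "female", "treated", "diabetes", "smoker"]


class CohortMarginals(BaseModel):
    """Marginal targets and dependence structure for cohort simulation."""

    model_config = ConfigDict(extra="forbid")

    n: int = 1345
    # binary prevalences
    p_female: float = 0.609
    p_bp_treated: float = 0.187
    p_diabetes: float = 0.078
    p_smoker: float = 0.040
    p_prior_mi: float = 0.0
    p_prior_stroke: float = 0.0
    p_on_statin: float = 0.0
    p_fam_hx: float = 0.05
    p_hiv: float = 0.025
    # age: piecewise-linear quantile knots {probability: years}, bounded at 40
    age_quantiles: dict[float, float] = {
        0.0: 40.0, 0.25: 47.0, 0.5: 54.0, 0.75: 62.0, 0.9: 70.0, 1.0: 90.0}
    # blood pressure (true underlying values, mmHg)
    sbp_mean: float = 133.1
    sbp_sd: float = 26.6
    dbp_mean: float = 79.1
    dbp_sd: float = 16.8
    reading_noise_sd: float = 4.0
    first_reading_bias: float = 4.0
    # log-normal lipid / BMI marginals: median and log-scale sigma
    tc_median: float = 190.0
    tc_sigma: float = 0.2245
    hdl_median: float = 48.0
    hdl_sigma: float = 0.2263
    ldl_median: float = 115.0
    ldl_sigma: float = 0.287
    bmi_median: float = 26.0
    bmi_sigma: float = 0.1837
    # latent correlations, keys "var1,var2" over LATENT_VARS; unlisted = 0
    latent_correlations: dict[str, float] = {
        "age,sbp": 0.35, "age,dbp": 0.10, "age,tc": 0.20, "age,ldl": 0.18,
        "age,bmi": -0.05, "age,treated": 0.30, "age,diabetes": 0.20,
        "age,smoker": -0.05,
        "sbp,dbp": 0.65, "sbp,treated": 0.30, "sbp,bmi": 0.15,
        "sbp,diabetes": 0.10,
        "dbp,treated": 0.20, "dbp,bmi": 0.15,
        "tc,ldl": 0.90, "tc,hdl": 0.25, "tc,bmi": 0.10,
        "hdl,ldl": 0.05, "hdl,bmi": -0.20, "hdl,female": 0.15,
        "hdl,smoker": -0.05,
        "ldl,bmi": 0.10,
        "bmi,female": 0.25, "bmi,diabetes": 0.25, "bmi,treated": 0.10,
        "female,smoker": -0.20, "female,treated": 0.10,
        "diabetes,treated": 0.15,
    }

    @model_validator(mode="after")
    def _check(self) -> "CohortMarginals":
        if self.n <= 0:
            raise ValueError("n must be positive")
        for f in ("p_female", "p_bp_treated", "p_diabetes", "p_smoker",
                  "p_prior_mi", "p_prior_stroke", "p_on_statin", "p_fam_hx",
                  "p_hiv"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1]")
        qs = sorted(self.age_quantiles)
        if qs[0] != 0.0 or qs[-1] != 1.0:
            raise ValueError("age_quantiles must include probabilities 0 and 1")
        vals = [self.age_quantiles[q] for q in qs]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("age quantile values must be non-decreasing")
        np.linalg.cholesky(self.correlation_matrix())  # infeasible -> raises
        return self

    def correlation_matrix(self) -> np.ndarray:
        k = len(LATENT_VARS)
        r = np.eye(k)
        for key, v in self.latent_correlations.items():
            a, b = (s.strip() for s in key.split(","))
            i, j = LATENT_VARS.index(a), LATENT_VARS.index(b)
            r[i, j] = r[j, i] = v
        try:
            np.linalg.cholesky(r + 1e-12 * np.eye(k))
        except np.linalg.LinAlgError as exc:
            raise ValueError("latent correlation matrix is not positive "
                             "semi-definite") from exc
        return r

    @classmethod
    def from_yaml(cls, path: "str | Path | None" = None) -> "CohortMarginals":
        """Load marginals from YAML; default is the shipped Haiti cohort
        characteristics file."""
        if path is None:
            path = resources.files("cvdcompare").joinpath(
                "data/haiti_cohort.yaml")
        with open(str(path)) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def _age_map(u: np.ndarray, quantiles: dict[float, float]) -> np.ndarray:
    qs = np.array(sorted(quantiles))
    vals = np.array([quantiles[q] for q in qs])
    return np.interp(u, qs, vals)


def generate_frame(marginals: Optional[CohortMarginals] = None,
                   seed: int = 0, n: Optional[int] = None) -> pd.DataFrame:
    """Generate a synthetic cohort in the cohort CSV schema.

    Deterministic given (marginals, seed, n): a single seeded generator
    drives all draws in a fixed order.
    """
    m = marginals or CohortMarginals()
    n = int(n if n is not None else m.n)
    rng = np.random.default_rng(seed)
    corr = m.correlation_matrix()
    z = rng.multivariate_normal(np.zeros(len(LATENT_VARS)), corr, size=n,
                                method="cholesky")
    zc = {v: z[:, i] for i, v in enumerate(LATENT_VARS)}

    age = _age_map(sps.norm.cdf(zc["age"]), m.age_quantiles)
    sbp_true = np.clip(m.sbp_mean + m.sbp_sd * zc["sbp"], 70.0, None)
    dbp = np.clip(m.dbp_mean + m.dbp_sd * zc["dbp"], 35.0, None)
    tc = m.tc_median * np.exp(m.tc_sigma * zc["tc"])
    hdl = m.hdl_median * np.exp(m.hdl_sigma * zc["hdl"])
    ldl = m.ldl_median * np.exp(m.ldl_sigma * zc["ldl"])
    bmi = m.bmi_median * np.exp(m.bmi_sigma * zc["bmi"])

    def cut(name: str, p: float) -> np.ndarray:
        return (zc[name] > sps.norm.ppf(1.0 - p)).astype(int)

    female = cut("female", m.p_female)
    treated = cut("treated", m.p_bp_treated)
    diabetes = cut("diabetes", m.p_diabetes)
    smoker = cut("smoker", m.p_smoker)

    noise = rng.normal(0.0, m.reading_noise_sd, size=(n, 3))
    sbp1 = sbp_true + m.first_reading_bias + noise[:, 0]
    sbp2 = sbp_true + noise[:, 1]
    sbp3 = sbp_true + noise[:, 2]

    prior_mi = (rng.random(n) < m.p_prior_mi).astype(int)
    prior_stroke = (rng.random(n) < m.p_prior_stroke).astype(int)
    on_statin = (rng.random(n) < m.p_on_statin).astype(int)
    fam_hx = (rng.random(n) < m.p_fam_hx).astype(int)
    hiv = (rng.random(n) < m.p_hiv).astype(int)

    width = max(5, len(str(n)))
    df = pd.DataFrame({
        "participant_id": [f"S{i + 1:0{width}d}" for i in range(n)],
        "age_years": np.round(age, 1),
        "sex": np.where(female == 1, "female", "male"),
        "tc_mgdl": np.round(tc, 1),
        "hdl_mgdl": np.round(hdl, 1),
        "ldl_mgdl": np.round(ldl, 1),
        "sbp1_mmhg": np.round(sbp1, 1),
        "sbp2_mmhg": np.round(sbp2, 1),
        "sbp3_mmhg": np.round(sbp3, 1),
        "dbp_avg_mmhg": np.round(dbp, 1),
        "bp_treated": treated,
        "diabetes": diabetes,
        "smoker_current": smoker,
        "bmi_kgm2": np.round(bmi, 1),
        "prior_mi": prior_mi,
        "prior_stroke": prior_stroke,
        "on_statin": on_statin,
        "fam_hx_premature_chd": fam_hx,
        "hiv": hiv,
    }, columns=COHORT_COLUMNS)
    return df


def generate_cohort(marginals: Optional[CohortMarginals] = None,
                    seed: int = 0, n: Optional[int] = None
                    ) -> list[ParticipantRecord]:
    """Generate validated participant records (see :func:`generate_frame`)."""
    df = generate_frame(marginals, seed=seed, n=n)
    records = []
    for _, row in df.iterrows():
        from .cohort import _row_to_record  # shared row parser
        records.append(_row_to_record(row))
    return records


def marginal_report(records: "list[ParticipantRecord] | pd.DataFrame"
                    ) -> dict:
    """Summary of the published cohort-characteristics rows for generated
    (or any) data: n (%) for binaries, median [IQR] for age."""
    if isinstance(records, pd.DataFrame):
        return _marginal_report_frame(records)
    if not records:
        raise ValueError("empty cohort")
    n = len(records)
    age = np.array([r.age for r in records])
    q25, med, q75 = np.percentile(age, [25, 50, 75])

    def prev(flag) -> float:
        return float(np.mean([bool(flag(r)) for r in records]))

    return {
        "n": n,
        "female": prev(lambda r: r.sex == "female"),
        "age_median": float(med),
        "age_q25": float(q25),
        "age_q75": float(q75),
        "hypertension": prev(
            lambda r: r.bp_treated or r.sbp_avg >= 140
            or (r.dbp_avg is not None and r.dbp_avg >= 90)),
        "bp_treated": prev(lambda r: r.bp_treated),
        "diabetes": prev(lambda r: r.diabetes),
        "smoker": prev(lambda r: r.smoker),
        "bmi_ge_30": prev(lambda r: r.bmi >= 30),
        "hdl_lt_40": prev(lambda r: r.hdl < 40),
        "ldl_ge_130": prev(lambda r: r.ldl >= 130),
        "sbp_ge_140": prev(lambda r: r.sbp_avg >= 140),
        "sbp_ge_130": prev(lambda r: r.sbp_avg >= 130),
        "dbp_ge_90": prev(lambda r: r.dbp_avg >= 90),
        "hiv": prev(lambda r: r.hiv),
    }


def _marginal_report_frame(df: pd.DataFrame) -> dict:
    # vectorized equivalent of the record path, for large cohorts
    if df.empty:
        raise ValueError("empty cohort")
    sbp = (df["sbp2_mmhg"] + df["sbp3_mmhg"]) / 2.0
    treated = df["bp_treated"].astype(bool)
    dbp = df["dbp_avg_mmhg"]
    q25, med, q75 = np.percentile(df["age_years"], [25, 50, 75])
    return {
        "n": int(len(df)),
        "female": float((df["sex"] == "female").mean()),
        "age_median": float(med), "age_q25": float(q25), "age_q75": float(q75),
        "hypertension": float((treated | (sbp >= 140) | (dbp >= 90)).mean()),
        "bp_treated": float(treated.mean()),
        "diabetes": float(df["diabetes"].astype(bool).mean()),
        "smoker": float(df["smoker_current"].astype(bool).mean()),
        "bmi_ge_30": float((df["bmi_kgm2"] >= 30).mean()),
        "hdl_lt_40": float((df["hdl_mgdl"] < 40).mean()),
        "ldl_ge_130": float((df["ldl_mgdl"] >= 130).mean()),
        "sbp_ge_140": float((sbp >= 140).mean()),
        "sbp_ge_130": float((sbp >= 130).mean()),
        "dbp_ge_90": float((dbp >= 90).mean()),
        "hiv": float(df["hiv"].astype(bool).mean()),
    }


def _frame_to_records(df: pd.DataFrame):
    import io
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return read_cohort(buf)
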