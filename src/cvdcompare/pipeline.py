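"""End-to-end orchestration: simulate or ingest -> prepare -> score ->
categorize -> statin rules -> comparison statistics.

Every run writes its stage outputs as tidy delimited text plus a manifest
recording the configuration, seed, package and model-config versions, and
a SHA-256 checksum per output file.  All stages are deterministic, so
re-running a manifest's configuration reproduces the outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from .categorize import (SCHEMES, categorize_cohort, category_table,
                         discordance_pattern_counts, find_discordant)
from .cohort import read_cohort, records_to_frame, prepare_cohort
from .engine import DEFAULT_ANCESTRY, score_cohort, scores_wide
from .registry import MODEL_IDS, load_registry
from .simulate import CohortMarginals, generate_cohort
from .statins import eligibility_table, statin_decisions
from .stats import chi_square_independence, high_risk_profile_summary, \
    spearman_matrix

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    input: Optional[str] = None        # cohort CSV; None -> simulate
    simulate_n: Optional[int] = None   # participants to simulate
    marginals: Optional[str] = None    # marginals YAML (None -> shipped)
    seed: int = 0
    models: list[str] = list(MODEL_IDS)
    scheme: str = "both"               # uniform | model_specific | both
    ancestry: str = DEFAULT_ANCESTRY
    out: str = "results"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not self.models:
            raise ValueError("at least one model must be selected")
        unknown = [m for m in self.models if m not in MODEL_IDS]
        if unknown:
            raise ValueError(f"unknown model id(s): {unknown}")
        if self.scheme not in ("uniform", "model_specific", "both"):
            raise ValueError("scheme must be uniform, model_specific or both")
        if self.ancestry not in ("black", "white"):
            raise ValueError("ancestry must be 'black' or 'white'")
        return self

    def scheme_names(self) -> list[str]:
        return (["uniform", "model_specific"] if self.scheme == "both"
                else [self.scheme])


def _sha256(path: Path) -> str:
    return "sha256:" + hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to the output
    directory).  Any stage failure raises :class:`StageError` naming the
    stage."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    stage = "ingest"
    try:
        if config.input is None:
            stage = "simulate"
            marginals = (CohortMarginals.from_yaml(config.marginals)
                         if config.marginals else CohortMarginals())
            records = generate_cohort(marginals, seed=config.seed,
                                      n=config.simulate_n)
            log.info("simulated %d participants (seed=%d)",
                     len(records), config.seed)
        else:
            records, rejects = read_cohort(config.input)
            if len(rejects):
                _write_csv(rejects, out / "rejected_rows.csv")
                outputs["rejected_rows"] = out / "rejected_rows.csv"
                log.warning("rejected %d rows on ingest", len(rejects))

        stage = "prepare"
        analytic, report = prepare_cohort(records)
        if not analytic:
            raise ValueError("no participants survive the exclusion cascade")
        _write_csv(records_to_frame(analytic), out / "cohort.csv")
        outputs["cohort"] = out / "cohort.csv"
        exclusions = {
            "n_input": report.n_input, "incomplete": report.incomplete,
            "age_under_40": report.age_under_40, "on_statin": report.on_statin,
            "prior_mi_stroke": report.prior_mi_stroke, "n_final": report.n_final}

        stage = "score"
        log.info("scoring %d participants x %d models (ancestry stratum: %s)",
                 len(analytic), len(config.models), config.ancestry)
        specs = load_registry(model_ids=config.models)
        scores = score_cohort(analytic, specs=specs, ancestry=config.ancestry)
        if (scores["error"] != "").any():
            bad = scores.loc[scores["error"] != "", "error"].iloc[0]
            raise ValueError(f"scoring failures, first: {bad}")
        _write_csv(scores.drop(columns=["error"]), out / "scores.csv")
        outputs["scores"] = out / "scores.csv"

        stage = "categorize"
        cats = {name: categorize_cohort(scores, SCHEMES[name])
                for name in config.scheme_names()}
        _write_csv(pd.concat(cats.values(), ignore_index=True),
                   out / "categories.csv")
        outputs["categories"] = out / "categories.csv"

        stage = "statin"
        decisions = statin_decisions(analytic, scores)
        _write_csv(decisions, out / "statin.csv")
        outputs["statin"] = out / "statin.csv"

        stage = "compare"
        comparison = compare(analytic, scores, cats, decisions)
        (out / "comparison.json").write_text(
            json.dumps(comparison, indent=2, sort_keys=True) + "\n")
        outputs["comparison"] = out / "comparison.json"
        (out / "comparison.txt").write_text(render_report(comparison))
        outputs["comparison_text"] = out / "comparison.txt"
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "cvdcompare",
        "version": __version__,
        "config": config.model_dump(),
        "exclusions": exclusions,
        "outputs": {k: {"path": p.name, "checksum": _sha256(p)}
                    for k, p in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def compare(records, scores: pd.DataFrame, categories: dict[str, pd.DataFrame],
            decisions: pd.DataFrame) -> dict:
    """All between-model comparison statistics as one JSON-ready report."""
    wide = scores_wide(scores)
    result: dict = {
        "n": int(wide.shape[0]),
        "median_risk_pct": {m: {"median": float(wide[m].median() * 100),
                                "q25": float(wide[m].quantile(0.25) * 100),
                                "q75": float(wide[m].quantile(0.75) * 100)}
                            for m in wide.columns},
    }
    if wide.shape[1] >= 2:
        rho = spearman_matrix(wide)
        off = rho.where(~pd.DataFrame(
            [[i == j for j in range(len(rho))] for i in range(len(rho))],
            index=rho.index, columns=rho.columns))
        result["spearman"] = {
            "matrix": {a: {b: (None if pd.isna(v) else round(float(v), 4))
                           for b, v in row.items()}
                       for a, row in rho.iterrows()},
            "min": float(off.min().min()),
            "max": float(off.max().max()),
        }
    result["schemes"] = {}
    for name, cat in categories.items():
        table = category_table(cat)
        ids, patterns = find_discordant(cat)
        entry = {
            "category_counts": {m: {c: int(table.loc[m, c])
                                    for c in ("low", "intermediate", "high")}
                                for m in table.index},
            "high_pct": {m: round(float(table.loc[m, "high_pct"]), 2)
                         for m in table.index},
            "discordant_n": len(ids),
            "discordant_high_side_counts":
                {k: int(v) for k, v in
                 discordance_pattern_counts(patterns).items()},
        }
        if len(table) >= 2:
            stat, df, p = chi_square_independence(
                table[["low", "intermediate", "high"]])
            entry["chi2_categories"] = {"statistic": round(stat, 2),
                                        "df": df, "p": p}
        result["schemes"][name] = entry

    elig = eligibility_table(decisions)
    result["statin_eligibility"] = {
        m: {"eligible": int(elig.loc[m, "eligible"]),
            "n": int(elig.loc[m, "n"]),
            "pct": round(float(elig.loc[m, "pct"]), 2),
            "ci95_pct": [round(float(elig.loc[m, "ci_low_pct"]), 2),
                         round(float(elig.loc[m, "ci_high_pct"]), 2)]}
        for m in elig.index}
    if len(elig) >= 2:
        tab = [[int(elig.loc[m, "eligible"]),
                int(elig.loc[m, "n"] - elig.loc[m, "eligible"])]
               for m in elig.index]
        stat, df, p = chi_square_independence(pd.DataFrame(tab))
        result["chi2_statin"] = {"statistic": round(stat, 2), "df": df, "p": p}

    spec_cats = categories.get("model_specific")
    if spec_cats is not None:
        profile = high_risk_profile_summary(records, spec_cats)
        result["high_risk_profile"] = json.loads(
            profile.to_json(orient="index"))
    return result


def render_report(comparison: dict) -> str:
    """Human-readable text rendering of the comparison report."""
    lines = [f"Cohort n = {comparison['n']}", ""]
    lines.append("10-year predicted CVD risk, median [IQR] %:")
    for m, q in comparison["median_risk_pct"].items():
        lines.append(f"  {m:<18} {q['median']:5.1f} [{q['q25']:.1f}, "
                     f"{q['q75']:.1f}]")
    if "spearman" in comparison:
        lines.append("")
        lines.append(f"Spearman rank concordance: "
                     f"{comparison['spearman']['min']:.2f} to "
                     f"{comparison['spearman']['max']:.2f}")
    for name, entry in comparison.get("schemes", {}).items():
        lines.append("")
        lines.append(f"[{name} thresholds]")
        for m, counts in entry["category_counts"].items():
            lines.append(
                f"  {m:<18} low {counts['low']:>5}  intermediate "
                f"{counts['intermediate']:>5}  high {counts['high']:>5}"
                f"  ({entry['high_pct'][m]:.1f}% high)")
        if "chi2_categories" in entry:
            c = entry["chi2_categories"]
            lines.append(f"  chi-square = {c['statistic']:.1f} "
                         f"(df = {c['df']}, p = {c['p']:.3g})")
        lines.append(f"  discordant participants: {entry['discordant_n']}")
    lines.append("")
    lines.append("Statin eligibility:")
    for m, e in comparison["statin_eligibility"].items():
        lines.append(f"  {m:<18} {e['eligible']:>5} ({e['pct']:.1f}%, "
                     f"95% CI {e['ci95_pct'][0]:.1f} to {e['ci95_pct'][1]:.1f})")
    if "chi2_statin" in comparison:
        c = comparison["chi2_statin"]
        lines.append(f"  chi-square = {c['statistic']:.1f} (df = {c['df']}, "
                     f"p = {c['p']:.3g})")
    return "\n".join(lines) + "\n"
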