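"""Risk categorization and between-model discordance.

Two threshold schemes are supported:

* ``uniform`` — the same cut-points for every model: low < 5%,
  intermediate 5 to < 7.5%, high >= 7.5%.
* ``model_specific`` — each model family's native cut-points: PCE and
  adjusted PCE 5% / 7.5%; Framingham (both versions) 10% / 20%; WHO (both
  versions) 5% / 20%.

Boundary convention: intervals are left-closed, right-open, with the top
category closed at its cut (a risk exactly equal to the upper cut is
high).  Risks are compared at full precision, never after rounding.

A participant is *discordant* when at least one model calls them low risk
and at least one other calls them high risk (intermediate never triggers
discordance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CATEGORIES = ("low", "intermediate", "high")


@dataclass(frozen=True)
class ThresholdScheme:
    """Named mapping model id -> (lower cut c1, upper cut c2), proportions."""

    name: str
    cuts: dict[str, tuple[float, float]] = field(default_factory=dict)
    default: "tuple[float, float] | None" = None

    def __post_init__(self):
        for mid, (c1, c2) in list(self.cuts.items()) + (
            [("default", self.default)] if self.default else []
        ):
            if not 0.0 < c1 < c2 < 1.0:
                raise ValueError(
                    f"{self.name}/{mid}: cut-points must satisfy 0 < c1 < c2 < 1")

    def cutpoints(self, model_id: str) -> tuple[float, float]:
        if model_id in self.cuts:
            return self.cuts[model_id]
        if self.default is not None:
            return self.default
        raise KeyError(f"scheme {self.name!r} has no cut-points for model "
                       f"{model_id!r}")


UNIFORM = ThresholdScheme("uniform", default=(0.05, 0.075))

MODEL_SPECIFIC = ThresholdScheme(
    "model_specific",
    cuts={
        "pce": (0.05, 0.075),
        "apce": (0.05, 0.075),
        "framingham_lipids": (0.10, 0.20),
        "framingham_bmi": (0.10, 0.20),
        "who_lipids": (0.05, 0.20),
        "who_bmi": (0.05, 0.20),
    },
)

SCHEMES = {"uniform": UNIFORM, "model_specific": MODEL_SPECIFIC}


def categorize(risk: float, model_id: str, scheme: ThresholdScheme) -> str:
    """Map one risk probability to low / intermediate / high."""
    if not 0.0 <= risk <= 1.0:
        raise ValueError(f"risk must be in [0, 1], got {risk}")
    c1, c2 = scheme.cutpoints(model_id)
    if risk < c1:
        return "low"
    if risk < c2:
        return "intermediate"
    return "high"


def categorize_cohort(scores: pd.DataFrame, scheme: ThresholdScheme
                      ) -> pd.DataFrame:
    """Tidy category table: participant_id, model_id, scheme, category."""
    out = scores[["participant_id", "model_id", "risk10y"]].copy()
    out["scheme"] = scheme.name
    out["category"] = [
        categorize(r, m, scheme)
        for r, m in zip(out["risk10y"], out["model_id"])
    ]
    return out.drop(columns=["risk10y"])


def category_table(categories: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions per model x category.

    Rows indexed by model id (first-appearance order), columns
    ``low, intermediate, high, low_pct, intermediate_pct, high_pct, n``.
    Per-model counts sum to the cohort n.
    """
    order = categories["model_id"].drop_duplicates().tolist()
    counts = (categories.groupby(["model_id", "category"], sort=False)
              .size().unstack(fill_value=0)
              .reindex(index=order, columns=list(CATEGORIES), fill_value=0))
    counts["n"] = counts.sum(axis=1)
    for c in CATEGORIES:
        counts[f"{c}_pct"] = 100.0 * counts[c] / counts["n"]
    return counts[[*CATEGORIES, "n",
                   *(f"{c}_pct" for c in CATEGORIES)]]


def find_discordant(categories: pd.DataFrame
                    ) -> tuple[set[str], pd.DataFrame]:
    """Discordant participants and their high/low model patterns.

    Returns the set of discordant participant ids and a frame with one row
    per discordant participant: ``participant_id``, ``high_models`` and
    ``low_models`` (comma-joined, registry order).  Symmetric in model
    order and invariant to model relabeling.
    """
    rows = []
    ids: set[str] = set()
    for pid, grp in categories.groupby("participant_id", sort=False):
        cats = dict(zip(grp["model_id"], grp["category"]))
        high = [m for m, c in cats.items() if c == "high"]
        low = [m for m, c in cats.items() if c == "low"]
        if high and low:
            ids.add(pid)
            rows.append({"participant_id": pid,
                         "high_models": ",".join(high),
                         "low_models": ",".join(low)})
    return ids, pd.DataFrame(rows,
                             columns=["participant_id", "high_models",
                                      "low_models"])


def discordance_pattern_counts(patterns: pd.DataFrame) -> pd.Series:
    """How often each model appears on the high side of a discordant pair."""
    if patterns.empty:
        return pd.Series(dtype=int)
    return (patterns["high_models"].str.split(",").explode()
            .value_counts())


def export_category_bars(table: pd.DataFrame, path: str) -> None:
    """Minimal stacked-bar export of a category table (counts are
    authoritative; this is a convenience view)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = table[list(CATEGORIES)].plot(
        kind="bar", stacked=True, figsize=(8, 4),
        color=["#2c7bb6", "#fdae61", "#d7191c"])
    ax.set_ylabel("participants")
    ax.set_xlabel("model")
    plt.tight_layout()
    plt.savefig(path, dpi=150)
    plt.close()
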