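"""Between-model comparison statistics.

Spearman rank concordance between models' risk orderings, Pearson
chi-square tests of independence on category/eligibility count tables,
Wilson score intervals for one-sample proportions, and risk-factor
summaries of the high-risk groups.

Conventions: Spearman uses average ranks for ties; chi-square is Pearson
without continuity correction (the Yates correction is never applied, for
any table size used here); Wilson intervals are without continuity
correction; quantiles use linear interpolation.  The Wilson and chi-square
variants were chosen because they reproduce published confidence intervals
and test statistics recomputed from count data at the printed precision.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .cohort import ParticipantRecord


def spearman_matrix(scores_wide: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations of a participants x models table.

    Average ranks for ties.  A constant column has no defined rank
    correlation; its entries are reported as NaN rather than raised.
    """
    if len(scores_wide) < 3:
        raise ValueError("need at least 3 participants for rank correlation")
    if scores_wide.isna().any().any():
        raise ValueError("missing scores; score the cohort completely first")
    cols = list(scores_wide.columns)
    k = len(cols)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            xi = scores_wide.iloc[:, i]
            xj = scores_wide.iloc[:, j]
            if xi.nunique() == 1 or xj.nunique() == 1:
                rho = np.nan
            else:
                rho = sps.spearmanr(xi, xj).statistic
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=cols, columns=cols)


def chi_square_independence(table: "pd.DataFrame | np.ndarray"
                            ) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a count table.

    No continuity correction.  Returns (statistic, df, p).  A zero
    expected count makes the statistic undefined; the offending cell is
    named in the error.
    """
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (arr.sum(axis=1) <= 0).any():
        raise ValueError("every row must have a positive total")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected == 0).any():
        i, j = np.argwhere(expected == 0)[0]
        raise ValueError(f"zero expected count in cell ({i}, {j})")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)


def wilson_ci(successes: int, n: int, level: float = 0.95
              ) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (no continuity
    correction).  Bounds are proportions in [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be between 0 and n")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


#: Table-3-style variables: (label, kind) where kind is 'continuous' or 'binary'
_PROFILE_CONTINUOUS = ["age", "sbp_treated", "sbp_untreated",
                       "total_cholesterol", "hdl"]
_PROFILE_BINARY = ["female", "diabetes", "smoker"]

EMPTY_MARKER = "—"


def high_risk_profile_summary(records: Iterable[ParticipantRecord],
                              categories: pd.DataFrame) -> pd.DataFrame:
    """Risk-factor distribution of each model's high-risk group.

    For each model, restricts to participants that model calls high under
    the supplied category table and reports median [25th, 75th percentile]
    for continuous variables (SBP split by treatment status) and n (%) for
    binary ones.  An empty high-risk group yields a row of explicit empty
    markers.
    """
    by_id = {r.participant_id: r for r in records}
    order = categories["model_id"].drop_duplicates().tolist()
    rows = []
    for mid in order:
        ids = categories.loc[
            (categories["model_id"] == mid) & (categories["category"] == "high"),
            "participant_id"]
        group = [by_id[i] for i in ids]
        row: dict = {"model_id": mid, "n_high": len(group)}
        if not group:
            for v in _PROFILE_BINARY:
                row[f"{v}_n"] = row[f"{v}_pct"] = EMPTY_MARKER
            for v in _PROFILE_CONTINUOUS:
                row[f"{v}_median"] = row[f"{v}_q25"] = row[f"{v}_q75"] = EMPTY_MARKER
        else:
            vals = {
                "age": [r.age for r in group],
                "sbp_treated": [r.sbp_avg for r in group if r.bp_treated],
                "sbp_untreated": [r.sbp_avg for r in group if not r.bp_treated],
                "total_cholesterol": [r.total_cholesterol for r in group],
                "hdl": [r.hdl for r in group],
            }
            flags = {
                "female": [r.sex == "female" for r in group],
                "diabetes": [r.diabetes for r in group],
                "smoker": [r.smoker for r in group],
            }
            for v, xs in flags.items():
                row[f"{v}_n"] = int(np.sum(xs))
                row[f"{v}_pct"] = 100.0 * float(np.mean(xs))
            for v, xs in vals.items():
                if xs:
                    q25, med, q75 = np.percentile(xs, [25, 50, 75])  # linear interp
                    row[f"{v}_median"], row[f"{v}_q25"], row[f"{v}_q75"] = (
                        float(med), float(q25), float(q75))
                else:
                    row[f"{v}_median"] = row[f"{v}_q25"] = row[f"{v}_q75"] = (
                        EMPTY_MARKER)
        rows.append(row)
    return pd.DataFrame(rows).set_index("model_id")
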