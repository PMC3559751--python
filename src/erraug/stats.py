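"""Group-comparison statistics for the four-group design.

The planned analysis is five one-way ANOVAs over the per-subject
exponential-fit parameters — training A, B, C and washout A, B — followed
by Tukey HSD pairwise comparisons at alpha = 0.05, with Kruskal-Wallis
tests as a non-parametric check (sample sizes of four per group are too
small to verify normality).  Effect sizes are pooled-SD Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "AnovaResult",
    "one_way_anova",
    "tukey_hsd",
    "kruskal_wallis",
    "cohens_d",
    "percent_reduction_summary",
    "ANALYSIS_PLAN",
    "run_analysis_plan",
]

#: The five planned tests: (phase, fitted parameter).
ANALYSIS_PLAN: tuple[tuple[str, str], ...] = (
    ("training", "A"),
    ("training", "B"),
    ("training", "C"),
    ("washout", "A"),
    ("washout", "B"),
)


@dataclass(frozen=True)
class GroupSample:
    """Per-subject values of one quantity for one group."""

    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.size < 2:
            raise ValueError(f"group {self.group!r} needs n >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.group!r} contains non-finite values")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def _check(groups: Sequence[GroupSample]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    return [g.values for g in groups]


def one_way_anova(groups: Sequence[GroupSample]) -> AnovaResult:
    """Classical between/within one-way ANOVA.

    With 4 groups of 4 subjects the degrees of freedom are (3, 12).  If
    every group has zero variance and all means are equal, F is reported
    as 0 with p = 1 (no evidence of any effect) rather than as 0/0.
    """
    vals = _check(groups)
    df_b = len(vals) - 1
    df_w = sum(v.size for v in vals) - len(vals)
    grand = np.concatenate(vals)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in vals)
    ss_between = sum(v.size * (v.mean() - grand.mean()) ** 2 for v in vals)
    if ss_within == 0 and ss_between == 0:
        return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
    F, p = sps.f_oneway(*vals)
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=float(p))


def tukey_hsd(groups: Sequence[GroupSample], alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise Tukey HSD comparisons (studentized-range adjusted).

    Returns one row per unordered pair with the mean difference, adjusted
    p-value and significance at ``alpha`` — C(k, 2) rows for k groups.
    """
    vals = _check(groups)
    res = sps.tukey_hsd(*vals)
    rows = []
    for i in range(len(vals)):
        for j in range(i + 1, len(vals)):
            p = float(res.pvalue[i, j])
            rows.append(
                {
                    "group1": groups[i].group,
                    "group2": groups[j].group,
                    "mean_diff": float(vals[i].mean() - vals[j].mean()),
                    "p_adj": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def kruskal_wallis(groups: Sequence[GroupSample]) -> tuple[float, int, float]:
    """Rank-based Kruskal-Wallis H with tie correction; df = k - 1.

    When every observation is identical the tie correction degenerates;
    by convention H = 0, p = 1 (all ranks tied, no evidence of effect).
    """
    vals = _check(groups)
    df = len(vals) - 1
    grand = np.concatenate(vals)
    if np.all(grand == grand[0]):
        return 0.0, df, 1.0
    H, p = sps.kruskal(*vals)
    return float(H), df, float(p)


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Pooled-SD Cohen's d for two equal-n groups.

    d = |mean1 - mean2| / sqrt((sd1^2 + sd2^2) / 2).
    """
    if not (sd1 > 0 and sd2 > 0):
        raise ValueError("standard deviations must be positive")
    return abs(mean1 - mean2) / np.sqrt((sd1**2 + sd2**2) / 2.0)


def percent_reduction_summary(
    initial: Sequence[float], steady_state: Sequence[float]
) -> float:
    """Average percent error reduction across groups.

    mean over groups of (initial - steady_state) / initial * 100.
    """
    initial = np.asarray(initial, dtype=float)
    steady = np.asarray(steady_state, dtype=float)
    if initial.shape != steady.shape:
        raise ValueError("initial and steady_state must have equal length")
    if np.any(initial == 0):
        raise ValueError("initial errors must be nonzero")
    return float(np.mean((initial - steady) / initial) * 100.0)


def run_analysis_plan(
    fits: pd.DataFrame, alpha: float = 0.05, group_order: Sequence[str] | None = None
) -> dict:
    """Run the five planned ANOVAs (+ Tukey, Kruskal-Wallis) on a fit table.

    ``fits`` is the per-subject fit table from
    :func:`erraug.curves.fit_all_subjects` (columns subject_id, group,
    phase, A, B, C).  No multiple-testing correction is applied across the
    five planned tests.
    """
    results = {}
    for phase, param in ANALYSIS_PLAN:
        sub = fits[(fits["phase"] == phase) & fits[param].notna()]
        order = group_order or sorted(sub["group"].unique())
        groups = [
            GroupSample(g, sub.loc[sub["group"] == g, param].to_numpy())
            for g in order
        ]
        anova = one_way_anova(groups)
        H, kw_df, kw_p = kruskal_wallis(groups)
        results[f"{phase}_{param}"] = {
            "anova": anova,
            "tukey": tukey_hsd(groups, alpha=alpha),
            "kruskal": {"H": H, "df": kw_df, "p": kw_p},
            "group_means": {g.group: float(g.values.mean()) for g in groups},
            "group_sds": {g.group: float(g.values.std(ddof=1)) for g in groups},
        }
    return results
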