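"""Nonparametric group statistics over measure tables.

The inferential battery is deliberately rank-based: measure
distributions on small clinical cohorts are skewed and heavy-tailed, so
every test here is invariant under strictly monotone transformations of
the data.  Per measure, a Kruskal–Wallis test gates at alpha = 0.05;
pairwise Wilcoxon rank-sum tests then run at a Bonferroni-corrected
alpha (family alpha divided by the number of group pairs — 0.0166 for
three groups, matching the convention of truncating the displayed value
to four decimals).  Spearman correlations relate measures to
psychometric scale totals.  Missing values are dropped pairwise, never
imputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairwiseResult",
    "GroupComparison",
    "kruskal_wallis",
    "wilcoxon_ranksum",
    "bonferroni",
    "format_alpha",
    "spearman",
    "compare_groups",
    "comparison_frame",
    "spearman_table",
]

RanksumMethod = Literal["auto", "exact", "approx"]

#: largest per-group n at which the exact rank-sum null is enumerated
EXACT_RANKSUM_MAX_N = 10


def _clean(x: Sequence[float]) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[~np.isnan(arr)]


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and its chi-square p-value.

    Missing values are dropped per group.  If every observation across
    all groups is identical the statistic is 0 and p = 1 by convention.
    """
    groups = [_clean(s) for s in samples]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def wilcoxon_ranksum(
    a: Sequence[float], b: Sequence[float], method: RanksumMethod = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    With ``method="auto"`` the exact permutation null is enumerated when
    both samples have at most ``EXACT_RANKSUM_MAX_N`` observations and
    there are no ties — at the cohort sizes this tool targets (8 per
    group) the normal approximation is poor.  Otherwise the normal
    approximation with tie and continuity correction is used.  Returns
    the Mann–Whitney U of the first sample and the p-value.
    """
    x, y = _clean(a), _clean(b)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples need at least one observation")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        use_exact = (
            len(x) <= EXACT_RANKSUM_MAX_N
            and len(y) <= EXACT_RANKSUM_MAX_N
            and not has_ties
        )
    elif method == "exact":
        use_exact = True
    else:
        use_exact = False
    if use_exact:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bonferroni(alpha: float, m: int) -> float:
    """Corrected per-comparison alpha = family alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def format_alpha(alpha: float, decimals: int = 4) -> str:
    """Display form of a corrected alpha, truncated (not rounded).

    0.05/3 displays as "0.0166".
    """
    scale = 10**decimals
    return f"{math.floor(alpha * scale) / scale:.{decimals}f}"


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with pairwise deletion of missing values.

    Returns (rho, p) with p from the t approximation; rho is NaN when
    either vector has zero variance or fewer than 3 pairs remain.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    if len(xa) < 3:
        return math.nan, math.nan
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return math.nan, math.nan
    rho, p = sps.spearmanr(xa, ya)
    return float(rho), float(p)


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p: float
    significant: bool


@dataclass
class GroupComparison:
    """Kruskal–Wallis + pairwise rank-sum results for one measure."""

    measure: str
    kw_h: float
    kw_p: float
    corrected_alpha: float
    pairwise: list[PairwiseResult] = field(default_factory=list)

    @property
    def any_significant(self) -> bool:
        return any(pw.significant for pw in self.pairwise)


def compare_groups(
    table: pd.DataFrame,
    measures: Optional[Sequence[str]] = None,
    groups: Optional[Sequence[str]] = None,
    group_col: str = "group",
    alpha: float = 0.05,
    ranksum_method: RanksumMethod = "auto",
) -> list[GroupComparison]:
    """Run the full battery on a measure table.

    Per measure: Kruskal–Wallis across all groups, then every pairwise
    rank-sum test.  A pairwise difference is flagged significant when the
    KW p-value passes the family alpha AND the pairwise p-value passes
    the Bonferroni-corrected alpha (family alpha / number of pairs).
    Entirely missing measure columns are skipped with a warning.
    """
    if groups is None:
        groups = [g for g in table[group_col].unique() if g != "unlabeled"]
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two labeled groups")
    if measures is None:
        measures = [
            c
            for c in table.columns
            if c not in (group_col, "subject_id", "word_count")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    pairs = list(combinations(groups, 2))
    corrected = bonferroni(alpha, len(pairs))

    results: list[GroupComparison] = []
    for measure in measures:
        if measure not in table.columns or table[measure].dropna().empty:
            warnings.warn(f"measure column {measure!r} empty or absent; skipped")
            continue
        samples = [
            table.loc[table[group_col] == g, measure].to_numpy(dtype=float)
            for g in groups
        ]
        kw_h, kw_p = kruskal_wallis(samples)
        comp = GroupComparison(
            measure=measure, kw_h=kw_h, kw_p=kw_p, corrected_alpha=corrected
        )
        for (ga, gb), (sa, sb) in zip(pairs, combinations(samples, 2)):
            stat, p = wilcoxon_ranksum(sa, sb, method=ranksum_method)
            comp.pairwise.append(
                PairwiseResult(
                    group_a=ga,
                    group_b=gb,
                    statistic=stat,
                    p=p,
                    significant=(kw_p < alpha) and (p < corrected),
                )
            )
        results.append(comp)
    return results


def comparison_frame(results: Iterable[GroupComparison]) -> pd.DataFrame:
    """Flatten comparisons into a table: measure x {KW, pairwise p, flags}."""
    rows = []
    for comp in results:
        row: dict[str, float | str | bool] = {
            "measure": comp.measure,
            "kw_H": comp.kw_h,
            "kw_p": comp.kw_p,
            "corrected_alpha": comp.corrected_alpha,
        }
        for pw in comp.pairwise:
            key = f"{pw.group_a[0].upper()}x{pw.group_b[0].upper()}"
            row[f"{key}_p"] = pw.p
            row[f"{key}_significant"] = pw.significant
        rows.append(row)
    return pd.DataFrame(rows)


def spearman_table(
    table: pd.DataFrame,
    measures: Sequence[str],
    scales: Sequence[str] = ("bprs", "panss"),
) -> pd.DataFrame:
    """Spearman rho/p of each measure against each psychometric scale."""
    rows = []
    for measure in measures:
        row: dict[str, float | str] = {"measure": measure}
        for scale in scales:
            if scale not in table.columns:
                warnings.warn(f"scale column {scale!r} absent; omitted")
                continue
            rho, p = spearman(table[measure], table[scale])
            row[f"{scale}_rho"] = rho
            row[f"{scale}_p"] = p
        rows.append(row)
    return pd.DataFrame(rows)
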