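"""Normality-gated two-group comparisons and summary conventions.

Every per-cell metric (mIPSC frequency, conductance, PPR, ...) is compared
between genotypes the same way: both groups are tested for normality with
Shapiro–Wilk at α = 0.05; if both pass, a two-tailed unpaired Student's
t-test is used, otherwise a two-tailed rank test. Summaries are mean ± SEM.

The rank test defaults to the Mann–Whitney rank-sum form, the coherent
two-sample test for unpaired groups; a Wilcoxon signed-rank mode on paired
differences is available for paired designs. No multiple-testing correction
is applied, matching the source analysis convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "normality_gate", "compare_groups", "summarize"]

ALPHA_NORMALITY = 0.05


@dataclass
class GroupComparison:
    """Outcome of one gated two-group comparison."""

    test_used: str  # "t_test" | "wilcoxon"
    p_value: float
    statistic: float
    normality_p_a: float
    normality_p_b: float
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int


def summarize(values: Sequence[float]) -> tuple[float, float, int]:
    """Mean, SEM (sample SD / sqrt(n)), and n.

    SEM of a single value is undefined and returned as NaN rather than 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to summarize")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else math.nan
    return mean, sem, int(v.size)


def normality_gate(
    a: Sequence[float], b: Sequence[float], alpha: float = ALPHA_NORMALITY
) -> tuple[str, float, float]:
    """Choose the two-sample test: t-test iff both groups look normal.

    Shapiro–Wilk on each group at ``alpha``; any failure routes to the rank
    test. Returns (test name, p_a, p_b). Groups of fewer than 3 values cannot
    be tested and are rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("normality gate needs at least 3 values per group")
    p_a = float(sps.shapiro(a).pvalue)
    p_b = float(sps.shapiro(b).pvalue)
    test = "t_test" if (p_a > alpha and p_b > alpha) else "wilcoxon"
    return test, p_a, p_b


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = ALPHA_NORMALITY,
    rank_mode: Literal["rank_sum", "signed_rank"] = "rank_sum",
) -> GroupComparison:
    """Gated two-tailed comparison of two groups of per-cell values.

    Runs the test chosen by :func:`normality_gate`. ``rank_mode`` selects the
    rank test: "rank_sum" (Mann–Whitney, unpaired; default) or "signed_rank"
    (Wilcoxon on paired differences; requires equal group sizes).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    test, p_a, p_b = normality_gate(a, b, alpha)
    if test == "t_test":
        res = sps.ttest_ind(a, b)
        stat, p = float(res.statistic), float(res.pvalue)
    elif rank_mode == "rank_sum":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if a.size != b.size:
            raise ValueError("signed-rank mode requires paired (equal-size) groups")
        res = sps.wilcoxon(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    mean_a, sem_a, n_a = summarize(a)
    mean_b, sem_b, n_b = summarize(b)
    return GroupComparison(
        test_used=test,
        p_value=p,
        statistic=stat,
        normality_p_a=p_a,
        normality_p_b=p_b,
        mean_a=mean_a,
        sem_a=sem_a,
        n_a=n_a,
        mean_b=mean_b,
        sem_b=sem_b,
        n_b=n_b,
    )
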