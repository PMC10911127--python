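"""Normality-gated statistical test selection and group comparison.

The selection rule mirrors the reporting convention used for all group
comparisons in this workflow: every group is tested for normality
(D'Agostino–Pearson; Shapiro–Wilk when a group is too small for the
omnibus test), and the comparison then uses the parametric test (t-test /
one-way ANOVA) when all groups look normal, otherwise the rank-based
alternative (Mann–Whitney / Kruskal–Wallis).  Omnibus comparisons of
more than two groups are followed by pairwise post-hoc tests with a
multiple-comparison correction (Holm by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonPlan", "select_test", "run_comparison", "holm_correction"]

#: below this per-group n the D'Agostino–Pearson omnibus test is
#: unreliable (it needs a usable kurtosis estimate); Shapiro–Wilk is the
#: small-sample fallback.
DAGOSTINO_MIN_N = 8


@dataclass
class ComparisonPlan:
    """A resolved group comparison: data, normality outcome, chosen test."""

    groups: dict[str, np.ndarray]
    paired: bool = False
    normality_alpha: float = 0.05
    all_normal: bool = False
    normality_pvalues: dict[str, float] = field(default_factory=dict)
    chosen_test: str = ""
    multiple_comparison: bool = False


def _normality_p(x: np.ndarray) -> float:
    if len(x) < DAGOSTINO_MIN_N:
        return float(sps.shapiro(x).pvalue)
    return float(sps.normaltest(x).pvalue)


def select_test(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    paired: bool = False,
    normality_alpha: float = 0.05,
) -> ComparisonPlan:
    """Choose the comparison test from per-group normality.

    Two groups: t-test (paired or two-sample) when all groups pass
    normality at ``normality_alpha``, else Mann–Whitney (Wilcoxon
    signed-rank when paired).  More than two groups: one-way ANOVA or
    Kruskal–Wallis, with pairwise post-hoc correction enabled.
    """
    if not isinstance(groups, dict):
        groups = {f"group{i}": g for i, g in enumerate(groups)}
    groups = {k: np.asarray(v, float) for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, g in groups.items():
        if len(g) < 3:
            raise ValueError(f"group '{name}' has n < 3")
        if np.ptp(g) == 0:
            raise ValueError(f"group '{name}' has zero variance")
    pvals = {name: _normality_p(g) for name, g in groups.items()}
    all_normal = all(p > normality_alpha for p in pvals.values())
    k = len(groups)
    if k == 2:
        if all_normal:
            test = "paired_t" if paired else "t"
        else:
            test = "wilcoxon" if paired else "mann_whitney"
    else:
        test = "anova" if all_normal else "kruskal_wallis"
    return ComparisonPlan(
        groups=groups,
        paired=paired,
        normality_alpha=normality_alpha,
        all_normal=all_normal,
        normality_pvalues=pvals,
        chosen_test=test,
        multiple_comparison=k > 2,
    )


def holm_correction(pvalues: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj.tolist()


def _pairwise_test(a: np.ndarray, b: np.ndarray, parametric: bool) -> float:
    if parametric:
        return float(sps.ttest_ind(a, b).pvalue)
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def run_comparison(plan: ComparisonPlan) -> dict:
    """Execute the planned test and summarize the groups.

    Returns the test name, statistic, two-sided p-value, per-group
    median/quartile summaries and, for omnibus tests, a pairwise
    post-hoc table with Holm-corrected p-values.
    """
    groups = plan.groups
    for name, g in groups.items():
        if np.ptp(g) == 0:
            raise ValueError(f"group '{name}' has zero variance")
    arrays = list(groups.values())
    names = list(groups.keys())
    if plan.chosen_test == "t":
        res = sps.ttest_ind(*arrays)
    elif plan.chosen_test == "paired_t":
        res = sps.ttest_rel(*arrays)
    elif plan.chosen_test == "mann_whitney":
        res = sps.mannwhitneyu(*arrays, alternative="two-sided")
    elif plan.chosen_test == "wilcoxon":
        res = sps.wilcoxon(*arrays)
    elif plan.chosen_test == "anova":
        res = sps.f_oneway(*arrays)
    elif plan.chosen_test == "kruskal_wallis":
        res = sps.kruskal(*arrays)
    else:
        raise ValueError(f"unknown test '{plan.chosen_test}'")
    out = {
        "test": plan.chosen_test,
        "statistic": float(res.statistic),
        "pvalue": float(res.pvalue),
        "groups": {
            name: {
                "n": int(len(g)),
                "median": float(np.median(g)),
                "q1": float(np.quantile(g, 0.25)),
                "q3": float(np.quantile(g, 0.75)),
            }
            for name, g in groups.items()
        },
    }
    if plan.multiple_comparison:
        parametric = plan.chosen_test == "anova"
        pairs = list(combinations(names, 2))
        raw = [
            _pairwise_test(groups[a], groups[b], parametric) for a, b in pairs
        ]
        adj = holm_correction(raw)
        out["posthoc"] = [
            {"pair": f"{a} vs {b}", "pvalue_raw": pr, "pvalue_holm": pa}
            for (a, b), pr, pa in zip(pairs, raw, adj)
        ]
        out["correction"] = "holm"
    return out
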