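"""Statistical machinery shared by the categorization and clustering stages.

Two patterns recur throughout the pipeline:

* proportion comparisons between populations, using a chi-squared test
  unless a cell count is too small for its assumptions (any cell < 5), in
  which case Fisher's exact test is used;
* prevalence comparisons across >= 3 groups, using a Kruskal-Wallis test on
  leave-one-subject-out count distributions followed, when significant, by
  pairwise Wilcoxon rank-sum post hocs of the largest group against each
  other group at a Bonferroni-adjusted alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ProportionTestResult:
    test: str  # "chi2" or "fisher"
    p_value: float
    statistic: float


@dataclass
class PrevalenceTestResult:
    """Kruskal-Wallis omnibus plus optional largest-vs-rest post hocs."""

    kw_statistic: float
    kw_p: float
    significant: bool
    reference_group: object = None  # group with the largest mean
    adjusted_alpha: float = float("nan")
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)


def proportion_test(table) -> ProportionTestResult:
    """Compare proportions in a contingency table.

    Chi-squared by default; Fisher's exact test when the table is 2x2 and
    any observed cell is below 5 (the chi-squared small-sample violation).
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.size == 0:
        raise ValueError("contingency table must be 2-D and non-empty")
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("contingency table must hold non-negative integers")
    if tab.sum() == 0:
        raise ValueError("degenerate contingency table: all cells zero")
    if tab.shape == (2, 2) and tab.min() < 5:
        odds, p = sps.fisher_exact(tab)
        return ProportionTestResult("fisher", float(p), float(odds))
    chi2, p, _, _ = sps.chi2_contingency(tab)
    return ProportionTestResult("chi2", float(p), float(chi2))


def ranksum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value (exact for small samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum groups must be non-empty")
    method = "exact" if (x.size <= 25 and y.size <= 25) else "auto"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method=method).pvalue)


def signed_rank(x: Sequence[float], y: Sequence[float]) -> float:
    """Paired Wilcoxon signed-rank p-value; 1.0 when all differences are 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("signed-rank requires equal-length non-empty pairs")
    d = x - y
    if np.all(d == 0):
        return 1.0
    return float(sps.wilcoxon(x, y, zero_method="wilcox").pvalue)


def kruskal_with_posthoc(groups: Mapping[object, Sequence[float]],
                         alpha: float = 0.05) -> PrevalenceTestResult:
    """Kruskal-Wallis across groups; if significant, compare the group with
    the highest mean pairwise (rank-sum) against every other group, with the
    significance level Bonferroni-divided by the number of pairs tested."""
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if any(s.size == 0 for s in samples):
        raise ValueError("all groups must be non-empty")
    # identical samples across all groups: Kruskal-Wallis is undefined
    # (zero variance); report trivially non-significant
    flat = np.concatenate(samples)
    if np.all(flat == flat[0]):
        return PrevalenceTestResult(0.0, 1.0, False)
    kw = sps.kruskal(*samples)
    res = PrevalenceTestResult(float(kw.statistic), float(kw.pvalue),
                               bool(kw.pvalue < alpha))
    if not res.significant:
        return res
    means = [s.mean() for s in samples]
    ref = int(np.argmax(means))
    others = [i for i in range(len(labels)) if i != ref]
    res.reference_group = labels[ref]
    res.adjusted_alpha = alpha / len(others)
    rows = []
    for i in others:
        p = ranksum(samples[ref], samples[i])
        rows.append(
            {
                "reference": labels[ref],
                "other": labels[i],
                "p_value": p,
                "significant": p < res.adjusted_alpha,
            }
        )
    res.posthoc = pd.DataFrame(rows)
    return res


def ols_slope_ci(y: Sequence[float], x: Sequence[float] | None = None,
                 ci_level: float = 0.95) -> tuple[float, float, float]:
    """Ordinary least-squares slope with a t-based confidence interval.

    Returns ``(slope, low, high)``.
    """
    y = np.asarray(y, dtype=float)
    if x is None:
        x = np.arange(y.size, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need >= 3 paired observations for a slope CI")
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct x values")
    dof = y.size - 2
    xc = x - x.mean()
    ss_xx = float(np.sum(xc**2))
    slope = float(np.sum(xc * y) / ss_xx)
    resid = y - (y.mean() + slope * xc)
    ss_res = float(np.sum(resid**2))
    stderr = np.sqrt(ss_res / dof / ss_xx)  # 0 for an exact line
    tcrit = sps.t.ppf(0.5 + ci_level / 2.0, dof)
    half = tcrit * stderr
    return slope, slope - half, slope + half
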