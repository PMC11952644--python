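"""Group comparisons and correlations used throughout the analyses.

Two-group designs use the two-sample t-test (pooled variance by default,
Welch optional) or the Wilcoxon rank-sum test; multi-group designs use
one-way ANOVA with Tukey's HSD post hoc or Kruskal-Wallis with Dunn's post
hoc (rank z-statistics with tie correction, Holm-adjusted). Tests are
two-sided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "compare_groups", "pearson_r", "dunn_test", "ranksum_p"]

DESIGNS = ("ttest", "ranksum", "anova_tukey", "kw_dunn")


@dataclass
class TestResult:
    test_name: str
    groups: list[str]
    statistic: float
    p_value: float
    posthoc_pairs: list[tuple[tuple[str, str], float]] = field(default_factory=list)

    def posthoc_p(self, a: str, b: str) -> float:
        for (g1, g2), p in self.posthoc_pairs:
            if {g1, g2} == {a, b}:
                return p
        raise KeyError(f"no post hoc pair ({a}, {b})")


def compare_groups(values: dict[str, np.ndarray], design: str = "ttest",
                   equal_var: bool = True, paired: bool = False) -> TestResult:
    """Run the named test on a mapping of group name -> 1D samples.

    For omnibus designs the post hoc adjusted p-values cover every group
    pair. Variance-based designs require at least 2 values per group.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {DESIGNS}")
    names = list(values)
    groups = [np.asarray(values[k], dtype=float) for k in names]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if design in ("ttest", "anova_tukey") and any(g.size < 2 for g in groups):
        raise ValueError("variance-based tests need >= 2 values per group")

    if design == "ttest":
        if len(groups) != 2:
            raise ValueError("t-test takes exactly 2 groups")
        if paired:
            stat, p = sps.ttest_rel(groups[0], groups[1])
        else:
            stat, p = sps.ttest_ind(groups[0], groups[1], equal_var=equal_var)
        return TestResult("ttest", names, float(stat), float(p))

    if design == "ranksum":
        if len(groups) != 2:
            raise ValueError("rank-sum test takes exactly 2 groups")
        stat, p = sps.ranksums(groups[0], groups[1])
        return TestResult("ranksum", names, float(stat), float(p))

    if design == "anova_tukey":
        stat, p = sps.f_oneway(*groups)
        tk = sps.tukey_hsd(*groups)
        pairs = [((names[i], names[j]), float(tk.pvalue[i, j]))
                 for i, j in itertools.combinations(range(len(groups)), 2)]
        return TestResult("anova_tukey", names, float(stat), float(p), pairs)

    stat, p = sps.kruskal(*groups)
    pairs = dunn_test(dict(zip(names, groups)))
    return TestResult("kw_dunn", names, float(stat), float(p), pairs)


def dunn_test(values: dict[str, np.ndarray],
              p_adjust: str = "holm") -> list[tuple[tuple[str, str], float]]:
    """Dunn's post hoc test after Kruskal-Wallis.

    Pairwise z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))
    on the joint ranks, with tie correction T = sum(t^3 - t)/(12(N-1));
    two-sided normal p-values, adjusted across pairs (Holm by default,
    ``p_adjust=None`` for raw).
    """
    names = list(values)
    groups = [np.asarray(values[k], dtype=float) for k in names]
    pooled = np.concatenate(groups)
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (12.0 * (n_tot - 1)))
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    raw = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt((n_tot * (n_tot + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        raw.append(2.0 * sps.norm.sf(abs(z)))
    if p_adjust is None:
        adj = raw
    else:
        adj = multipletests(raw, method=p_adjust)[1]
    return [((names[i], names[j]), float(p)) for (i, j), p
            in zip(itertools.combinations(range(len(groups)), 2), adj)]


def ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value (convenience wrapper)."""
    return float(sps.ranksums(np.asarray(x, float), np.asarray(y, float)).pvalue)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of >= 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(sps.pearsonr(x, y).statistic)
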