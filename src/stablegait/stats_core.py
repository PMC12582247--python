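"""Core statistics: Chatterjee's xi, Cohen's d, and the group-test gateway.

Chatterjee's rank correlation is the package's primary dependence measure --
unlike Pearson's r it detects non-monotone association -- and is implemented
here from first principles (sort by x with seeded random tie-breaks, rank y,
normalize the sum of successive rank differences, with the tie-corrected
denominator).  Standard tests (Shapiro-Wilk, Wilcoxon, Kolmogorov-Smirnov,
Kruskal-Wallis) are delegated to scipy through one gateway that applies the
normality gate and logs every choice; Dunn's post hoc with FDR correction is
implemented locally on the pooled Kruskal-Wallis ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("stablegait")

__all__ = [
    "XiResult",
    "chatterjee_xi",
    "effect_size_d",
    "compare_groups",
    "dunn_posthoc",
]


@dataclass(frozen=True)
class XiResult:
    """Chatterjee's xi with its asymptotic (or permutation) p-value."""
    xi: float
    p: float
    n: int
    tie_handling: str

    def __iter__(self):
        return iter((self.xi, self.p))


def _xi_statistic(x: np.ndarray, y: np.ndarray,
                  rng: np.random.Generator) -> tuple[float, str]:
    n = len(x)
    # sort by x, breaking ties at random (seeded)
    jitter = rng.random(n)
    order = np.lexsort((jitter, x))
    ys = y[order]
    # r_i = #{j: y_j <= y_i}; l_i = #{j: y_j >= y_i}
    sort_idx = np.argsort(ys, kind="mergesort")
    ranked = ys[sort_idx]
    right = np.searchsorted(ranked, ys, side="right")
    left = np.searchsorted(ranked, ys, side="left")
    r = right.astype(float)
    l = (n - left).astype(float)
    num = float(np.sum(np.abs(np.diff(r))))
    has_ties = len(np.unique(ys)) < n
    if has_ties:
        denom = 2.0 * float(np.sum(l * (n - l)))
        if denom == 0.0:  # constant y
            return 0.0, "constant"
        return 1.0 - n * num / denom, "mid-count"
    return 1.0 - 3.0 * num / (n ** 2 - 1.0), "none"


def chatterjee_xi(x, y, method: str = "asymptotic",
                  n_permutations: int = 1000, seed: int = 0) -> XiResult:
    """Chatterjee's xi coefficient of ``y`` against ``x`` with an
    independence test.

    The statistic is asymmetric by design (dependence of y on x).  Under
    independence and continuous marginals, ``sqrt(n) * xi`` is asymptotically
    Normal(0, 2/5); the right-tailed p-value from that limit is the default.
    ``method="permutation"`` replaces it with a seeded permutation null for
    small samples.  A constant ``y`` yields xi = 0, flagged via
    ``tie_handling="constant"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 5:
        raise ValueError("need n >= 5")
    rng = np.random.default_rng(seed)
    xi, ties = _xi_statistic(x, y, rng)
    if ties == "constant":
        return XiResult(xi=0.0, p=1.0, n=n, tie_handling=ties)
    if method == "asymptotic":
        z = np.sqrt(n) * xi / np.sqrt(2.0 / 5.0)
        p = float(stats.norm.sf(z))
    elif method == "permutation":
        null = np.empty(n_permutations)
        for k in range(n_permutations):
            null[k], _ = _xi_statistic(x, rng.permutation(y), rng)
        p = float((1 + np.sum(null >= xi)) / (1 + n_permutations))
    else:
        raise ValueError(f"unknown method {method!r}")
    return XiResult(xi=float(xi), p=p, n=n, tie_handling=ties)


def effect_size_d(a, b, paired: bool = False) -> float:
    """Cohen's d: standardized mean difference (pooled SD), or mean paired
    difference over the SD of differences when ``paired``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        diff = a - b
        sd = diff.std(ddof=1)
        if sd == 0:
            raise ValueError("zero SD of paired differences")
        return float(diff.mean() / sd)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD")
    return float((a.mean() - b.mean()) / pooled)


def dunn_posthoc(groups: dict[str, np.ndarray], fdr: bool = True,
                 ) -> dict[tuple[str, str], dict]:
    """Dunn's rank-based post hoc comparisons after Kruskal-Wallis.

    z statistics use the pooled mid-ranks with the standard tie correction;
    two-sided normal p-values are FDR-corrected (Benjamini-Hochberg) by
    default.
    """
    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float)
                             for g in labels])
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (N - 1))
    mean_rank = {}
    i = 0
    for g in labels:
        n_g = len(groups[g])
        mean_rank[g] = float(ranks[i:i + n_g].mean())
        i += n_g
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    pvals, zs = [], []
    for a, b in pairs:
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                     * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_rank[a] - mean_rank[b]) / se
        zs.append(z)
        pvals.append(2.0 * stats.norm.sf(abs(z)))
    if fdr and pvals:
        _, pvals, *_ = multipletests(pvals, method="fdr_bh")
    return {pair: {"z": float(z), "p": float(p)}
            for pair, z, p in zip(pairs, zs, pvals)}


def compare_groups(groups: dict[str, np.ndarray], paired: bool = False,
                   alpha_normality: float = 0.05) -> dict:
    """Normality-gated group comparison through one logged gateway.

    Shapiro-Wilk decides the path: parametric (paired/independent t test,
    one-way ANOVA) when every group (or the paired differences) passes,
    otherwise nonparametric (Wilcoxon signed-rank, Mann-Whitney U,
    Kruskal-Wallis with Dunn's FDR-corrected post hoc).  Returns test name,
    statistic, p, Cohen's d for two groups, and post hoc table for more.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")

    def normal(x: np.ndarray) -> bool:
        if len(x) < 3 or np.ptp(x) == 0:
            return False
        return stats.shapiro(x).pvalue >= alpha_normality

    out: dict = {"groups": {g: len(a) for g, a in zip(labels, arrays)},
                 "paired": paired}
    if len(arrays) == 2:
        a, b = arrays
        if paired:
            gate = normal(a - b)
            if gate:
                res = stats.ttest_rel(a, b)
                out.update(test="paired t", statistic=float(res.statistic),
                           p=float(res.pvalue))
            else:
                res = stats.wilcoxon(a, b)
                out.update(test="wilcoxon signed-rank",
                           statistic=float(res.statistic),
                           p=float(res.pvalue))
        else:
            gate = normal(a) and normal(b)
            if gate:
                res = stats.ttest_ind(a, b)
                out.update(test="t", statistic=float(res.statistic),
                           p=float(res.pvalue))
            else:
                res = stats.mannwhitneyu(a, b)
                out.update(test="mann-whitney U",
                           statistic=float(res.statistic),
                           p=float(res.pvalue))
        out["d"] = effect_size_d(a, b, paired=paired)
        out["normality_gate"] = bool(gate)
    else:
        gate = all(normal(a) for a in arrays)
        if gate:
            res = stats.f_oneway(*arrays)
            out.update(test="one-way ANOVA", statistic=float(res.statistic),
                       p=float(res.pvalue))
        else:
            res = stats.kruskal(*arrays)
            out.update(test="kruskal-wallis", statistic=float(res.statistic),
                       p=float(res.pvalue))
        out["normality_gate"] = bool(gate)
        out["posthoc"] = {f"{a}|{b}": v for (a, b), v in
                          dunn_posthoc(dict(zip(labels, arrays))).items()}
    logger.info("compare_groups: %s -> %s, p=%.4g",
                labels, out["test"], out["p"])
    return out
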