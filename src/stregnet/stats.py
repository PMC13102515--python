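"""Statistical primitives shared across the pipeline.

Correlation with significance, one-sided hypergeometric (Fisher)
over-representation, Benjamini-Hochberg FDR, Welch's two-sample t test,
Wilcoxon rank-sum for marker detection, and term enrichment over a gene
annotation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_with_p",
    "fisher_enrichment",
    "bh_adjust",
    "welch_t",
    "wilcoxon_rank_sum",
    "term_enrichment",
    "EnrichmentRow",
]

# exact enumeration is used when both groups are at most this size
EXACT_RANKSUM_MAX_N = 8


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the t transform.

    ``t = r * sqrt(n-2) / sqrt(1-r^2)`` on n-2 degrees of freedom.
    Constant input yields ``(nan, nan)`` — a flagged missing result, not
    a silent zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def fisher_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric P(X >= k): one-sided over-representation.

    ``k`` hits in a drawn set of size ``n``, ``K`` marked in a universe
    of ``N``.  This is the one-sided "Fisher test" convention used for
    pathway screening.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if k > min(n, K):
        raise ValueError("k exceeds min(n, K)")
    if k == 0:
        return 1.0
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    ``q_(i) = min_{j >= i} p_(j) * m / j``, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch's t statistic and two-sided p (Welch-Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum p; exact by enumeration for small groups.

    Mid-ranks handle ties.  When both groups have at most
    ``EXACT_RANKSUM_MAX_N`` observations the p-value is the exact
    permutation tail over all C(n+m, n) label assignments; otherwise the
    normal approximation with tie correction (Mann-Whitney U, asymptotic)
    is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("empty group")
    if n <= EXACT_RANKSUM_MAX_N and m <= EXACT_RANKSUM_MAX_N:
        pooled = np.concatenate([x, y])
        ranks = scipy.stats.rankdata(pooled)
        w_obs = ranks[:n].sum()
        mu = n * (n + m + 1) / 2.0
        dev_obs = abs(w_obs - mu)
        total = 0
        extreme = 0
        for idx in combinations(range(n + m), n):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev_obs - 1e-9:
                extreme += 1
        return extreme / total
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's over-representation result within a gene set."""

    term_id: str
    k: int  # hits in gene set
    n: int  # gene-set size
    K: int  # hits in universe
    N: int  # universe size
    p: float
    q: float

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValueError("k exceeds min(n, K)")


def term_enrichment(gene_set, annotation, universe) -> list[EnrichmentRow]:
    """One-sided hypergeometric enrichment of every annotated term.

    Every term with at least one member in the universe is tested;
    q-values are BH-adjusted across the full tested set and rows come
    back sorted by q (ties by p, then term id).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    if not gene_set:
        logger.warning("empty gene set: no enrichment computed")
        return []
    N = len(universe)
    n = len(gene_set)
    rows = []
    for term_id, members in sorted(annotation.term_sets().items()):
        members = members & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & gene_set)
        rows.append((term_id, k, K, fisher_enrichment(k, n, K, N)))
    if not rows:
        return []
    qvals = bh_adjust([p for (_, _, _, p) in rows])
    result = [
        EnrichmentRow(term_id, k, n, K, N, p, float(q))
        for (term_id, k, K, p), q in zip(rows, qvals)
    ]
    result.sort(key=lambda r: (r.q, r.p, r.term_id))
    return result
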