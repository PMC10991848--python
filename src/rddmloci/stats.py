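"""Overlap-enrichment statistics.

The central quantity is the log2(observed/expected) enrichment of a locus
subset for some genomic feature, with the expected count defined by
proportional allocation::

    expected = K * n / N

where N is the size of the locus universe (e.g. all Pol V peaks), K the
number of universe loci overlapping the feature (e.g. peaks with a DMR), n
the size of the subset of interest and k the observed number of subset loci
overlapping the feature.  Significance comes from the hypergeometric
distribution (one-sided, tail chosen by the direction of deviation) and
multiple testing is handled by Benjamini-Hochberg.  Between-set comparisons
use log2 ratios of means with Mann-Whitney U significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OverlapCounts",
    "EnrichmentResult",
    "hypergeom_pvalue",
    "overlap_enrichment",
    "bh_adjust",
    "mann_whitney",
    "Log2RatioResult",
    "log2_set_ratio",
    "enrichment_to_fold",
]


@dataclass(frozen=True)
class OverlapCounts:
    """Counts of a 2x2 overlap design: ``N`` loci in the universe, ``K`` of
    them overlapping the feature, ``n`` loci of interest, ``k`` of those
    overlapping the feature."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("universe size N must be positive")
        if not (0 <= self.K <= self.N):
            raise ValueError(f"require 0 <= K <= N, got K={self.K}, N={self.N}")
        if not (0 < self.n <= self.N):
            raise ValueError(f"require 0 < n <= N, got n={self.n}, N={self.N}")
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(
                f"require 0 <= k <= min(K, n), got k={self.k}, K={self.K}, n={self.n}"
            )


@dataclass
class EnrichmentResult:
    observed: int
    expected: float
    log2_enrichment: float  # NaN when k == 0 (flagged undefined, no pseudocount)
    p_value: float
    direction: str  # {"enriched", "depleted", "undefined"}
    q_value: float = field(default=float("nan"))

    @property
    def defined(self) -> bool:
        return self.direction != "undefined"


def hypergeom_pvalue(N: int, K: int, n: int, k, alternative: str = "auto"):
    """Hypergeometric tail probability for drawing ``k`` marked loci.

    ``alternative``: "greater" gives P(X >= k), "less" gives P(X <= k),
    "auto" picks the tail on the side of the deviation from the expectation
    K*n/N.  ``k`` may be an array.
    """
    k = np.asarray(k)
    if alternative == "greater":
        p = sps.hypergeom.sf(k - 1, N, K, n)
    elif alternative == "less":
        p = sps.hypergeom.cdf(k, N, K, n)
    elif alternative == "auto":
        expected = K * n / N
        upper = sps.hypergeom.sf(k - 1, N, K, n)
        lower = sps.hypergeom.cdf(k, N, K, n)
        p = np.where(k >= expected, upper, lower)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(np.clip(p, 0.0, 1.0)) if p.ndim == 0 else np.clip(p, 0.0, 1.0)


def overlap_enrichment(c: OverlapCounts) -> EnrichmentResult:
    """log2(observed/expected) enrichment with hypergeometric significance.

    ``expected = K*n/N``.  When ``k = 0`` the log2 enrichment is undefined
    (reported as NaN without a pseudocount; display layers may floor it) and
    the p-value comes from the lower tail.
    """
    expected = c.K * c.n / c.N
    if c.k == 0:
        direction = "undefined"
        enrichment = float("nan")
        p = hypergeom_pvalue(c.N, c.K, c.n, c.k, "less")
    else:
        # k > 0 forces K > 0 and hence expected > 0
        enrichment = math.log2(c.k / expected)
        direction = "enriched" if c.k >= expected else "depleted"
        p = hypergeom_pvalue(
            c.N, c.K, c.n, c.k, "greater" if c.k >= expected else "less"
        )
    return EnrichmentResult(c.k, expected, enrichment, p, direction)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney(x, y, exact_max: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    Uses exact enumeration for combined sizes <= ``exact_max`` without ties,
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (x.size + y.size <= exact_max and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class Log2RatioResult:
    log2_ratio: float
    u_statistic: float
    p_value: float


def log2_set_ratio(values_pos, values_neg) -> Log2RatioResult:
    """log2(mean(pos)/mean(neg)) with Mann-Whitney significance on the
    per-locus vectors; non-positive means are an error."""
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both sets must be non-empty")
    mp, mn = float(pos.mean()), float(neg.mean())
    if mp <= 0 or mn <= 0:
        raise ValueError(f"means must be positive, got {mp} and {mn}")
    u, p = mann_whitney(pos, neg)
    return Log2RatioResult(math.log2(mp / mn), u, p)


def enrichment_to_fold(log2_enrichment: float) -> float:
    """Fold change corresponding to a log2 enrichment (2**e)."""
    return float(2.0 ** log2_enrichment)
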