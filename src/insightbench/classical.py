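"""Supporting classical statistics: Fisher exact, rank-sum, median/IQR.

These are self-contained reference implementations with fixed, documented
conventions:

* :func:`fisher_exact` — two-sided p by the probability-mass rule: the sum of
  hypergeometric probabilities of every margin-preserving table no more likely
  than the observed one (relative tolerance 1e-7 on the comparison), evaluated
  in exact integer arithmetic.
* :func:`ranksum` — Wilcoxon rank-sum with midranks for ties, tie-corrected
  variance, no continuity correction; two-sided p from the normal
  approximation.
* :func:`median_iqr` — midpoint-interpolation empirical quantiles (position
  ``h = q * n + 0.5``, linear interpolation between order statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "ContingencyTable2x2",
    "RankSumResult",
    "QuantileSummary",
    "fisher_exact",
    "ranksum",
    "median_iqr",
    "midpoint_quantile",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of non-negative counts (rows: groups, columns: outcomes)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("table entries must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("table must contain at least one non-zero entry")


@dataclass(frozen=True)
class RankSumResult:
    z: float
    p: float
    n1: int
    n2: int
    statistic: float  # rank sum of the first sample


@dataclass(frozen=True)
class QuantileSummary:
    median: float
    q1: float
    q3: float


def _coerce_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    return ContingencyTable2x2(*(int(x) for x in arr.ravel()))


def fisher_exact(table, rtol: float = 1e-7) -> float:
    """Two-sided Fisher exact p-value on a 2x2 table.

    Conditional on both margins, cell (0,0) is hypergeometric; the p-value
    sums the probabilities of all tables whose probability does not exceed
    that of the observed table by more than a relative ``rtol``.
    """
    t = _coerce_table(table)
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = r1 + r2
    # Unnormalized weights comb(r1, k) * comb(r2, c1 - k); exact integers.
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    observed = weights[t.a]
    cutoff = Fraction(observed) * (1 + Fraction(rtol))
    kept = sum(w for w in weights.values() if w <= cutoff)
    p = Fraction(kept, math.comb(n, c1))
    return min(1.0, float(p))


def ranksum(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Wilcoxon rank-sum test via the tie-corrected normal approximation.

    ``z = (W - E[W]) / sqrt(Var[W])`` where ``W`` is the midrank sum of ``x``
    and the variance carries the usual tie correction; no continuity
    correction.  Two-sided ``p = 2 * (1 - Phi(|z|))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    expected = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (n * (n - 1))
    variance = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if variance <= 0.0:
        return RankSumResult(z=0.0, p=1.0, n1=n1, n2=n2, statistic=w)
    z = (w - expected) / math.sqrt(variance)
    p = float(2.0 * norm.sf(abs(z)))
    return RankSumResult(z=float(z), p=min(1.0, p), n1=n1, n2=n2, statistic=w)


def midpoint_quantile(values: Sequence[float], q: float) -> float:
    """Empirical quantile at position ``h = q * n + 0.5`` (midpoint rule).

    Linear interpolation between adjacent order statistics; positions outside
    ``[1, n]`` clamp to the extreme order statistics.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("need at least one value")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    h = q * v.size + 0.5
    if h <= 1.0:
        return float(v[0])
    if h >= v.size:
        return float(v[-1])
    lo = int(math.floor(h))
    frac = h - lo
    return float(v[lo - 1] + frac * (v[lo] - v[lo - 1]))


def median_iqr(values: Sequence[float]) -> QuantileSummary:
    """Median and interquartile range under the midpoint quantile rule."""
    return QuantileSummary(
        median=midpoint_quantile(values, 0.5),
        q1=midpoint_quantile(values, 0.25),
        q3=midpoint_quantile(values, 0.75),
    )
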