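"""Placement of one answer combination among all combinations of equal score.

Core quantities:

* :func:`profile_probability` — occurrence probability of a single answer
  combination, ``prod(p_j for correct) * prod(1 - p_j for incorrect)``,
  accumulated in log space.
* :func:`enumerate_conditional` / :func:`enumerate_conditional_mitm` — the
  multiset of occurrence probabilities of *all* ``C(n, k)`` combinations
  attaining a fixed total score ``k``, either materialized by direct
  lexicographic enumeration or represented implicitly by a meet-in-the-middle
  (MITM) factorization over two battery halves.  The MITM route handles the
  pooled 30-item battery, whose score-12 level set holds 86,493,225
  combinations, in bounded memory.
* :func:`percentile_rank` / :func:`top_fraction_threshold` /
  :func:`placement` — where a given combination sits inside that conditional
  distribution.

Conventions (recorded in reports): percentile rank counts combinations with
*strictly* smaller probability (relative tolerance 1e-9 on ties); the top-q
threshold is the nearest-rank upper quantile (ascending rank
``ceil((1 - q) * m)``, no interpolation); membership in the top q is
non-strict (``probability >= threshold``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence, Union

import numpy as np

from .battery import AnswerProfile, Battery
from .scoredist import RatesLike, as_rates, joint_outcome_probabilities

__all__ = [
    "ConditionalProfileDistribution",
    "DenseConditionalDistribution",
    "MitmConditionalDistribution",
    "PlacementReport",
    "CombinationCapError",
    "profile_probability",
    "enumerate_conditional",
    "enumerate_conditional_mitm",
    "percentile_rank",
    "top_fraction_threshold",
    "placement",
]

#: Largest C(n, k) materialized by direct enumeration by default.
DEFAULT_DIRECT_CAP = 10**7

#: Default number of probabilities held per chunk on the MITM path.
DEFAULT_CHUNK_SIZE = 1 << 22

#: Relative tolerance at which two probabilities are considered tied.
TIE_RTOL = 1e-9


class CombinationCapError(ValueError):
    """Too many combinations for direct materialization."""


ProfileLike = Union[AnswerProfile, Sequence[int], np.ndarray]


def _as_bits(profile: ProfileLike) -> np.ndarray:
    bits = (
        profile.as_array()
        if isinstance(profile, AnswerProfile)
        else np.asarray(profile, dtype=np.int8)
    )
    if bits.ndim != 1 or np.any((bits != 0) & (bits != 1)):
        raise ValueError("profile must be a 1-D 0/1 vector")
    return bits


def profile_probability(battery: RatesLike, profile: ProfileLike) -> float:
    """Occurrence probability of one answer combination.

    Computed as ``exp(sum(log p_j) + sum(log(1 - p_j)))`` over correct and
    incorrect items respectively; a rate of exactly 0 (or 1) on a correct
    (incorrect) item yields probability 0.
    """
    rates = as_rates(battery)
    bits = _as_bits(profile)
    if bits.size != rates.size:
        raise ValueError(
            f"profile length {bits.size} does not match battery size {rates.size}"
        )
    with np.errstate(divide="ignore"):
        logs = np.where(bits == 1, np.log(rates), np.log1p(-rates))
    total = logs.sum()
    return 0.0 if np.isneginf(total) else float(np.exp(total))


class ConditionalProfileDistribution:
    """Multiset of occurrence probabilities of all score-``k`` combinations.

    Concrete backends are :class:`DenseConditionalDistribution` (materialized)
    and :class:`MitmConditionalDistribution` (implicit, bounded memory); both
    expose the fixed score ``k``, battery size ``n``, exact combination count
    ``m = C(n, k)`` and the query methods used by the percentile machinery.
    """

    k: int
    n: int

    @property
    def m(self) -> int:
        raise NotImplementedError

    def sum(self) -> float:
        """Total mass: equals the score PMF at ``k`` (conservation)."""
        raise NotImplementedError

    def count_less(self, t: float) -> int:
        """Number of probabilities strictly below ``t``."""
        raise NotImplementedError

    def nth_smallest(self, rank: int) -> float:
        """The ``rank``-th smallest probability (1-based)."""
        raise NotImplementedError

    def iter_chunks(self, chunk_size: int | None = None) -> Iterator[np.ndarray]:
        """Yield every probability exactly once, in deterministic chunks."""
        raise NotImplementedError

    def min(self) -> float:
        raise NotImplementedError

    def max(self) -> float:
        raise NotImplementedError

    def _check_rank(self, rank: int) -> None:
        if not 1 <= rank <= self.m:
            raise ValueError(f"rank {rank} outside 1..{self.m}")


class DenseConditionalDistribution(ConditionalProfileDistribution):
    """Materialized conditional distribution (all probabilities in memory)."""

    def __init__(self, k: int, n: int, probabilities: np.ndarray):
        self.k = int(k)
        self.n = int(n)
        self.probabilities = np.asarray(probabilities, dtype=float)
        expected = math.comb(self.n, self.k)
        if self.probabilities.size != expected:
            raise ValueError(
                f"got {self.probabilities.size} probabilities, "
                f"expected C({n},{k}) = {expected}"
            )
        self._sorted: np.ndarray | None = None

    @property
    def m(self) -> int:
        return self.probabilities.size

    def _ascending(self) -> np.ndarray:
        if self._sorted is None:
            self._sorted = np.sort(self.probabilities)
        return self._sorted

    def sum(self) -> float:
        return float(self.probabilities.sum())

    def count_less(self, t: float) -> int:
        return int(np.searchsorted(self._ascending(), t, side="left"))

    def nth_smallest(self, rank: int) -> float:
        self._check_rank(rank)
        return float(self._ascending()[rank - 1])

    def iter_chunks(self, chunk_size: int | None = None) -> Iterator[np.ndarray]:
        step = chunk_size or DEFAULT_CHUNK_SIZE
        for i in range(0, self.m, step):
            yield self.probabilities[i : i + step]

    def min(self) -> float:
        return float(self.probabilities.min())

    def max(self) -> float:
        return float(self.probabilities.max())


def _subscore_probability_lists(rates: np.ndarray) -> list[np.ndarray]:
    """Sorted occurrence probabilities of a half-battery, per sub-score.

    Element ``k`` is the ascending array of the ``C(n_half, k)`` probabilities
    of the half-battery combinations with exactly ``k`` correct answers.
    """
    n = rates.size
    joint = joint_outcome_probabilities(rates)
    scores = np.bitwise_count(np.arange(1 << n, dtype=np.uint64)).astype(np.int64)
    return [np.sort(joint[scores == k]) for k in range(n + 1)]


class MitmConditionalDistribution(ConditionalProfileDistribution):
    """Conditional distribution factored over two battery halves.

    Each full-battery combination with score ``k`` splits uniquely into a
    first-half combination with ``k1`` correct answers and a second-half one
    with ``k - k1``; independence across items makes its probability the
    product of the two half probabilities.  The distribution is therefore the
    disjoint union, over feasible ``k1``, of the outer products of two short
    per-half probability lists — small enough to store even when ``C(n, k)``
    runs into the tens of millions.
    """

    def __init__(self, k: int, rates: np.ndarray, chunk_size: int = DEFAULT_CHUNK_SIZE):
        if chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        n = rates.size
        if not 0 <= k <= n:
            raise ValueError(f"score k={k} outside 0..{n}")
        self.k = int(k)
        self.n = int(n)
        self.chunk_size = int(chunk_size)
        n1 = (n + 1) // 2  # split point ceil(n/2)
        self._lists_a = _subscore_probability_lists(rates[:n1])
        self._lists_b = _subscore_probability_lists(rates[n1:])
        n2 = n - n1
        self._pairs: list[tuple[np.ndarray, np.ndarray]] = []
        counted = 0
        for k1 in range(max(0, k - n2), min(n1, k) + 1):
            a, b = self._lists_a[k1], self._lists_b[k - k1]
            self._pairs.append((a, b))
            counted += a.size * b.size
        self._m = math.comb(n, k)
        # Vandermonde identity guarantees this; check it anyway so a half-list
        # bug cannot silently corrupt every downstream count.
        if counted != self._m:
            raise AssertionError(
                f"enumerated {counted} combinations, expected C({n},{k}) = {self._m}"
            )

    @property
    def m(self) -> int:
        return self._m

    def sum(self) -> float:
        return float(sum(a.sum() * b.sum() for a, b in self._pairs))

    def count_less(self, t: float) -> int:
        if t <= 0.0:
            return 0
        total = 0
        for a, b in self._pairs:
            pos = a[a > 0.0]
            if pos.size:
                total += int(np.searchsorted(b, t / pos, side="left").sum())
            total += (a.size - pos.size) * b.size  # zero * anything == 0 < t
        return total

    def iter_chunks(self, chunk_size: int | None = None) -> Iterator[np.ndarray]:
        step = chunk_size or self.chunk_size
        for a, b in self._pairs:
            rows = max(1, step // max(1, b.size))
            for i in range(0, a.size, rows):
                yield np.multiply.outer(a[i : i + rows], b).ravel()

    def min(self) -> float:
        return float(min(a[0] * b[0] for a, b in self._pairs))

    def max(self) -> float:
        return float(max(a[-1] * b[-1] for a, b in self._pairs))

    def nth_smallest(self, rank: int) -> float:
        self._check_rank(rank)
        keep_small = rank <= self.m - rank
        keep = rank if keep_small else self.m - rank + 1
        if keep <= 2 * self.chunk_size:
            return self._nth_by_selection(rank, keep, keep_small)
        return self._nth_by_bisection(rank)

    def _nth_by_selection(self, rank: int, keep: int, keep_small: bool) -> float:
        """Exact order statistic by chunked partial selection."""
        buf = np.empty(0)
        for chunk in self.iter_chunks():
            buf = np.concatenate([buf, chunk])
            if buf.size > keep:
                if keep_small:
                    buf = np.partition(buf, keep - 1)[:keep]
                else:
                    buf = np.partition(buf, buf.size - keep)[buf.size - keep :]
        return float(buf.max() if keep_small else buf.min())

    def _nth_by_bisection(self, rank: int) -> float:
        """Order statistic by bisection on the counting function.

        Maintains ``count_less(lo) < rank <= count_less(hi)`` until ``lo`` and
        ``hi`` are adjacent floats, at which point ``lo`` is the answer.
        """
        lo = self.min()
        hi = float(np.nextafter(self.max(), np.inf))
        while np.nextafter(lo, np.inf) < hi:
            mid = 0.5 * (lo + hi)
            if mid <= lo or mid >= hi:  # denormal-range stagnation guard
                mid = float(np.nextafter(lo, np.inf))
            if self.count_less(mid) < rank:
                lo = mid
            else:
                hi = mid
        return lo

    def histogram(self, edges: np.ndarray) -> np.ndarray:
        """Counts of probabilities in ``[edges[i], edges[i+1])`` bins."""
        counts = np.zeros(edges.size + 1, dtype=np.int64)
        for a, b in self._pairs:
            pos = a[a > 0.0]
            if pos.size:
                grid = np.searchsorted(b, edges[None, :] / pos[:, None], side="left")
                per_edge = grid.sum(axis=0)
                counts[0] += int(per_edge[0])
                counts[1:-1] += np.diff(per_edge)
                counts[-1] += pos.size * b.size - int(per_edge[-1])
            nzero = a.size - pos.size
            if nzero:
                counts[0 if edges[0] > 0.0 else int(np.searchsorted(edges, 0.0, "right"))] += (
                    nzero * b.size
                )
        return counts


def enumerate_conditional(
    battery: RatesLike, k: int, cap: int = DEFAULT_DIRECT_CAP
) -> DenseConditionalDistribution:
    """Materialize the probabilities of all score-``k`` combinations.

    Combinations are enumerated in lexicographic order of correct-item index
    sets.  Refuses to materialize more than ``cap`` combinations; use
    :func:`enumerate_conditional_mitm` beyond that.
    """
    rates = as_rates(battery)
    n = rates.size
    if not 0 <= k <= n:
        raise ValueError(f"score k={k} outside 0..{n}")
    m = math.comb(n, k)
    if m > cap:
        raise CombinationCapError(
            f"C({n},{k}) = {m} exceeds the direct-enumeration cap ({cap}); "
            "use enumerate_conditional_mitm"
        )
    with np.errstate(divide="ignore"):
        log_correct = np.log(rates)  # -inf where rate == 0
        log_wrong = np.log1p(-rates)  # -inf where rate == 1
    # Split each log into a finite part and a zero-probability indicator so
    # that rates of exactly 0 or 1 stay exact (their combinations get
    # probability 0 but are still enumerated and counted).
    inf_correct = np.isneginf(log_correct)
    inf_wrong = np.isneginf(log_wrong)
    fin_correct = np.where(inf_correct, 0.0, log_correct)
    fin_wrong = np.where(inf_wrong, 0.0, log_wrong)
    base_log = fin_wrong.sum()
    base_zeros = int(inf_wrong.sum())
    delta_log = fin_correct - fin_wrong
    delta_zeros = inf_correct.astype(np.int64) - inf_wrong.astype(np.int64)
    probs = np.empty(m)
    for i, idx in enumerate(combinations(range(n), k)):
        sel = list(idx)
        if base_zeros + delta_zeros[sel].sum():
            probs[i] = 0.0
        else:
            probs[i] = np.exp(base_log + delta_log[sel].sum())
    return DenseConditionalDistribution(k, n, probs)


def enumerate_conditional_mitm(
    battery: RatesLike, k: int, chunk_size: int = DEFAULT_CHUNK_SIZE
) -> MitmConditionalDistribution:
    """Meet-in-the-middle conditional distribution (bounded memory, any k).

    Produces exactly the same multiset of probabilities as
    :func:`enumerate_conditional`, without ever holding more than about
    ``chunk_size`` of them at once.
    """
    return MitmConditionalDistribution(k, as_rates(battery), chunk_size=chunk_size)


def percentile_rank(
    distribution: ConditionalProfileDistribution, p: float, rtol: float = TIE_RTOL
) -> float:
    """Percentile of ``p``: 100 x (fraction of strictly smaller probabilities).

    Probabilities within relative tolerance ``rtol`` of ``p`` count as ties
    and are excluded, so every member of an all-equal distribution sits at
    percentile 0.
    """
    cutoff = p * (1.0 - rtol) if p > 0 else 0.0
    return 100.0 * distribution.count_less(cutoff) / distribution.m


def top_fraction_threshold(
    distribution: ConditionalProfileDistribution, q: float
) -> float:
    """Probability separating the fraction ``q`` of most probable combinations.

    Nearest-rank upper quantile: the ``ceil((1 - q) * m)``-th smallest
    probability.  Non-increasing in ``q``.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    rank = math.ceil((1.0 - q) * distribution.m)
    return distribution.nth_smallest(max(1, rank))


@dataclass(frozen=True)
class PlacementReport:
    """Placement of one answer combination within its score level set."""

    profile_probability: float
    percentile_rank: float
    top_q_threshold: float
    in_top_q: bool
    q: float
    k: int
    n: int
    m: int
    method: str  # "direct" or "mitm"

    def to_dict(self) -> dict:
        return {
            "profile_probability": self.profile_probability,
            "percentile_rank": self.percentile_rank,
            "top_q_threshold": self.top_q_threshold,
            "in_top_q": self.in_top_q,
            "q": self.q,
            "k": self.k,
            "n": self.n,
            "m": self.m,
            "method": self.method,
        }


def build_conditional(
    battery: RatesLike,
    k: int,
    direct_cap: int = DEFAULT_DIRECT_CAP,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> ConditionalProfileDistribution:
    """Direct enumeration when ``C(n, k) <= direct_cap``, else MITM."""
    rates = as_rates(battery)
    if math.comb(rates.size, k) <= direct_cap:
        return enumerate_conditional(rates, k, cap=direct_cap)
    return enumerate_conditional_mitm(rates, k, chunk_size=chunk_size)


def placement(
    battery: RatesLike,
    profile: ProfileLike,
    q: float = 0.05,
    direct_cap: int = DEFAULT_DIRECT_CAP,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> PlacementReport:
    """Full placement of a profile among the combinations of equal score."""
    rates = as_rates(battery)
    bits = _as_bits(profile)
    if bits.size != rates.size:
        raise ValueError(
            f"profile length {bits.size} does not match battery size {rates.size}"
        )
    k = int(bits.sum())
    dist = build_conditional(rates, k, direct_cap=direct_cap, chunk_size=chunk_size)
    p = profile_probability(rates, bits)
    threshold = top_fraction_threshold(dist, q)
    in_top = p >= threshold * (1.0 - TIE_RTOL)
    return PlacementReport(
        profile_probability=p,
        percentile_rank=percentile_rank(dist, p),
        top_q_threshold=threshold,
        in_top_q=bool(in_top),
        q=q,
        k=k,
        n=rates.size,
        m=dist.m,
        method="mitm" if isinstance(dist, MitmConditionalDistribution) else "direct",
    )
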