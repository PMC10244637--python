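"""Exact distribution of the total score under independent per-item rates.

With item ``j`` answered correctly with probability ``p_j`` independently of
the other items, the total score follows a Poisson-binomial distribution.  Two
routes compute it exactly: :func:`score_pmf_enumerate` sums the occurrence
probability of every one of the ``2**n`` answer combinations (the brute-force
oracle, capped at small ``n``) and :func:`score_pmf_dp` runs the standard
``O(n^2)`` convolution recursion; the two agree to within 1e-12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .battery import Battery

__all__ = [
    "ScorePMF",
    "EnumerationCapError",
    "score_pmf_enumerate",
    "score_pmf_dp",
    "pmf_mode",
    "total_variation",
]

RatesLike = Union[Battery, Sequence[float], np.ndarray]

#: Largest n for which full 2**n outcome enumeration is allowed by default.
DEFAULT_ENUMERATION_CAP = 20


class EnumerationCapError(ValueError):
    """Battery too large for full outcome enumeration."""


def as_rates(battery: RatesLike) -> np.ndarray:
    """Coerce a battery or bare sequence to a validated rate vector."""
    rates = battery.rates if isinstance(battery, Battery) else np.asarray(
        battery, dtype=float
    )
    if rates.ndim != 1 or rates.size == 0:
        raise ValueError("rates must be a non-empty 1-D vector")
    if np.any((rates < 0.0) | (rates > 1.0)):
        raise ValueError("rates must lie in [0, 1]")
    return rates


@dataclass(frozen=True)
class ScorePMF:
    """Probability of each total score ``k = 0..n`` (``probs[k]``)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1 or probs.size < 1:
            raise ValueError("probs must be a non-empty 1-D vector")
        if np.any(probs < -1e-15):
            raise ValueError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError(f"probabilities sum to {probs.sum()!r}, not 1")
        probs = np.clip(probs, 0.0, None)
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)

    @property
    def n(self) -> int:
        return self.probs.size - 1

    def __getitem__(self, k: int) -> float:
        return float(self.probs[k])

    def __len__(self) -> int:
        return self.probs.size

    def mean(self) -> float:
        return float(np.arange(self.probs.size) @ self.probs)

    def to_frame(self) -> pd.DataFrame:
        """Two-column table (score, probability)."""
        return pd.DataFrame(
            {"score": np.arange(self.probs.size), "probability": self.probs}
        )


def _popcounts(n: int) -> np.ndarray:
    masks = np.arange(1 << n, dtype=np.uint64)
    return np.bitwise_count(masks).astype(np.int64)


def joint_outcome_probabilities(rates: np.ndarray) -> np.ndarray:
    """Probability of each of the ``2**n`` answer combinations.

    Entry ``m`` is the occurrence probability of the combination whose bit
    ``j`` (LSB = item 0) indicates a correct answer on item ``j``.
    """
    probs = np.array([1.0])
    for p in rates:
        probs = np.concatenate([probs * (1.0 - p), probs * p])
    return probs


def score_pmf_enumerate(
    battery: RatesLike, cap: int = DEFAULT_ENUMERATION_CAP
) -> ScorePMF:
    """Exact score PMF by enumerating all ``2**n`` answer combinations.

    ``probs[k]`` is the sum, over the ``C(n, k)`` combinations with exactly
    ``k`` correct answers, of the product of ``p_j`` over correct items and
    ``1 - p_j`` over incorrect ones.  Cost is exponential; batteries larger
    than ``cap`` are refused.
    """
    rates = as_rates(battery)
    n = rates.size
    if n > cap:
        raise EnumerationCapError(
            f"n={n} exceeds the enumeration cap ({cap}); use score_pmf_dp, "
            "which is exact at any n"
        )
    joint = joint_outcome_probabilities(rates)
    probs = np.bincount(_popcounts(n), weights=joint, minlength=n + 1)
    return ScorePMF(probs)


def score_pmf_dp(battery: RatesLike) -> ScorePMF:
    """Exact score PMF by iterative convolution (any ``n``, ``O(n^2)``).

    Starting from the empty battery (point mass at 0), each item updates
    ``probs'[k] = probs[k] * (1 - p_j) + probs[k - 1] * p_j``.
    """
    rates = as_rates(battery)
    probs = np.array([1.0])
    for p in rates:
        nxt = np.empty(probs.size + 1)
        nxt[:-1] = probs * (1.0 - p)
        nxt[-1] = 0.0
        nxt[1:] += probs * p
        probs = nxt
    return ScorePMF(probs)


def pmf_mode(pmf: ScorePMF, tol: float = 1e-12) -> tuple[int, bool]:
    """Most probable total score.

    Returns ``(score, tied)`` where ``score`` is the smallest maximizing score
    and ``tied`` flags another score attaining the maximum within ``tol``.
    """
    probs = pmf.probs
    mode = int(np.argmax(probs))
    peak = probs[mode]
    tied = bool(np.any(np.abs(np.delete(probs, mode) - peak) <= tol))
    return mode, tied


def total_variation(a: ScorePMF, b: ScorePMF) -> float:
    """Total-variation distance between two score PMFs on the same support."""
    if a.n != b.n:
        raise ValueError("PMFs have different supports")
    return float(0.5 * np.abs(a.probs - b.probs).sum())
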