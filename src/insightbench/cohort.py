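"""Synthetic batteries and simulated cohorts for Monte-Carlo validation.

The analytic machinery assumes a cohort of independent subjects in which
subject ``s`` answers item ``j`` correctly with probability ``p_j``,
independently across items.  This module generates data with exactly that
structure so every analytic quantity (profile probability, score PMF,
conditional ordering) can be cross-checked by simulation without external
data.

Reproducibility: a single root seed drives everything.  ``simulate_study``
derives two independent generators from ``numpy.random.SeedSequence(seed)``
via ``spawn(2)`` — child 0 draws the battery rates, child 1 the cohort
answers — so a reported run is reproducible end to end from one integer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .battery import AnswerProfile, Battery
from .conditional import profile_probability
from .scoredist import ScorePMF

__all__ = [
    "UniformRates",
    "BetaRates",
    "FixedRates",
    "RateModel",
    "SimulationConfig",
    "ResponseMatrix",
    "ProfileValidation",
    "ImpossibleEventError",
    "parse_rate_model",
    "generate_battery",
    "simulate_cohort",
    "simulate_study",
    "empirical_score_pmf",
    "validate_profile_probability",
]


class ImpossibleEventError(RuntimeError):
    """Simulation produced an event whose analytic probability is zero."""


@dataclass(frozen=True)
class UniformRates:
    """Rates drawn i.i.d. from Uniform(lo, hi) within [0, 1]."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ValueError("uniform rate model requires 0 <= lo < hi <= 1")

    def draw(self, rng: np.random.Generator, n_items: int) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=n_items)

    def spec(self) -> str:
        return f"uniform:{self.lo},{self.hi}"


@dataclass(frozen=True)
class BetaRates:
    """Rates drawn i.i.d. from Beta(alpha, beta)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0.0 or self.beta <= 0.0:
            raise ValueError("beta rate model requires alpha, beta > 0")

    def draw(self, rng: np.random.Generator, n_items: int) -> np.ndarray:
        return rng.beta(self.alpha, self.beta, size=n_items)

    def spec(self) -> str:
        return f"beta:{self.alpha},{self.beta}"


@dataclass(frozen=True)
class FixedRates:
    """A fixed, fully specified rate vector (no randomness)."""

    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.rates)
        if not rates or any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("fixed rates must be a non-empty vector in [0, 1]")
        object.__setattr__(self, "rates", rates)

    def draw(self, rng: np.random.Generator, n_items: int) -> np.ndarray:
        if n_items != len(self.rates):
            raise ValueError(
                f"fixed rate model has {len(self.rates)} rates, need {n_items}"
            )
        return np.array(self.rates)

    def spec(self) -> str:
        return "fixed:" + ",".join(repr(r) for r in self.rates)


RateModel = Union[UniformRates, BetaRates, FixedRates]


def parse_rate_model(spec: str) -> RateModel:
    """Parse ``"uniform:lo,hi"``, ``"beta:a,b"`` or ``"fixed:r1,r2,..."``."""
    try:
        name, _, argtext = spec.partition(":")
        args = [float(a) for a in argtext.split(",") if a.strip()]
    except ValueError:
        raise ValueError(f"cannot parse rate model {spec!r}") from None
    if name == "uniform" and len(args) == 2:
        return UniformRates(*args)
    if name == "beta" and len(args) == 2:
        return BetaRates(*args)
    if name == "fixed" and args:
        return FixedRates(tuple(args))
    raise ValueError(
        f"cannot parse rate model {spec!r}; expected 'uniform:lo,hi', "
        "'beta:alpha,beta' or 'fixed:r1,r2,...'"
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_items: int
    n_subjects: int
    rate_model: RateModel
    seed: int

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if isinstance(self.rate_model, str):
            object.__setattr__(self, "rate_model", parse_rate_model(self.rate_model))

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "n_items": self.n_items,
                "n_subjects": self.n_subjects,
                "rate_model": self.rate_model.spec(),
                "seed": self.seed,
            },
            sort_keys=True,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        data = yaml.safe_load(text)
        return cls(
            n_items=int(data["n_items"]),
            n_subjects=int(data["n_subjects"]),
            rate_model=parse_rate_model(data["rate_model"]),
            seed=int(data["seed"]),
        )


@dataclass(frozen=True)
class ResponseMatrix:
    """Simulated 0/1 answers, one row per subject, one column per item."""

    bits: np.ndarray
    battery: Battery

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.int8)
        if bits.ndim != 2:
            raise ValueError("bits must be a 2-D subjects x items array")
        if bits.shape[1] != self.battery.n:
            raise ValueError("column count must equal battery size")
        if np.any((bits != 0) & (bits != 1)):
            raise ValueError("entries must be 0 or 1")
        bits.setflags(write=False)
        object.__setattr__(self, "bits", bits)

    @property
    def n_subjects(self) -> int:
        return self.bits.shape[0]

    @property
    def n_items(self) -> int:
        return self.bits.shape[1]

    def scores(self) -> np.ndarray:
        return self.bits.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(np.asarray(self.bits), columns=self.battery.item_ids)


def _spawned_rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    battery_seq, cohort_seq = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(battery_seq), np.random.default_rng(cohort_seq)


def generate_battery(config: SimulationConfig, set_label: str = "synthetic") -> Battery:
    """Draw a battery from the config's rate model (seed-deterministic)."""
    rng, _ = _spawned_rngs(config.seed)
    rates = config.rate_model.draw(rng, config.n_items)
    return Battery.from_rates(rates, set_label=set_label)


def simulate_cohort(
    battery: Battery,
    n_subjects: int,
    seed: int | np.random.Generator,
) -> ResponseMatrix:
    """Simulate independent Bernoulli answers for a cohort of subjects."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bits = (rng.random((n_subjects, battery.n)) < battery.rates).astype(np.int8)
    return ResponseMatrix(bits=bits, battery=battery)


def simulate_study(config: SimulationConfig) -> tuple[Battery, ResponseMatrix]:
    """Battery plus cohort from one root seed (see module docstring)."""
    battery_rng, cohort_rng = _spawned_rngs(config.seed)
    rates = config.rate_model.draw(battery_rng, config.n_items)
    battery = Battery.from_rates(rates, set_label="synthetic")
    return battery, simulate_cohort(battery, config.n_subjects, cohort_rng)


def empirical_score_pmf(matrix: ResponseMatrix) -> ScorePMF:
    """Normalized histogram of per-subject total scores."""
    counts = np.bincount(matrix.scores(), minlength=matrix.n_items + 1)
    return ScorePMF(counts / matrix.n_subjects)


def _discrepancy_z(empirical: float, analytic: float, n_subjects: int) -> float:
    if analytic == 0.0:
        if empirical > 0.0:
            raise ImpossibleEventError(
                f"observed frequency {empirical} for an event with analytic "
                "probability 0"
            )
        return 0.0
    if analytic == 1.0:
        return 0.0 if empirical == 1.0 else -np.inf
    se = np.sqrt(analytic * (1.0 - analytic) / n_subjects)
    return float((empirical - analytic) / se)


@dataclass(frozen=True)
class ProfileValidation:
    empirical: float
    analytic: float
    z_discrepancy: float
    n_subjects: int


def validate_profile_probability(
    battery: Battery,
    profile: AnswerProfile | Sequence[int],
    n_subjects: int,
    seed: int,
) -> ProfileValidation:
    """Monte-Carlo check of the analytic combination occurrence probability.

    Simulates a cohort, measures the fraction of subjects whose full answer
    vector equals the profile and standardizes the gap to the analytic
    probability by its binomial standard error.
    """
    profile = profile if isinstance(profile, AnswerProfile) else AnswerProfile(
        tuple(profile)
    )
    profile.check_against(battery)
    analytic = profile_probability(battery, profile)
    matrix = simulate_cohort(battery, n_subjects, seed)
    hits = np.all(matrix.bits == profile.as_array(), axis=1)
    empirical = float(hits.mean())
    z = _discrepancy_z(empirical, analytic, n_subjects)
    return ProfileValidation(
        empirical=empirical, analytic=analytic, z_discrepancy=z, n_subjects=n_subjects
    )
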