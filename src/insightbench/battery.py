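"""Item batteries and binary answer profiles.

A :class:`Battery` is an ordered collection of items, each carrying a human
solution rate in ``[0, 1]`` (the fraction of a normative reference sample that
answered the item correctly) and a set label.  An :class:`AnswerProfile` is an
ordered 0/1 vector of one respondent's answers over the same items.

The package ships a built-in battery of 30 verbal insight items split into a
*practice* and a *transfer* set of 15 items each, together with the answer
profile of the benchmarked agent, so that the full reference analysis runs
without any external data.  Rates are stored as proportions at their printed
precision; tabular I/O accepts percent strings (``"50%"``) on input and always
writes decimal proportions.
"""

from __future__ import annotations

import decimal
import hashlib
import os
from dataclasses import dataclass
from typing import IO, Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Battery",
    "AnswerProfile",
    "Item",
    "BatteryError",
    "BatteryValidationError",
    "UnknownSetError",
    "builtin_battery",
    "builtin_profile",
    "read_battery",
    "write_battery",
    "read_profile",
    "battery_checksum",
    "PRACTICE",
    "TRANSFER",
    "POOLED",
    "BUILTIN_SETS",
]

PRACTICE = "practice"
TRANSFER = "transfer"
POOLED = "pooled"
BUILTIN_SETS = (PRACTICE, TRANSFER, POOLED)

Source = Union[str, os.PathLike, IO[str]]


class BatteryError(ValueError):
    """Malformed battery or profile data."""


class BatteryValidationError(BatteryError):
    """A row or field violates a battery invariant."""


class UnknownSetError(BatteryError, KeyError):
    """Requested built-in set label does not exist."""

    def __init__(self, which: str):
        super().__init__(
            f"unknown set label {which!r}; valid labels are "
            f"{', '.join(repr(s) for s in BUILTIN_SETS)}"
        )


# Normative per-item solution rates of the reference human sample, as printed
# (percentages / 100, at printed precision), plus the benchmarked agent's
# 0/1 answers.  Item order is significant throughout.
_PRACTICE_RATES = (
    0.50, 0.211, 0.75, 0.20, 0.65, 0.65, 0.19, 0.55,
    0.65, 0.10, 0.556, 0.579, 0.286, 0.50, 0.60,
)
_TRANSFER_RATES = (
    0.40, 0.45, 0.364, 0.40, 0.30, 0.30, 0.421, 0.35,
    0.30, 0.318, 0.35, 0.368, 0.30, 0.40, 0.318,
)
_PRACTICE_ANSWERS = (0, 0, 1, 0, 0, 1, 0, 1, 0, 0, 1, 0, 1, 1, 1)
_TRANSFER_ANSWERS = (1, 0, 0, 0, 0, 1, 0, 1, 0, 0, 0, 1, 1, 0, 0)


@dataclass(frozen=True)
class Item:
    """One battery item: identifier, set label and human solution rate."""

    item_id: str
    set_label: str
    solution_rate: float


@dataclass(frozen=True, eq=True)
class Battery:
    """Ordered battery of items with per-item solution rates.

    Invariants (enforced at construction): every rate lies in ``[0, 1]``,
    item identifiers are unique, and item order is preserved.
    """

    items: tuple[Item, ...]

    def __post_init__(self) -> None:
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if not items:
            raise BatteryValidationError("battery must contain at least one item")
        seen: set[str] = set()
        for i, item in enumerate(items):
            if not (0.0 <= item.solution_rate <= 1.0):
                raise BatteryValidationError(
                    f"item {item.item_id!r} (row {i + 1}): solution_rate "
                    f"{item.solution_rate!r} outside [0, 1]"
                )
            if item.item_id in seen:
                raise BatteryValidationError(
                    f"duplicate item_id {item.item_id!r} (row {i + 1})"
                )
            seen.add(item.item_id)

    @property
    def n(self) -> int:
        return len(self.items)

    @property
    def rates(self) -> np.ndarray:
        """Solution rates as a float vector, in item order."""
        return np.array([it.solution_rate for it in self.items], dtype=float)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def set_labels(self) -> tuple[str, ...]:
        """Distinct set labels in order of first appearance."""
        out: list[str] = []
        for it in self.items:
            if it.set_label not in out:
                out.append(it.set_label)
        return tuple(out)

    def subset(self, set_label: str) -> "Battery":
        """Sub-battery of the items carrying ``set_label`` (order kept)."""
        items = tuple(it for it in self.items if it.set_label == set_label)
        if not items:
            raise BatteryError(
                f"no items with set_label {set_label!r}; present labels: "
                f"{', '.join(self.set_labels)}"
            )
        return Battery(items)

    def __add__(self, other: "Battery") -> "Battery":
        return Battery(self.items + other.items)

    @classmethod
    def from_rates(
        cls,
        rates: Sequence[float],
        set_label: str = "default",
        item_ids: Sequence[str] | None = None,
    ) -> "Battery":
        """Build a battery from bare rates, synthesizing item identifiers."""
        rates = list(rates)
        if item_ids is None:
            width = max(2, len(str(len(rates))))
            item_ids = [f"I{j + 1:0{width}d}" for j in range(len(rates))]
        if len(item_ids) != len(rates):
            raise BatteryValidationError("item_ids and rates differ in length")
        return cls(
            tuple(
                Item(str(i), set_label, float(r)) for i, r in zip(item_ids, rates)
            )
        )


@dataclass(frozen=True, eq=True)
class AnswerProfile:
    """A single respondent's 0/1 answers over a battery, in item order."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if any(b not in (0, 1) for b in bits):
            raise BatteryValidationError("profile bits must be 0 or 1")
        if not bits:
            raise BatteryValidationError("profile must contain at least one bit")
        object.__setattr__(self, "bits", bits)

    @property
    def n(self) -> int:
        return len(self.bits)

    @property
    def score(self) -> int:
        """Total score: the number of correct (1) answers."""
        return sum(self.bits)

    def as_array(self) -> np.ndarray:
        return np.array(self.bits, dtype=np.int8)

    def subset(self, battery: Battery, set_label: str) -> "AnswerProfile":
        """Bits of the items of ``battery`` carrying ``set_label``."""
        self.check_against(battery)
        bits = tuple(
            b for b, it in zip(self.bits, battery.items) if it.set_label == set_label
        )
        if not bits:
            raise BatteryError(f"no items with set_label {set_label!r}")
        return AnswerProfile(bits)

    def check_against(self, battery: Battery) -> None:
        if self.n != battery.n:
            raise BatteryValidationError(
                f"profile length {self.n} does not match battery size {battery.n}"
            )

    def __add__(self, other: "AnswerProfile") -> "AnswerProfile":
        return AnswerProfile(self.bits + other.bits)


def _builtin_items(which: str) -> tuple[Item, ...]:
    if which == PRACTICE:
        return tuple(
            Item(f"P{j + 1:02d}", PRACTICE, r) for j, r in enumerate(_PRACTICE_RATES)
        )
    if which == TRANSFER:
        return tuple(
            Item(f"T{j + 1:02d}", TRANSFER, r) for j, r in enumerate(_TRANSFER_RATES)
        )
    if which == POOLED:
        return _builtin_items(PRACTICE) + _builtin_items(TRANSFER)
    raise UnknownSetError(which)


def builtin_battery(which: str = POOLED) -> Battery:
    """Return a built-in battery: ``practice``, ``transfer`` or ``pooled``.

    The pooled battery is the 15 practice items followed by the 15 transfer
    items, in printed order.
    """
    return Battery(_builtin_items(which))


def builtin_profile(which: str = POOLED) -> AnswerProfile:
    """Return the benchmarked agent's built-in answer profile for a set."""
    if which == PRACTICE:
        return AnswerProfile(_PRACTICE_ANSWERS)
    if which == TRANSFER:
        return AnswerProfile(_TRANSFER_ANSWERS)
    if which == POOLED:
        return AnswerProfile(_PRACTICE_ANSWERS + _TRANSFER_ANSWERS)
    raise UnknownSetError(which)


def _parse_rate(raw: object, row: int, item_id: str) -> float:
    """Parse a solution rate: decimal proportion or percent string."""
    text = str(raw).strip()
    try:
        if text.endswith("%"):
            # decimal division so "21.1%" hits the same double as 0.211
            value = float(decimal.Decimal(text[:-1].strip()) / 100)
        else:
            value = float(text)
    except (ValueError, decimal.InvalidOperation):
        raise BatteryValidationError(
            f"item {item_id!r} (row {row}): cannot parse solution_rate {raw!r}"
        ) from None
    if not (0.0 <= value <= 1.0):
        raise BatteryValidationError(
            f"item {item_id!r} (row {row}): solution_rate {value!r} outside [0, 1]"
        )
    return value


_REQUIRED_COLUMNS = ("item_id", "set_label", "solution_rate")


def _read_frame(source: Source) -> pd.DataFrame:
    frame = pd.read_csv(source, dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise BatteryError(
            f"missing required column(s): {', '.join(missing)}; "
            f"expected header item_id,set_label,solution_rate[,answer]"
        )
    return frame


def read_battery(source: Source) -> Battery:
    """Read a battery from CSV (path, file object or CSV text buffer).

    Required columns: ``item_id``, ``set_label``, ``solution_rate``.  Rates may
    be decimal proportions (``0.5``) or percent strings (``"50%"``).  An
    optional ``answer`` column (see :func:`read_profile`) is ignored here.
    """
    frame = _read_frame(source)
    items = []
    for row, rec in enumerate(frame.itertuples(index=False), start=1):
        item_id = str(getattr(rec, "item_id"))
        rate = _parse_rate(getattr(rec, "solution_rate"), row, item_id)
        items.append(Item(item_id, str(getattr(rec, "set_label")), rate))
    return Battery(tuple(items))


def write_battery(
    battery: Battery,
    dest: Source | None = None,
    profile: AnswerProfile | None = None,
) -> str:
    """Write a battery (optionally with a profile's answers) as CSV.

    Returns the CSV text; if ``dest`` is given the text is also written there.
    Rates are written as decimal proportions with full round-trip precision, so
    ``read_battery(write_battery(b)) == b``.
    """
    data = {
        "item_id": [it.item_id for it in battery.items],
        "set_label": [it.set_label for it in battery.items],
        "solution_rate": [repr(it.solution_rate) for it in battery.items],
    }
    if profile is not None:
        profile.check_against(battery)
        data["answer"] = list(profile.bits)
    text = pd.DataFrame(data).to_csv(index=False)
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)  # type: ignore[union-attr]
        else:
            with open(dest, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text


def read_profile(source: Source, battery: Battery | None = None) -> AnswerProfile:
    """Read an answer profile from CSV.

    The file must contain an ``answer`` column of 0/1 values, one row per item
    in battery order (a battery CSV with an extra ``answer`` column works).
    If ``battery`` is given the profile length is checked against it.
    """
    frame = pd.read_csv(source)
    if "answer" not in frame.columns:
        raise BatteryError("missing required column 'answer'")
    raw = frame["answer"].tolist()
    bits = []
    for row, value in enumerate(raw, start=1):
        try:
            bit = int(value)
        except (TypeError, ValueError):
            raise BatteryValidationError(
                f"row {row}: answer {value!r} is not 0 or 1"
            ) from None
        if bit not in (0, 1):
            raise BatteryValidationError(f"row {row}: answer {value!r} is not 0 or 1")
        bits.append(bit)
    profile = AnswerProfile(tuple(bits))
    if battery is not None:
        profile.check_against(battery)
    return profile


def battery_checksum(battery: Battery) -> str:
    """SHA-256 of the canonical CSV serialization (provenance fingerprint)."""
    return hashlib.sha256(write_battery(battery).encode("utf-8")).hexdigest()
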