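"""One-call reproduction of the full benchmark analysis, plus figure data.

:func:`run_full_analysis` runs, for every problem set in a battery (and for
the pooled battery when it holds more than one set): the exact score PMF and
its mode, the profile's occurrence probability and conditional placement, and
the per-set rate summaries; plus the between-set Fisher exact and rank-sum
comparisons.  Results come back as an :class:`AnalysisReport` that serializes
to a schema-tagged JSON document in which every probability is carried at full
precision alongside a 3-significant-figure display string.

:func:`export_figure_data` emits the plot-ready tables behind the three
standard views: score PMFs, the combination x item matrix of a score level
set, and the sorted (down-sampled) conditional probability curve with
percentile markers.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__
from .battery import (
    AnswerProfile,
    Battery,
    battery_checksum,
    builtin_battery,
    builtin_profile,
)
from .classical import QuantileSummary, RankSumResult, fisher_exact, median_iqr, ranksum
from .conditional import (
    DEFAULT_CHUNK_SIZE,
    DEFAULT_DIRECT_CAP,
    MitmConditionalDistribution,
    PlacementReport,
    build_conditional,
    placement,
)
from .scoredist import ScorePMF, pmf_mode, score_pmf_dp

__all__ = [
    "SetAnalysis",
    "Comparisons",
    "AnalysisReport",
    "FigureExportError",
    "run_full_analysis",
    "export_figure_data",
    "round_sig",
]

logger = logging.getLogger(__name__)

REPORT_SCHEMA = "insightbench-report/1"

CONVENTIONS = {
    "percentile_rank": "100 * (strictly smaller) / m, relative tie tolerance 1e-9",
    "top_q_threshold": "nearest-rank upper quantile at ascending rank ceil((1-q)*m)",
    "in_top_q": "non-strict (probability >= threshold)",
    "quantiles": "midpoint interpolation, position h = q*n + 0.5",
    "ranksum": "midranks, tie-corrected variance, no continuity correction",
    "fisher": "two-sided probability-mass rule",
}


class FigureExportError(ValueError):
    """Requested figure data cannot be produced for this set."""


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def _fmt_sig(x: float, digits: int = 3) -> str:
    return f"{x:.{digits - 1}e}"


@dataclass
class SetAnalysis:
    """All per-set quantities, with the inputs retained for figure export."""

    label: str
    battery: Battery
    profile: AnswerProfile
    pmf: ScorePMF
    mode: int
    mode_tied: bool
    placement: PlacementReport
    rate_summary: QuantileSummary

    @property
    def chatgpt_score(self) -> int:
        return self.profile.score

    @property
    def mode_equals_profile_score(self) -> bool:
        return self.mode == self.profile.score

    def to_dict(self) -> dict:
        pl = self.placement
        return {
            "n_items": self.battery.n,
            "chatgpt_score": self.chatgpt_score,
            "score_pmf": [float(p) for p in self.pmf.probs],
            "mode": self.mode,
            "mode_tied": self.mode_tied,
            "mode_equals_chatgpt": self.mode_equals_profile_score,
            "profile_probability": pl.profile_probability,
            "profile_probability_3sf": _fmt_sig(pl.profile_probability),
            "percentile_rank": pl.percentile_rank,
            "top_q_threshold": pl.top_q_threshold,
            "top_q_threshold_3sf": _fmt_sig(pl.top_q_threshold),
            "in_top_q": pl.in_top_q,
            "combination_count": pl.m,
            "placement_method": pl.method,
            "median_solution_rate": self.rate_summary.median,
            "iqr_solution_rate": [self.rate_summary.q1, self.rate_summary.q3],
        }


@dataclass
class Comparisons:
    labels: tuple[str, str]
    fisher_table: tuple[tuple[int, int], tuple[int, int]]
    fisher_p: float
    ranksum_result: RankSumResult

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "fisher_table": [list(r) for r in self.fisher_table],
            "fisher_p": self.fisher_p,
            "ranksum_z": self.ranksum_result.z,
            "ranksum_p": self.ranksum_result.p,
        }


@dataclass
class AnalysisReport:
    sets: dict[str, SetAnalysis]
    comparisons: Comparisons | None
    q: float
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema": REPORT_SCHEMA,
            "q": self.q,
            "conventions": dict(CONVENTIONS),
            "provenance": dict(self.provenance),
            "sets": {label: block.to_dict() for label, block in self.sets.items()},
            "comparisons": (
                self.comparisons.to_dict() if self.comparisons is not None else None
            ),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def _resolve_inputs(battery_source, profile_source) -> tuple[Battery, AnswerProfile]:
    from .battery import read_battery, read_profile

    if battery_source is None:
        battery = builtin_battery("pooled")
    elif isinstance(battery_source, Battery):
        battery = battery_source
    else:
        battery = read_battery(battery_source)

    if profile_source is None:
        if battery_source is None:
            profile = builtin_profile("pooled")
        else:
            # battery file may carry its own answer column
            profile = read_profile(battery_source, battery)
    elif isinstance(profile_source, AnswerProfile):
        profile = profile_source
    else:
        profile = read_profile(profile_source, battery)
    return battery, profile


def _analyze_set(
    label: str,
    battery: Battery,
    profile: AnswerProfile,
    q: float,
    direct_cap: int,
    chunk_size: int,
) -> SetAnalysis:
    logger.info("analyzing set %r (n=%d, score=%d)", label, battery.n, profile.score)
    pmf = score_pmf_dp(battery)
    mode, tied = pmf_mode(pmf)
    pl = placement(battery, profile, q=q, direct_cap=direct_cap, chunk_size=chunk_size)
    return SetAnalysis(
        label=label,
        battery=battery,
        profile=profile,
        pmf=pmf,
        mode=mode,
        mode_tied=tied,
        placement=pl,
        rate_summary=median_iqr(battery.rates),
    )


def run_full_analysis(
    battery_source=None,
    profile_source=None,
    q: float = 0.05,
    direct_cap: int = DEFAULT_DIRECT_CAP,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> AnalysisReport:
    """Run the complete analysis on a battery/profile pair.

    With no sources, the built-in 30-item battery and profile are used,
    producing the three standard blocks (practice, transfer, pooled) plus the
    between-set comparisons.  Sources may be paths to CSV files or in-memory
    objects.  Deterministic given its inputs.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    battery, profile = _resolve_inputs(battery_source, profile_source)
    profile.check_against(battery)

    labels = battery.set_labels
    blocks: dict[str, SetAnalysis] = {}
    for label in labels:
        sub_battery = battery.subset(label)
        sub_profile = profile.subset(battery, label)
        blocks[label] = _analyze_set(
            label, sub_battery, sub_profile, q, direct_cap, chunk_size
        )
    if len(labels) > 1:
        blocks["pooled"] = _analyze_set(
            "pooled", battery, profile, q, direct_cap, chunk_size
        )

    comparisons = None
    if len(labels) == 2:
        b1, b2 = blocks[labels[0]], blocks[labels[1]]
        s1, s2 = b1.chatgpt_score, b2.chatgpt_score
        table = ((s1, b1.battery.n - s1), (s2, b2.battery.n - s2))
        comparisons = Comparisons(
            labels=(labels[0], labels[1]),
            fisher_table=table,
            fisher_p=fisher_exact(table),
            ranksum_result=ranksum(b1.battery.rates, b2.battery.rates),
        )

    provenance = {
        "package_version": __version__,
        "battery_sha256": battery_checksum(battery),
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "direct_cap": direct_cap,
    }
    return AnalysisReport(sets=blocks, comparisons=comparisons, q=q, provenance=provenance)


# ---------------------------------------------------------------------------
# figure data


def _fig3(report: AnalysisReport) -> dict[str, pd.DataFrame]:
    frames = []
    for label, block in report.sets.items():
        frame = block.pmf.to_frame()
        frame.insert(0, "set", label)
        frames.append(frame)
    return {"fig3": pd.concat(frames, ignore_index=True)}


def _fig4_matrix(block: SetAnalysis, cap: int) -> pd.DataFrame:
    from itertools import combinations

    n, k, m = block.battery.n, block.chatgpt_score, block.placement.m
    if m > cap:
        raise FigureExportError(
            f"set {block.label!r} has {m} score-{k} combinations, above the "
            f"direct-enumeration cap ({cap}); the matrix is not exportable"
        )
    rows = np.zeros((m, n), dtype=np.int8)
    for i, idx in enumerate(combinations(range(n), k)):
        rows[i, list(idx)] = 1
    return pd.DataFrame(rows, columns=block.battery.item_ids)


def _fig5_curve(
    block: SetAnalysis, max_points: int, chunk_size: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    dist = build_conditional(
        block.battery.rates, block.chatgpt_score, chunk_size=chunk_size
    )
    m = dist.m
    stride = max(1, math.ceil(m / max_points))
    ranks = np.arange(1, m + 1, stride)
    if isinstance(dist, MitmConditionalDistribution):
        values, method = _binned_quantiles(dist, ranks), "binned"
    else:
        ascending = np.sort(dist.probabilities)
        values, method = ascending[ranks - 1], "exact"
    curve = pd.DataFrame({"rank": ranks, "probability": values})
    curve["stride"] = stride
    curve["method"] = method

    markers = []
    for pct in (5, 50, 95):
        rank = max(1, math.ceil(pct / 100.0 * m))
        markers.append(("p%d" % pct, rank, dist.nth_smallest(rank)))
    pl = block.placement
    profile_rank = dist.count_less(pl.profile_probability) + 1
    markers.append(("profile", profile_rank, pl.profile_probability))
    marker_frame = pd.DataFrame(markers, columns=["kind", "rank", "probability"])
    return curve, marker_frame


def _binned_quantiles(
    dist: MitmConditionalDistribution, ranks: np.ndarray, n_bins: int = 2048
) -> np.ndarray:
    """Approximate order statistics from a fine log-spaced histogram."""
    lo = max(dist.min(), 1e-300)
    hi = dist.max()
    if lo >= hi:
        return np.full(ranks.size, hi)
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    counts = dist.histogram(edges)
    cumulative = np.cumsum(counts)
    # value assigned to a rank: geometric midpoint of the bin containing it
    mids = np.concatenate([[lo], np.sqrt(edges[:-1] * edges[1:]), [hi]])
    idx = np.searchsorted(cumulative, ranks, side="left")
    return mids[np.clip(idx, 0, mids.size - 1)]


def export_figure_data(
    report: AnalysisReport,
    which: str,
    sets: list[str] | None = None,
    direct_cap: int = DEFAULT_DIRECT_CAP,
    max_points: int = 2000,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> dict[str, pd.DataFrame]:
    """Plot-ready tables for ``which`` in ``{"fig3", "fig4", "fig5"}``.

    fig3: (set, score, probability) rows for every set.  fig4: the
    combination x item 0/1 matrix of the profile's score level set, one table
    per requested set (refused above ``direct_cap`` combinations).  fig5: per
    set, the ascending (down-sampled, stride recorded) conditional probability
    curve plus marker rows for the 5th/50th/95th percentiles and the
    profile's own probability.
    """
    if which == "fig3":
        return _fig3(report)
    chosen = sets
    if chosen is None:
        chosen = list(report.sets)
        if which == "fig4":
            # mirror the source analysis: sets above the cap are omitted
            # unless explicitly requested (which then raises)
            chosen = [l for l in chosen if report.sets[l].placement.m <= direct_cap]
    out: dict[str, pd.DataFrame] = {}
    for label in chosen:
        if label not in report.sets:
            raise FigureExportError(f"unknown set {label!r}")
        block = report.sets[label]
        if which == "fig4":
            out[f"fig4_{label}"] = _fig4_matrix(block, direct_cap)
        elif which == "fig5":
            curve, markers = _fig5_curve(block, max_points, chunk_size)
            out[f"fig5_{label}"] = curve
            out[f"fig5_{label}_markers"] = markers
        else:
            raise ValueError(f"unknown figure {which!r}; expected fig3, fig4 or fig5")
    return out
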