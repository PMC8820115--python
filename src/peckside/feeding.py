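"""Feeding accuracy and efficiency analyses.

Covers: active feeding time with freeze exclusion, ingestion rate
(items consumed per minute of active feeding), accuracy comparison of
per-bird success proportions between lateralized and non-lateralized
birds, the balanced six-error eye-conditional design (Wilcoxon
matched-pairs on errors after preferred- vs non-preferred-eye
inspections), and Mann-Whitney efficiency/latency comparisons.

The balanced-error design equalises the number of errors per bird: only
lateralized birds contributing at least the cap (default 6) of pecking
errors are kept, and only their first cap errors in observation order
are used.  Errors not preceded by a monocular inspection are excluded
from the eye-conditional tallies.  Note that with a fixed cap the
paired comparison of counts is rank-equivalent to comparing proportions
of the cap.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .laterality import Classification, LateralityResult
from .stats_core import (
    DegenerateInputError,
    InvalidInputError,
    TestResult,
    mann_whitney_u,
    wilcoxon_signed_rank,
)

__all__ = [
    "TimelineEventType",
    "ErrorBreakdown",
    "EfficiencyRecord",
    "active_feeding_time",
    "ingestion_rate",
    "accuracy_comparison",
    "balanced_error_analysis",
    "efficiency_comparison",
    "DEFAULT_FREEZE_THRESHOLD_S",
    "DEFAULT_ERROR_CAP",
]

DEFAULT_FREEZE_THRESHOLD_S = 5.0
DEFAULT_ERROR_CAP = 6


class TimelineEventType(str, Enum):
    LAND = "land"
    PECK = "peck"
    FREEZE_START = "freeze_start"
    FREEZE_END = "freeze_end"
    DEPART = "depart"


@dataclass(frozen=True)
class ErrorBreakdown:
    bird_id: str
    preference: Classification  # LEFT or RIGHT
    errors_used: int
    errors_after_preferred_eye: int
    errors_after_nonpreferred_eye: int

    def to_record(self) -> dict:
        return {
            "bird_id": self.bird_id,
            "preference": self.preference.value,
            "errors_used": self.errors_used,
            "errors_after_preferred_eye": self.errors_after_preferred_eye,
            "errors_after_nonpreferred_eye": self.errors_after_nonpreferred_eye,
        }


@dataclass(frozen=True)
class EfficiencyRecord:
    bird_id: str
    ingestion_rate: float
    latency_s: float
    lateralized: bool
    direction: Classification | None = None  # LEFT/RIGHT when lateralized

    def __post_init__(self) -> None:
        if self.ingestion_rate < 0 or self.latency_s < 0:
            raise InvalidInputError("rates and latencies must be non-negative")


def active_feeding_time(
    timeline: Sequence[tuple[float, TimelineEventType | str]],
    freeze_threshold_s: float = DEFAULT_FREEZE_THRESHOLD_S,
) -> float:
    """Visit duration minus freezes longer than the threshold.

    ``timeline`` is an ordered list of ``(timestamp_s, event_type)``
    covering one feeding visit from landing to departure.  Freezes are
    delimited by ``freeze_start`` / ``freeze_end`` pairs; only pauses
    *strictly longer* than ``freeze_threshold_s`` are excluded from the
    total, since shorter pauses are part of normal food searching.
    """
    if not timeline:
        raise InvalidInputError("empty timeline")
    times = [t for t, _ in timeline]
    if any(b < a for a, b in zip(times, times[1:])):
        raise InvalidInputError("timeline timestamps must be non-decreasing")
    events = [(t, TimelineEventType(e)) for t, e in timeline]
    if events[0][1] is not TimelineEventType.LAND:
        raise InvalidInputError("timeline must start with a landing event")
    if events[-1][1] is not TimelineEventType.DEPART:
        raise InvalidInputError("timeline must end with a departure event")
    total = events[-1][0] - events[0][0]
    frozen = 0.0
    freeze_start: float | None = None
    for t, e in events:
        if e is TimelineEventType.FREEZE_START:
            if freeze_start is not None:
                raise InvalidInputError("nested freeze_start")
            freeze_start = t
        elif e is TimelineEventType.FREEZE_END:
            if freeze_start is None:
                raise InvalidInputError("freeze_end without freeze_start")
            dur = t - freeze_start
            if dur > freeze_threshold_s:
                frozen += dur
            freeze_start = None
    if freeze_start is not None:
        raise InvalidInputError("unterminated freeze interval")
    return total - frozen


def ingestion_rate(n_success: int, active_time_s: float) -> float:
    """Food items consumed per minute of active feeding time."""
    if active_time_s <= 0:
        raise InvalidInputError("active_time_s must be positive")
    if n_success < 0:
        raise InvalidInputError("n_success must be non-negative")
    return 60.0 * n_success / active_time_s


def accuracy_comparison(
    success_props_lateralized: Sequence[float],
    success_props_nonlateralized: Sequence[float],
) -> TestResult:
    """Mann-Whitney comparison of per-bird success proportions between
    lateralized and non-lateralized birds."""
    for v in list(success_props_lateralized) + list(success_props_nonlateralized):
        if not 0.0 <= v <= 1.0:
            raise InvalidInputError(f"success proportion out of [0,1]: {v}")
    return mann_whitney_u(
        list(success_props_lateralized), list(success_props_nonlateralized)
    )


def _first_cap_split(
    preference: Classification,
    error_eyes: Sequence[str],
    cap: int,
) -> tuple[int, int, int]:
    """Tally the first ``cap`` errors into (used, after-preferred,
    after-nonpreferred); non-monocular errors count toward the cap but
    enter neither eye tally."""
    first = list(error_eyes)[:cap]
    pref_eye = "L" if preference is Classification.LEFT else "R"
    nonpref_eye = "R" if preference is Classification.LEFT else "L"
    n_pref = sum(1 for e in first if e == pref_eye)
    n_nonpref = sum(1 for e in first if e == nonpref_eye)
    return len(first), n_pref, n_nonpref


def balanced_error_analysis(
    birds: Iterable[tuple[LateralityResult, Sequence[str]]],
    n_errors_cap: int = DEFAULT_ERROR_CAP,
) -> tuple[dict[str, TestResult | None], list[ErrorBreakdown]]:
    """Eye-conditional error analysis on a balanced subsample.

    ``birds`` pairs each lateralized bird's classification with the
    chronologically ordered eyes ('L', 'R' or 'NONE') of its pecking
    errors.  Birds that are not LEFT/RIGHT or made fewer than
    ``n_errors_cap`` errors are dropped; for the rest only the first
    ``n_errors_cap`` errors are used.  Within each preference-direction
    group a Wilcoxon matched-pairs signed-rank test compares per-bird
    errors after the non-preferred eye against errors after the
    preferred eye (positive W: more errors after the non-preferred
    eye).  A group with no qualifying birds, or with all differences
    zero, yields ``None`` for that direction.
    """
    if n_errors_cap < 1:
        raise InvalidInputError("n_errors_cap must be >= 1")
    breakdowns: list[ErrorBreakdown] = []
    diffs: dict[Classification, list[int]] = {
        Classification.LEFT: [],
        Classification.RIGHT: [],
    }
    for result, error_eyes in birds:
        if result.classification not in (Classification.LEFT, Classification.RIGHT):
            continue
        if len(error_eyes) < n_errors_cap:
            continue  # balanced design: birds with fewer errors excluded
        used, n_pref, n_nonpref = _first_cap_split(
            result.classification, error_eyes, n_errors_cap
        )
        breakdowns.append(
            ErrorBreakdown(result.bird_id, result.classification, used,
                           n_pref, n_nonpref)
        )
        diffs[result.classification].append(n_nonpref - n_pref)
    tests: dict[str, TestResult | None] = {}
    for direction, d in diffs.items():
        key = direction.value
        if not d:
            tests[key] = None
            continue
        try:
            tests[key] = wilcoxon_signed_rank(d, 0.0)
        except DegenerateInputError:
            tests[key] = None
    return tests, breakdowns


def efficiency_comparison(
    records: Sequence[EfficiencyRecord],
    grouping: str = "lat_vs_nonlat",
    metric: str = "ingestion_rate",
) -> TestResult:
    """Mann-Whitney comparison of ingestion rate (or latency) between
    lateralized vs non-lateralized birds, or left- vs right-preferent
    birds."""
    if metric not in ("ingestion_rate", "latency_s"):
        raise InvalidInputError(f"unknown metric: {metric}")
    if grouping == "lat_vs_nonlat":
        a = [getattr(r, metric) for r in records if r.lateralized]
        b = [getattr(r, metric) for r in records if not r.lateralized]
    elif grouping == "left_vs_right":
        a = [
            getattr(r, metric)
            for r in records
            if r.direction is Classification.LEFT
        ]
        b = [
            getattr(r, metric)
            for r in records
            if r.direction is Classification.RIGHT
        ]
    else:
        raise InvalidInputError(f"unknown grouping: {grouping}")
    return mann_whitney_u(a, b)
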