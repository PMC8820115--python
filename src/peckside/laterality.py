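"""Per-individual eye-preference classification and population-level
lateralization inference.

A bird observed feeding is summarised by its counts of left-eye and
right-eye monocular inspections.  The laterality index
LI = (L - R) / (L + R) ranges over [-1, 1], positive values indicating a
left-eye bias.  Birds with enough monocular inspections are classified
LEFT / RIGHT / NONE by a two-tailed binomial test of the eye counts
against a fair-coin null; the rest are EXCLUDED.  Population-level
inference then asks (a) whether significantly more birds than expected
are lateralized at all, (b) whether the lateralized birds share a
direction, and (c) whether the LI distribution is shifted away from 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .stats_core import (
    InvalidInputError,
    TestResult,
    binomial_exact,
    binomial_z,
    wilcoxon_signed_rank,
)

__all__ = [
    "FoodType",
    "Classification",
    "BirdSummary",
    "LateralityResult",
    "PopulationReport",
    "laterality_index",
    "classify_individual",
    "population_analysis",
    "strength_comparison",
    "median_with_ci",
]

DEFAULT_MIN_INSPECTIONS = 15


class FoodType(str, Enum):
    MAHUA_FLOWER = "mahua_flower"
    FIG_FRUIT = "fig_fruit"


class Classification(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    NONE = "NONE"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class BirdSummary:
    """Per-individual aggregation of one feeding visit."""

    bird_id: str
    food_type: FoodType
    site_id: str
    tree_id: str
    flock_id: str
    n_left: int
    n_right: int
    n_nonlateral: int
    n_pecks: int
    n_success: int
    active_time_s: float
    latency_s: float
    interrupted: bool = False

    def __post_init__(self) -> None:
        counts = (self.n_left, self.n_right, self.n_nonlateral, self.n_pecks,
                  self.n_success)
        if any(c < 0 for c in counts):
            raise InvalidInputError("counts must be non-negative")
        if self.n_left + self.n_right + self.n_nonlateral != self.n_pecks:
            raise InvalidInputError("n_left + n_right + n_nonlateral != n_pecks")
        if self.n_success > self.n_pecks:
            raise InvalidInputError("n_success > n_pecks")
        if self.n_pecks > 0 and self.active_time_s <= 0:
            raise InvalidInputError("active_time_s must be positive when pecks occur")

    @property
    def n_monocular(self) -> int:
        return self.n_left + self.n_right


@dataclass(frozen=True)
class LateralityResult:
    bird_id: str
    classification: Classification
    li: float | None
    abs_li: float | None
    test: TestResult | None
    exclusion_reason: str | None = None

    def to_record(self) -> dict:
        return {
            "bird_id": self.bird_id,
            "classification": self.classification.value,
            "li": self.li,
            "abs_li": self.abs_li,
            "test": self.test.to_record() if self.test else None,
            "exclusion_reason": self.exclusion_reason,
        }


@dataclass(frozen=True)
class PopulationReport:
    food_type: FoodType | None
    n_analyzable: int
    n_left_pref: int
    n_right_pref: int
    n_none: int
    lateralized_vs_total: TestResult
    direction_among_lateralized: TestResult | None
    majority_direction: Classification | None
    li_location: TestResult
    median_inspections: float | None = None
    median_inspections_ci: tuple[float, float] | None = None

    def to_record(self) -> dict:
        return {
            "food_type": self.food_type.value if self.food_type else None,
            "n_analyzable": self.n_analyzable,
            "n_left_pref": self.n_left_pref,
            "n_right_pref": self.n_right_pref,
            "n_none": self.n_none,
            "lateralized_vs_total": self.lateralized_vs_total.to_record(),
            "direction_among_lateralized": (
                self.direction_among_lateralized.to_record()
                if self.direction_among_lateralized
                else None
            ),
            "majority_direction": (
                self.majority_direction.value if self.majority_direction else None
            ),
            "li_location": self.li_location.to_record(),
            "median_inspections": self.median_inspections,
            "median_inspections_ci": (
                list(self.median_inspections_ci)
                if self.median_inspections_ci
                else None
            ),
        }


def laterality_index(n_left: int, n_right: int) -> float:
    """LI = (L - R) / (L + R); +1 fully left, -1 fully right."""
    if n_left < 0 or n_right < 0:
        raise InvalidInputError("counts must be non-negative")
    total = n_left + n_right
    if total == 0:
        raise InvalidInputError("laterality index undefined for L + R = 0")
    return (n_left - n_right) / total


def classify_individual(
    summary: BirdSummary,
    alpha: float = 0.05,
    min_inspections: int = DEFAULT_MIN_INSPECTIONS,
    method: Literal["exact", "z"] = "exact",
) -> LateralityResult:
    """Classify one bird as LEFT / RIGHT / NONE / EXCLUDED.

    Birds whose feeding was interrupted by social interaction, or with
    fewer than ``min_inspections`` monocular inspections, are EXCLUDED.
    Otherwise the left count is tested against Binomial(L+R, 1/2); the
    bird is lateralized toward its majority eye when the two-tailed p is
    below ``alpha``.  ``method='exact'`` (default) uses the exact
    binomial, appropriate at the small per-bird counts typical of field
    data; ``method='z'`` uses the continuity-corrected normal
    approximation.
    """
    if summary.interrupted:
        return LateralityResult(
            summary.bird_id, Classification.EXCLUDED, None, None, None,
            exclusion_reason="interrupted",
        )
    n_mono = summary.n_monocular
    if n_mono < min_inspections:
        return LateralityResult(
            summary.bird_id, Classification.EXCLUDED, None, None, None,
            exclusion_reason=f"below_min_inspections ({n_mono} < {min_inspections})",
        )
    li = laterality_index(summary.n_left, summary.n_right)
    test_fn = binomial_exact if method == "exact" else binomial_z
    test = test_fn(summary.n_left, n_mono)
    if test.p_value < alpha and summary.n_left != summary.n_right:
        cls = (
            Classification.LEFT
            if summary.n_left > summary.n_right
            else Classification.RIGHT
        )
    else:
        cls = Classification.NONE
    return LateralityResult(summary.bird_id, cls, li, abs(li), test)


def median_with_ci(
    values: Sequence[float], confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Sample median with a distribution-free CI from binomial order
    statistics (reported descriptively; the exact coverage is at least
    the nominal level only up to the discreteness of the data)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise InvalidInputError("median of empty sample")
    med = float(np.median(x))
    if n == 1:
        return med, (med, med)
    alpha = 1.0 - confidence
    lo_idx = int(sps.binom.ppf(alpha / 2.0, n, 0.5))
    hi_idx = int(sps.binom.ppf(1.0 - alpha / 2.0, n, 0.5))
    lo_idx = max(lo_idx, 0)
    hi_idx = min(hi_idx, n - 1)
    return med, (float(x[lo_idx]), float(x[hi_idx]))


def population_analysis(
    results: Sequence[LateralityResult],
    li_values: Sequence[float],
    food_type: FoodType | None = None,
    inspection_counts: Sequence[int] | None = None,
) -> PopulationReport:
    """Population-level lateralization inference over classified birds.

    ``results`` are per-bird classifications; EXCLUDED birds are
    ignored.  ``li_values`` are the LI scores entering the one-sample
    Wilcoxon location test — by default all analyzable birds (including
    NONE), since the index is computed for every individual.  The
    prevalence test compares the number of lateralized birds with
    Binomial(n_analyzable, 1/2) using the continuity-corrected z; the
    direction test does the same for the majority direction among the
    lateralized.  When no bird is lateralized the direction test is
    omitted (None).
    """
    kept = [r for r in results if r.classification is not Classification.EXCLUDED]
    if not kept:
        raise InvalidInputError("no analyzable (non-EXCLUDED) birds")
    n_left = sum(1 for r in kept if r.classification is Classification.LEFT)
    n_right = sum(1 for r in kept if r.classification is Classification.RIGHT)
    n_none = sum(1 for r in kept if r.classification is Classification.NONE)
    n_analyzable = len(kept)
    n_lat = n_left + n_right
    prevalence = binomial_z(n_lat, n_analyzable)
    if n_lat > 0:
        majority = Classification.LEFT if n_left >= n_right else Classification.RIGHT
        direction = binomial_z(max(n_left, n_right), n_lat)
    else:
        majority = None
        direction = None
    li_test = wilcoxon_signed_rank(list(li_values), 0.0)
    med = ci = None
    if inspection_counts is not None and len(inspection_counts) > 0:
        med, ci = median_with_ci(list(inspection_counts))
    return PopulationReport(
        food_type=food_type,
        n_analyzable=n_analyzable,
        n_left_pref=n_left,
        n_right_pref=n_right,
        n_none=n_none,
        lateralized_vs_total=prevalence,
        direction_among_lateralized=direction,
        majority_direction=majority,
        li_location=li_test,
        median_inspections=med,
        median_inspections_ci=ci,
    )


def strength_comparison(
    abs_li_a: Sequence[float], abs_li_b: Sequence[float]
) -> TestResult:
    """Mann-Whitney comparison of preference strength (ABS-LI) between
    two groups, e.g. two food types."""
    from .stats_core import mann_whitney_u

    return mann_whitney_u(list(abs_li_a), list(abs_li_b))
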