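"""End-to-end orchestration: raw peck-event tables -> per-bird
summaries -> eye-preference classification -> population, feeding and
Monte-Carlo flock analyses -> a JSON-serializable report bundle.

The event table is a flat CSV, one row per peck:
``site_id, tree_id, flock_id, bird_id, food_type, t_land_s, t_peck_s,
inspection_eye (L/R/NONE), success (0/1), freeze_before_s,
interrupted (0/1)``.  One visit is one (bird, tree, landing) episode;
individuals are assumed distinct across trees by field protocol, so no
re-identification is attempted.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import feeding, flock_mc
from .laterality import (
    BirdSummary,
    Classification,
    FoodType,
    LateralityResult,
    classify_individual,
    population_analysis,
    strength_comparison,
)
from .stats_core import (
    DegenerateInputError,
    InvalidInputError,
    kruskal_wallis,
)

__all__ = ["AnalysisConfig", "summarize_birds", "classify_birds",
           "run_full_analysis", "EVENT_SCHEMA"]

logger = logging.getLogger("peckside")

EVENT_SCHEMA: dict[str, type] = {
    "site_id": str,
    "tree_id": str,
    "flock_id": str,
    "bird_id": str,
    "food_type": str,
    "t_land_s": float,
    "t_peck_s": float,
    "inspection_eye": str,
    "success": int,
    "freeze_before_s": float,
    "interrupted": int,
}


class AnalysisConfig(BaseModel):
    """Thresholds and knobs of the full analysis."""

    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    min_inspections: int = Field(default=15, ge=1)
    n_errors_cap: int = Field(default=6, ge=1)
    freeze_threshold_s: float = Field(default=5.0, gt=0.0)
    n_sim_flocks: int = Field(default=10, ge=1)
    seed: int = 0
    classification_method: str = "exact"  # "exact" or "z"

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        if self.classification_method not in ("exact", "z"):
            raise ValueError("classification_method must be 'exact' or 'z'")
        return self


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Schema-check an event table, coercing column dtypes."""
    missing = [c for c in EVENT_SCHEMA if c not in events.columns]
    if missing:
        raise InvalidInputError(f"event table missing columns: {missing}")
    out = events.copy()
    for col, typ in EVENT_SCHEMA.items():
        try:
            out[col] = out[col].astype(typ)
        except (TypeError, ValueError) as err:
            raise InvalidInputError(f"column {col!r} not coercible: {err}") from err
    bad_eye = ~out["inspection_eye"].isin(["L", "R", "NONE"])
    if bad_eye.any():
        raise InvalidInputError(
            f"invalid inspection_eye at rows {list(out.index[bad_eye][:5])}"
        )
    if (out["t_peck_s"] < out["t_land_s"]).any():
        raise InvalidInputError("t_peck_s before t_land_s")
    if (out["freeze_before_s"] < 0).any():
        raise InvalidInputError("negative freeze duration")
    for ft in out["food_type"].unique():
        FoodType(ft)
    return out


def summarize_birds(
    events: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Aggregate the event table to one row per (bird, tree, landing)
    visit: eye counts, successes, active feeding time (freezes longer
    than the threshold excluded), feeding latency.

    Active time runs from landing to the last peck; pauses above
    ``config.freeze_threshold_s`` are subtracted.
    """
    config = config or AnalysisConfig()
    if events.empty:
        logger.warning("empty event table; empty summary returned")
        return pd.DataFrame(
            columns=[
                "bird_id", "food_type", "site_id", "tree_id", "flock_id",
                "n_left", "n_right", "n_nonlateral", "n_pecks", "n_success",
                "active_time_s", "latency_s", "interrupted",
            ]
        )
    events = validate_events(events)
    rows = []
    for (bird, tree, t_land), g in events.groupby(
        ["bird_id", "tree_id", "t_land_s"], sort=True
    ):
        g = g.sort_values("t_peck_s")
        if g["t_peck_s"].diff().dropna().lt(0).any():
            raise InvalidInputError(f"unordered pecks for bird {bird}")
        eye = g["inspection_eye"]
        total = float(g["t_peck_s"].max() - t_land)
        frozen = float(
            g.loc[g["freeze_before_s"] > config.freeze_threshold_s,
                  "freeze_before_s"].sum()
        )
        rows.append(
            {
                "bird_id": bird,
                "food_type": g["food_type"].iloc[0],
                "site_id": g["site_id"].iloc[0],
                "tree_id": tree,
                "flock_id": g["flock_id"].iloc[0],
                "n_left": int((eye == "L").sum()),
                "n_right": int((eye == "R").sum()),
                "n_nonlateral": int((eye == "NONE").sum()),
                "n_pecks": int(len(g)),
                "n_success": int(g["success"].sum()),
                "active_time_s": max(total - frozen, 1e-9),
                "latency_s": float(g["t_peck_s"].min() - t_land),
                "interrupted": bool(g["interrupted"].iloc[0]),
            }
        )
    return pd.DataFrame(rows)


def _to_bird_summary(row: pd.Series) -> BirdSummary:
    return BirdSummary(
        bird_id=row["bird_id"],
        food_type=FoodType(row["food_type"]),
        site_id=row["site_id"],
        tree_id=row["tree_id"],
        flock_id=row["flock_id"],
        n_left=int(row["n_left"]),
        n_right=int(row["n_right"]),
        n_nonlateral=int(row["n_nonlateral"]),
        n_pecks=int(row["n_pecks"]),
        n_success=int(row["n_success"]),
        active_time_s=float(row["active_time_s"]),
        latency_s=float(row["latency_s"]),
        interrupted=bool(row["interrupted"]),
    )


def classify_birds(
    summaries: pd.DataFrame, config: AnalysisConfig | None = None
) -> list[tuple[BirdSummary, LateralityResult]]:
    """Classify every summarised bird; returns (summary, result) pairs."""
    config = config or AnalysisConfig()
    out = []
    for _, row in summaries.iterrows():
        summ = _to_bird_summary(row)
        res = classify_individual(
            summ,
            alpha=config.alpha,
            min_inspections=config.min_inspections,
            method=config.classification_method,  # type: ignore[arg-type]
        )
        out.append((summ, res))
    return out


def _error_eyes_for_bird(events: pd.DataFrame, bird_id: str) -> list[str]:
    g = events[(events["bird_id"] == bird_id) & (events["success"] == 0)]
    return list(g.sort_values("t_peck_s")["inspection_eye"])


def _grouping_checks(analyzable: pd.DataFrame, li: dict[str, float]) -> dict:
    """Kruskal-Wallis checks of LI homogeneity across sites, trees and
    flocks (run only where >= 2 groups each hold >= 2 birds)."""
    checks: dict[str, dict | None] = {}
    for level in ("site_id", "tree_id", "flock_id"):
        groups = [
            [li[b] for b in g["bird_id"]]
            for _, g in analyzable.groupby(level)
            if len(g) >= 2
        ]
        if len(groups) < 2:
            checks[level] = None
            continue
        try:
            checks[level] = kruskal_wallis(groups).to_record()
        except DegenerateInputError as err:
            checks[level] = {"degenerate": str(err)}
    return checks


def run_full_analysis(
    events: pd.DataFrame, config: AnalysisConfig | None = None
) -> dict:
    """Run every analysis stage per food type and return a JSON-ready
    report bundle.  Degenerate stages (e.g. no errors recorded for a
    food type) are reported as omitted, never abort the run."""
    config = config or AnalysisConfig()
    events = validate_events(events)
    summaries = summarize_birds(events, config)
    report: dict = {"config": config.model_dump(), "food_types": {}}
    n_input = len(summaries)
    n_excluded = 0
    abs_li_by_food: dict[str, list[float]] = {}
    for food in sorted(summaries["food_type"].unique()):
        sub = summaries[summaries["food_type"] == food]
        pairs = classify_birds(sub, config)
        results = [r for _, r in pairs]
        excluded = [r for r in results if r.classification is Classification.EXCLUDED]
        n_excluded += len(excluded)
        for r in excluded:
            logger.info("excluded %s: %s", r.bird_id, r.exclusion_reason)
        kept = [
            (s, r)
            for s, r in pairs
            if r.classification is not Classification.EXCLUDED
        ]
        food_report: dict = {
            "n_birds": len(pairs),
            "n_excluded": len(excluded),
            "exclusion_reasons": {
                r.bird_id: r.exclusion_reason for r in excluded
            },
        }
        if not kept:
            food_report["population"] = None
            report["food_types"][food] = food_report
            continue
        li = {r.bird_id: r.li for _, r in kept}
        abs_li_by_food[food] = [r.abs_li for _, r in kept]
        try:
            pop = population_analysis(
                [r for _, r in kept],
                [r.li for _, r in kept],
                food_type=FoodType(food),
                inspection_counts=[s.n_monocular for s, _ in kept],
            )
            food_report["population"] = pop.to_record()
        except (DegenerateInputError, InvalidInputError) as err:
            food_report["population"] = {"omitted": str(err)}
        food_report["classifications"] = [r.to_record() for _, r in kept]

        # accuracy: success proportion of lateral pecks, lateralized vs not
        lat_props, nonlat_props = [], []
        sub_events = events[events["bird_id"].isin(li.keys())]
        for s, r in kept:
            mono = sub_events[
                (sub_events["bird_id"] == s.bird_id)
                & (sub_events["inspection_eye"] != "NONE")
            ]
            if len(mono) == 0:
                continue
            prop = float(mono["success"].mean())
            if r.classification in (Classification.LEFT, Classification.RIGHT):
                lat_props.append(prop)
            else:
                nonlat_props.append(prop)
        any_errors = bool((sub_events["success"] == 0).any())
        if any_errors and lat_props and nonlat_props:
            food_report["accuracy_lat_vs_nonlat"] = feeding.accuracy_comparison(
                lat_props, nonlat_props
            ).to_record()
        else:
            food_report["accuracy_lat_vs_nonlat"] = {
                "omitted": "no pecking errors recorded"
                if not any_errors
                else "a group is empty"
            }

        # balanced six-error eye-conditional design
        if any_errors:
            birds_errors = [
                (r, _error_eyes_for_bird(sub_events, r.bird_id))
                for _, r in kept
                if r.classification in (Classification.LEFT, Classification.RIGHT)
            ]
            tests, breakdowns = feeding.balanced_error_analysis(
                birds_errors, config.n_errors_cap
            )
            food_report["balanced_errors"] = {
                "tests": {
                    k: (t.to_record() if t else None) for k, t in tests.items()
                },
                "breakdowns": [b.to_record() for b in breakdowns],
            }
        else:
            food_report["balanced_errors"] = {
                "omitted": "no pecking errors recorded"
            }

        # efficiency and latency comparisons
        records = [
            feeding.EfficiencyRecord(
                bird_id=s.bird_id,
                ingestion_rate=feeding.ingestion_rate(
                    s.n_success, s.active_time_s
                ),
                latency_s=s.latency_s,
                lateralized=r.classification
                in (Classification.LEFT, Classification.RIGHT),
                direction=r.classification
                if r.classification in (Classification.LEFT, Classification.RIGHT)
                else None,
            )
            for s, r in kept
        ]
        for key, grouping, metric in [
            ("ingestion_lat_vs_nonlat", "lat_vs_nonlat", "ingestion_rate"),
            ("ingestion_left_vs_right", "left_vs_right", "ingestion_rate"),
            ("latency_lat_vs_nonlat", "lat_vs_nonlat", "latency_s"),
        ]:
            try:
                food_report[key] = feeding.efficiency_comparison(
                    records, grouping, metric
                ).to_record()
            except (InvalidInputError, DegenerateInputError) as err:
                food_report[key] = {"omitted": str(err)}

        # Monte-Carlo synthetic-flock pseudoreplication check per flock
        analyzable_df = sub[sub["bird_id"].isin(li.keys())]
        mc_results = []
        for flock_id, g in analyzable_df.groupby("flock_id"):
            members = list(g["bird_id"])
            pool = list(
                analyzable_df.loc[
                    analyzable_df["flock_id"] != flock_id, "bird_id"
                ]
            )
            if len(members) < 2 or len(pool) < len(members):
                continue
            try:
                mc = flock_mc.flock_pseudoreplication_test(
                    li,
                    members,
                    pool,
                    n_sim=config.n_sim_flocks,
                    seed=config.seed,
                    real_flock_id=str(flock_id),
                )
                mc_results.append(mc.to_record())
            except (DegenerateInputError, InvalidInputError) as err:
                mc_results.append({"real_flock_id": str(flock_id),
                                   "omitted": str(err)})
        food_report["flock_mc"] = mc_results
        food_report["grouping_checks"] = _grouping_checks(analyzable_df, li)
        report["food_types"][food] = food_report

    foods = sorted(abs_li_by_food)
    if len(foods) == 2:
        try:
            report["strength_between_foods"] = strength_comparison(
                abs_li_by_food[foods[0]], abs_li_by_food[foods[1]]
            ).to_record()
        except (InvalidInputError, DegenerateInputError) as err:
            report["strength_between_foods"] = {"omitted": str(err)}
    report["accounting"] = {
        "n_input_birds": n_input,
        "n_excluded": n_excluded,
        "n_analyzed": n_input - n_excluded,
    }
    return report
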