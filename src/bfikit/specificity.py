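"""Cross-food generalizability, specificity scoring and elevation windows.

A candidate marker discovered against one food is credible as a food-group
marker when it recurs in the top candidates of every member food (e.g. the
same m/z bin for beans, peanuts, peas and soy), and as a food-specific
marker when its post-meal intensity separates samples following the target
food from post-meal samples following every other food.  Specificity is
scored as a Mann-Whitney AUC so it shares the discovery stage's oracle and
interpretation (1 = perfectly specific, 0.5 = uninformative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import IonAnnotation
from .discovery import FeatureStats, feature_auc

logger = logging.getLogger(__name__)

POST_MEAL_TYPES = ("post_breakfast", "post_lunch", "post_dinner", "bed_time")


@dataclass(frozen=True)
class BiomarkerCandidate:
    """One m/z bin proposed as a biomarker of a food (or food group)."""

    mz: float
    source_contrast: str
    aggregate_rank: int
    annotations: tuple[IonAnnotation, ...] = ()
    specificity_score: Optional[float] = None
    shared_across: tuple[str, ...] = ()
    elevation_window_h: Optional[float] = None

    def __post_init__(self) -> None:
        if self.specificity_score is not None and not (
            0.0 <= self.specificity_score <= 1.0
        ):
            raise ValueError(
                f"specificity score out of [0, 1]: {self.specificity_score}"
            )


def cross_food_consistency(
    candidates_by_food: Mapping[str, Sequence[FeatureStats]],
    group_map: Mapping[str, Sequence[str]],
) -> dict[str, dict[float, dict[str, int]]]:
    """Candidate bins shared by every member food of each food group.

    ``candidates_by_food`` maps food name to its ranked selected features;
    ``group_map`` maps group name to its member foods.  Returns, per group,
    the intersection of candidate bins across all member foods present, as
    ``{group: {mz: {food: aggregate_rank}}}``.  Groups with fewer than two
    member foods present are skipped with a logged notice.
    """
    if len(candidates_by_food) < 2:
        raise ValueError("candidate lists from >= 2 foods are required")
    out: dict[str, dict[float, dict[str, int]]] = {}
    for group, foods in group_map.items():
        present = [f for f in foods if f in candidates_by_food]
        if len(present) < 2:
            logger.info(
                "group %r skipped: %d member food(s) with candidates",
                group, len(present),
            )
            continue
        per_food_bins = {
            food: {round(c.mz, 9): c.aggregate_rank for c in candidates_by_food[food]}
            for food in present
        }
        shared = set.intersection(*(set(b) for b in per_food_bins.values()))
        out[group] = {
            mz: {food: per_food_bins[food][mz] for food in present}
            for mz in sorted(shared)
        }
    return out


def specificity_score(
    mz: float,
    matrix,
    truth: pd.DataFrame,
    target: str,
    post_meal_types: Sequence[str] = POST_MEAL_TYPES,
) -> float:
    """AUC of the bin's intensity: target-exposed vs other-food post-meal samples.

    Target-exposed samples are post-meal samples flagged for the target food
    (or ``group:<name>``); the comparison set is post-meal samples following
    any other food but not the target.  1 = perfectly specific, 0.5 = the bin
    does not distinguish the target from the rest of the menu.
    """
    col = target if ":" in target else f"food:{target}"
    if col not in truth.columns:
        raise ValueError(f"truth table has no column {col!r}")
    j = matrix.bin_index(mz)
    if abs(matrix.mz_bins[j] - mz) > 1e-6:
        raise ValueError(f"no bin at m/z {mz}")
    flags = truth.set_index("sample_id")
    food_cols = [c for c in truth.columns if c.startswith("food:")]
    values: list[float] = []
    labels: list[str] = []
    for i, m in enumerate(matrix.sample_meta):
        if m.urine_type not in post_meal_types:
            continue
        row = flags.loc[m.sample_id]
        if row[col]:
            values.append(matrix.intensities[i, j])
            labels.append("target")
        elif any(row[c] for c in food_cols):
            values.append(matrix.intensities[i, j])
            labels.append("other")
    if "target" not in labels or "other" not in labels:
        raise ValueError(
            f"empty comparison set for target {target!r}: need both "
            "target-exposed and other-food post-meal samples"
        )
    return feature_auc(values, np.array(labels), "target")


def elevation_window(
    times_h: Sequence[float],
    intensities: Sequence[float],
    baseline: float,
    meal_end_h: float = 0.0,
    threshold_fold: float = 2.0,
) -> float:
    """Width (h) of the contiguous post-meal interval above threshold x baseline.

    ``times_h``/``intensities`` are the sampled median time course of the
    marker; crossing times are located by linear interpolation between
    adjacent samples.  A signal that is never elevated yields 0.
    """
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    times = np.asarray(times_h, dtype=float)
    values = np.asarray(intensities, dtype=float)
    if times.ndim != 1 or times.size != values.size:
        raise ValueError("times and intensities must be 1-D and equal length")
    mask = times >= meal_end_h
    times, values = times[mask], values[mask]
    if times.size < 3:
        raise ValueError(">= 3 post-exposure time points are required")
    order = np.argsort(times)
    times, values = times[order], values[order]
    thresh = threshold_fold * baseline
    above = values >= thresh
    if not above.any():
        return 0.0

    def cross(i: int) -> float:
        # linear interpolation of the crossing time in (times[i], times[i+1])
        t0, t1 = times[i], times[i + 1]
        v0, v1 = values[i], values[i + 1]
        if v1 == v0:
            return t1
        return t0 + (thresh - v0) * (t1 - t0) / (v1 - v0)

    # find the first contiguous run of above-threshold samples
    start_idx = int(np.argmax(above))
    end_idx = start_idx
    while end_idx + 1 < above.size and above[end_idx + 1]:
        end_idx += 1
    t_start = times[start_idx] if start_idx == 0 else cross(start_idx - 1)
    t_end = times[end_idx] if end_idx == above.size - 1 else cross(end_idx)
    return float(t_end - t_start)


def median_time_course(
    matrix,
    mz: float,
    participant_days: Sequence[tuple[str, int, int]],
    urine_types: Sequence[str] = ("FMV",) + POST_MEAL_TYPES,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Median intensity per urine-type time over the given participant-days.

    Returns ``(times, medians, baseline)`` where baseline is the median FMV
    intensity of the same days (the participant's same-day first morning void
    is the elevation reference).
    """
    j = matrix.bin_index(mz)
    days = set(participant_days)
    per_type: dict[str, list[float]] = {t: [] for t in urine_types}
    for i, m in enumerate(matrix.sample_meta):
        if (m.participant_id, m.week, m.day) in days and m.urine_type in per_type:
            per_type[m.urine_type].append(matrix.intensities[i, j])
    from .design import URINE_TIMES

    times, meds = [], []
    for t in urine_types:
        if per_type[t]:
            times.append(URINE_TIMES[t])
            meds.append(float(np.median(per_type[t])))
    if not per_type.get("FMV"):
        raise ValueError("no FMV baseline samples among the given days")
    baseline = float(np.median(per_type["FMV"]))
    return np.array(times), np.array(meds), baseline
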