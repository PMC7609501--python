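"""Crossover dietary-intervention design objects.

The intervention is built around six daily menu plans delivered in two 3-day
experimental periods.  Plans 1-3 (period 1, Study 1) are eaten in the same
order in 2 consecutive weeks under a two-arm crossover of the "Pre"-day
dinner; plans 4-6 (period 2, Study 2) are eaten in orders given by the rows
of a randomly assigned 3x3 Latin square over 3 weeks, with the three
"Pre"-day dinners independently permuted.  Each experimental day carries a
fixed urine-collection schedule: first morning void (FMV), fasting,
post-breakfast and post-lunch spot samples, and an evening series after
dinner; the day after the last experimental day ("Post" day) contributes FMV
and fasting samples only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

MEAL_SLOTS = ("breakfast", "lunch", "snack", "dinner")

#: meal windows in hours from start of day (snack is a half-hour slot)
MEAL_WINDOWS: dict[str, tuple[float, float]] = {
    "breakfast": (8.0, 10.0),
    "lunch": (12.5, 14.5),
    "snack": (16.5, 17.0),
    "dinner": (18.0, 20.0),
}

#: spot-urine collection times in hours from start of day
URINE_TIMES: dict[str, float] = {
    "FMV": 7.0,
    "fasting": 7.5,
    "post_breakfast": 11.0,
    "post_lunch": 15.5,
    "post_dinner": 21.0,
    "bed_time": 23.0,
}

DAYTIME_URINE_TYPES = ("FMV", "fasting", "post_breakfast", "post_lunch")
POST_DINNER_SERIES = ("post_dinner", "bed_time")

PRE_DAY = 0
EXPERIMENTAL_DAYS = (1, 2, 3)
POST_DAY = 4


@dataclass(frozen=True)
class FoodItem:
    name: str
    food_group: str
    preparation: str = ""


@dataclass(frozen=True)
class MenuPlan:
    """One daily menu: four meal slots, each a list of food items."""

    plan_id: int
    meals: Mapping[str, tuple[FoodItem, ...]]

    def __post_init__(self) -> None:
        if not 1 <= self.plan_id <= 6:
            raise ValueError(f"plan_id must be 1-6, got {self.plan_id}")
        missing = [s for s in MEAL_SLOTS if s not in self.meals]
        if missing:
            raise ValueError(f"plan {self.plan_id}: missing meal slots {missing}")

    @property
    def period(self) -> int:
        """Experimental period: plans 1-3 -> 1, plans 4-6 -> 2."""
        return 1 if self.plan_id <= 3 else 2


def load_menu_plans(path=None) -> dict[int, MenuPlan]:
    """Load the packaged (or a user-supplied) menu-plan YAML fixture."""
    if path is None:
        text = (
            resources.files("bfikit").joinpath("data/menu_plans.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    plans: dict[int, MenuPlan] = {}
    for entry in raw["plans"]:
        meals = {
            slot: tuple(
                FoodItem(i["name"], i["food_group"], i.get("preparation", ""))
                for i in items
            )
            for slot, items in entry["meals"].items()
        }
        plan = MenuPlan(plan_id=int(entry["plan_id"]), meals=meals)
        plans[plan.plan_id] = plan
    return plans


@dataclass(frozen=True)
class LatinSquare:
    """n x n grid where every row and column is a permutation of 1..n."""

    grid: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        n = len(self.grid)
        symbols = set(range(1, n + 1))
        for i, row in enumerate(self.grid):
            if set(row) != symbols:
                raise ValueError(f"row {i} is not a permutation of 1..{n}: {row}")
        for j in range(n):
            col = {row[j] for row in self.grid}
            if col != symbols:
                raise ValueError(f"column {j} is not a permutation of 1..{n}")

    @property
    def order(self) -> int:
        return len(self.grid)

    def row(self, i: int) -> tuple[int, ...]:
        return self.grid[i]


MAX_ENUMERATION_ORDER = 4


def enumerate_latin_squares(order: int) -> list[LatinSquare]:
    """All Latin squares of the given order, lexicographically by grid.

    Exhaustive row-by-row search; order 3 yields exactly 12 squares (the
    randomization space of the three-plan, three-week crossover).
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if order > MAX_ENUMERATION_ORDER:
        raise ValueError(
            f"order {order} exceeds supported bound {MAX_ENUMERATION_ORDER}"
        )
    perms = list(itertools.permutations(range(1, order + 1)))
    squares: list[LatinSquare] = []

    def extend(rows: tuple[tuple[int, ...], ...]) -> None:
        if len(rows) == order:
            squares.append(LatinSquare(grid=rows))
            return
        for perm in perms:
            if all(
                perm[j] != prev[j] for prev in rows for j in range(order)
            ):
                extend(rows + (perm,))

    extend(())
    return squares


STUDY1_ARMS = ("standardized_first", "low_polyphenol_first")


@dataclass(frozen=True)
class StudyAssignment:
    """One participant's randomization outcome.

    Study 1: a crossover arm deciding which "Pre"-day dinner comes first.
    Study 2: a 3x3 Latin square (menu-plan order per week) plus an
    independent permutation of the three "Pre"-day dinners.
    """

    participant_id: str
    study: int
    square_index: Optional[int] = None
    square: Optional[LatinSquare] = None
    dinner_order: Optional[tuple[int, ...]] = None
    crossover_arm: Optional[str] = None

    def __post_init__(self) -> None:
        if self.study == 1:
            if self.crossover_arm not in STUDY1_ARMS:
                raise ValueError(
                    f"study-1 assignment needs a crossover arm in {STUDY1_ARMS}"
                )
        elif self.study == 2:
            if self.square is None or self.square.order != 3:
                raise ValueError("study-2 assignment needs a 3x3 Latin square")
            if self.dinner_order is None or sorted(self.dinner_order) != [1, 2, 3]:
                raise ValueError(
                    "study-2 assignment needs a dinner_order permutation of (1,2,3)"
                )
        else:
            raise ValueError(f"study must be 1 or 2, got {self.study}")

    @property
    def n_weeks(self) -> int:
        return 2 if self.study == 1 else 3

    def plan_order(self, week: int) -> tuple[int, ...]:
        """Menu-plan ids for the three experimental days of ``week`` (1-based)."""
        if not 1 <= week <= self.n_weeks:
            raise ValueError(f"week {week} invalid for study {self.study}")
        if self.study == 1:
            return (1, 2, 3)  # same order both weeks
        return tuple(s + 3 for s in self.square.row(week - 1))


def _check_ids(participant_ids: Sequence[str]) -> list[str]:
    ids = list(participant_ids)
    if not ids:
        raise ValueError("participant id list is empty")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate participant ids: {dupes}")
    return ids


def randomize_study1(participant_ids: Sequence[str], seed: int) -> list[StudyAssignment]:
    """Uniform two-arm crossover randomization, reproducible by seed."""
    ids = _check_ids(participant_ids)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    arms = rng.integers(0, 2, size=len(ids))
    return [
        StudyAssignment(participant_id=pid, study=1, crossover_arm=STUDY1_ARMS[a])
        for pid, a in zip(ids, arms)
    ]


def randomize_study2(participant_ids: Sequence[str], seed: int) -> list[StudyAssignment]:
    """Uniform draw over the 12 order-3 Latin squares, plus an independent
    "Pre"-day dinner permutation drawn from a separate stream of the seed."""
    ids = _check_ids(participant_ids)
    squares = enumerate_latin_squares(3)
    square_stream, dinner_stream = np.random.SeedSequence([seed, 2]).spawn(2)
    sq_rng = np.random.default_rng(square_stream)
    din_rng = np.random.default_rng(dinner_stream)
    out: list[StudyAssignment] = []
    for pid in ids:
        idx = int(sq_rng.integers(0, len(squares)))
        order = tuple(int(x) for x in din_rng.permutation([1, 2, 3]))
        out.append(
            StudyAssignment(
                participant_id=pid,
                study=2,
                square_index=idx,
                square=squares[idx],
                dinner_order=order,
            )
        )
    return out


@dataclass(frozen=True)
class MealEvent:
    day: int
    slot: str
    plan_id: Optional[int]  # None for the "Pre"-day dinner (not a menu plan)
    window_start: float
    window_end: float


@dataclass(frozen=True)
class UrineSlot:
    day: int
    urine_type: str
    time: float


@dataclass(frozen=True)
class WeekSchedule:
    participant_id: str
    week: int
    meals: tuple[MealEvent, ...]
    urine_slots: tuple[UrineSlot, ...]

    def plan_sequence(self) -> tuple[int, ...]:
        seen: list[int] = []
        for m in self.meals:
            if m.plan_id is not None and m.plan_id not in seen:
                seen.append(m.plan_id)
        return tuple(seen)


def build_week_schedule(assignment: StudyAssignment, week: int) -> WeekSchedule:
    """Expand one assignment-week into meal events and urine-collection slots.

    Day indices are abstract: Pre=0, experimental days 1-3, Post=4 (the
    calendar anchoring Monday-Friday is metadata only).
    """
    order = assignment.plan_order(week)  # validates week
    meals: list[MealEvent] = [
        MealEvent(
            day=PRE_DAY,
            slot="dinner",
            plan_id=None,
            window_start=MEAL_WINDOWS["dinner"][0],
            window_end=MEAL_WINDOWS["dinner"][1],
        )
    ]
    urine: list[UrineSlot] = []
    for day, plan_id in zip(EXPERIMENTAL_DAYS, order):
        for slot in MEAL_SLOTS:
            w0, w1 = MEAL_WINDOWS[slot]
            meals.append(
                MealEvent(day=day, slot=slot, plan_id=plan_id,
                          window_start=w0, window_end=w1)
            )
        for utype in DAYTIME_URINE_TYPES + POST_DINNER_SERIES:
            urine.append(UrineSlot(day=day, urine_type=utype, time=URINE_TIMES[utype]))
    for utype in ("FMV", "fasting"):
        urine.append(UrineSlot(day=POST_DAY, urine_type=utype, time=URINE_TIMES[utype]))
    return WeekSchedule(
        participant_id=assignment.participant_id,
        week=week,
        meals=tuple(meals),
        urine_slots=tuple(urine),
    )


COMPLIANCE_LEVELS = (0, 25, 50, 75, 100)


@dataclass(frozen=True)
class ComplianceRecord:
    participant_id: str
    item: str
    amount_eaten_percent: int
    substitutions: str = ""
    intrusions: str = ""

    def __post_init__(self) -> None:
        if self.amount_eaten_percent not in COMPLIANCE_LEVELS:
            raise ValueError(
                f"amount_eaten_percent must be one of {COMPLIANCE_LEVELS}, "
                f"got {self.amount_eaten_percent}"
            )


def compliance_fraction(
    records: Iterable[ComplianceRecord],
) -> tuple[dict[str, float], float]:
    """Per-participant mean fraction eaten, and the overall mean over participants."""
    records = list(records)
    if not records:
        raise ValueError("no compliance records given")
    sums: dict[str, list[float]] = {}
    for rec in records:
        sums.setdefault(rec.participant_id, []).append(
            rec.amount_eaten_percent / 100.0
        )
    per_participant = {pid: float(np.mean(v)) for pid, v in sums.items()}
    overall = float(np.mean(list(per_participant.values())))
    return per_participant, overall


#: planned vs achieved enrolment (study 2 over-recruited to allow for drop out)
PLANNED_SAMPLE_SIZE = {1: 15, 2: 30}
ACHIEVED_SAMPLE_SIZE = {1: 15, 2: 36}


def over_enrolment_percent(study: int = 2) -> float:
    """Achieved enrolment relative to the planned target, in percent."""
    planned = PLANNED_SAMPLE_SIZE[study]
    achieved = ACHIEVED_SAMPLE_SIZE[study]
    return 100.0 * (achieved - planned) / planned
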