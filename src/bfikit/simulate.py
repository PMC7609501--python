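"""Synthetic cohort, exposure and spot-urine fingerprint generator.

Emulates the statistical structure the discovery pipeline assumes: a cohort
drawn to the recruited study's marginals; menu-plan-driven food exposures per
participant, day and meal slot under the crossover randomization; and a
samples x m/z-bin fingerprint in which each biomarker's ionization products
rise multiplicatively after consumption of a source food and decay
first-order, on top of participant-specific log-normal baselines, urine
dilution variation, and multiplicative measurement noise.

The generator emits a truth table (per-sample exposure state per food and per
food group) alongside every fingerprint so that recall and precision of the
discovery stage can be computed exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import design
from .chem import ChemicalFormula, IonizationRule, RULES_BY_LABEL, ion_mz
from .design import (
    COMPLIANCE_LEVELS,
    MenuPlan,
    StudyAssignment,
    URINE_TIMES,
    WeekSchedule,
    build_week_schedule,
)

HOURS_PER_DAY = 24.0


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class TraitProfile:
    """Truncated-normal profile for one continuous trait."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"trait SD must be positive, got {self.sd}")
        if not self.lo < self.hi:
            raise ValueError(f"trait bounds must satisfy lo < hi: {self.lo}, {self.hi}")


@dataclass(frozen=True)
class CohortProfile:
    """Marginals the generated cohort must reproduce.

    Defaults are the recruited totals of the two studies combined: 51
    participants, 57% female, age 46.3 (SD 17.5) years within 19-77.
    """

    n: int = 51
    female_fraction: float = 0.57
    age: TraitProfile = field(default_factory=lambda: TraitProfile(46.3, 17.5, 19.0, 77.0))
    weight_kg: TraitProfile = field(default_factory=lambda: TraitProfile(68.3, 11.5, 45.0, 110.0))
    height_cm: TraitProfile = field(default_factory=lambda: TraitProfile(168.2, 8.0, 145.0, 195.0))
    waist_cm: TraitProfile = field(default_factory=lambda: TraitProfile(83.1, 9.7, 58.0, 125.0))

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError(
                f"female_fraction must be in [0, 1], got {self.female_fraction}"
            )


STUDY_PROFILES: dict[str, CohortProfile] = {
    "total": CohortProfile(),
    "study1": CohortProfile(
        n=15,
        female_fraction=0.53,
        age=TraitProfile(45.3, 14.8, 22.0, 63.0),
        weight_kg=TraitProfile(71.9, 13.5, 45.0, 115.0),
        height_cm=TraitProfile(169.5, 9.0, 145.0, 195.0),
        waist_cm=TraitProfile(84.5, 11.3, 58.0, 125.0),
    ),
    "study2": CohortProfile(
        n=36,
        female_fraction=0.58,
        age=TraitProfile(46.7, 18.7, 19.0, 77.0),
        weight_kg=TraitProfile(66.8, 10.4, 45.0, 110.0),
        height_cm=TraitProfile(167.6, 7.7, 145.0, 195.0),
        waist_cm=TraitProfile(82.5, 9.1, 58.0, 125.0),
    ),
}


@dataclass(frozen=True)
class Participant:
    participant_id: str
    sex: str
    age: float
    weight_kg: float
    height_cm: float
    waist_cm: float

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2


@dataclass(frozen=True)
class Cohort:
    participants: tuple[Participant, ...]

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]

    @property
    def female_count(self) -> int:
        return sum(1 for p in self.participants if p.sex == "F")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.ids,
                "sex": [p.sex for p in self.participants],
                "age": [p.age for p in self.participants],
                "weight_kg": [p.weight_kg for p in self.participants],
                "height_cm": [p.height_cm for p in self.participants],
                "waist_cm": [p.waist_cm for p in self.participants],
                "bmi": [p.bmi for p in self.participants],
            }
        )


def _draw_trait(profile: TraitProfile, n: int, rng: np.random.Generator) -> np.ndarray:
    a = (profile.lo - profile.mean) / profile.sd
    b = (profile.hi - profile.mean) / profile.sd
    return stats.truncnorm.rvs(
        a, b, loc=profile.mean, scale=profile.sd, size=n, random_state=rng
    )


def generate_cohort(
    profile: CohortProfile | None = None, seed: int = 0
) -> Cohort:
    """Draw a cohort matching the profile's marginals.

    The female count is fixed deterministically by rounding
    ``female_fraction * n`` (so the default profile reproduces 29/51 = 57%
    exactly); continuous traits are truncated-normal draws.
    """
    profile = profile or CohortProfile()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 10]))
    n_female = round(profile.female_fraction * profile.n)
    sexes = ["F"] * n_female + ["M"] * (profile.n - n_female)
    ages = _draw_trait(profile.age, profile.n, rng)
    weights = _draw_trait(profile.weight_kg, profile.n, rng)
    heights = _draw_trait(profile.height_cm, profile.n, rng)
    waists = _draw_trait(profile.waist_cm, profile.n, rng)
    width = max(2, len(str(profile.n)))
    participants = tuple(
        Participant(
            participant_id=f"P{i + 1:0{width}d}",
            sex=sexes[i],
            age=float(ages[i]),
            weight_kg=float(weights[i]),
            height_cm=float(heights[i]),
            waist_cm=float(waists[i]),
        )
        for i in range(profile.n)
    )
    return Cohort(participants=participants)


# ---------------------------------------------------------------------------
# biomarker panel


@dataclass(frozen=True)
class BiomarkerSpec:
    """A compound, its ionization products, source foods and response kinetics.

    The urinary signal appears ``appearance_lag_h`` hours after the end of a
    meal containing a source food and decays first-order with
    ``decay_halflife_h``; at its peak the signal is ``spike_magnitude`` times
    the participant's baseline (scaled by the fraction of the meal consumed).
    """

    compound_name: str
    formula: ChemicalFormula
    ionization_products: tuple[IonizationRule, ...]
    food_sources: str
    source_groups: tuple[str, ...]
    msi_evidence: tuple[str, ...]
    appearance_lag_h: float
    decay_halflife_h: float
    spike_magnitude: float

    def __post_init__(self) -> None:
        if self.appearance_lag_h < 0:
            raise ValueError("appearance lag must be >= 0")
        if self.decay_halflife_h <= 0:
            raise ValueError("decay half-life must be positive")
        if self.spike_magnitude < 1:
            raise ValueError("spike magnitude must be >= 1 (1 = no response)")

    def elevation_window_h(self, threshold_fold: float = 2.0) -> float:
        """Closed-form duration the noise-free signal stays above
        ``threshold_fold`` x baseline after a fully consumed meal."""
        excess = self.spike_magnitude - 1.0
        if excess <= threshold_fold - 1.0:
            return 0.0
        return self.appearance_lag_h + self.decay_halflife_h * math.log2(
            excess / (threshold_fold - 1.0)
        )


def load_panel(path=None) -> list[BiomarkerSpec]:
    """Load the packaged (or a user-supplied) biomarker panel CSV."""
    if path is None:
        with resources.files("bfikit").joinpath("data/biomarker_panel.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    required = {
        "name", "formula", "food_sources", "source_groups",
        "ionization_products", "msi_evidence",
        "appearance_lag_h", "decay_halflife_h", "spike_magnitude",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
    panel: list[BiomarkerSpec] = []
    for _, row in df.iterrows():
        labels = [s for s in str(row["ionization_products"]).split(";") if s]
        try:
            rules = tuple(RULES_BY_LABEL[lab] for lab in labels)
        except KeyError as exc:
            raise ValueError(
                f"panel row {row['name']!r}: unknown ionization product {exc}"
            ) from None
        panel.append(
            BiomarkerSpec(
                compound_name=str(row["name"]),
                formula=ChemicalFormula.parse(str(row["formula"])),
                ionization_products=rules,
                food_sources=str(row["food_sources"]),
                source_groups=tuple(str(row["source_groups"]).split(";")),
                msi_evidence=tuple(str(row["msi_evidence"]).split(";")),
                appearance_lag_h=float(row["appearance_lag_h"]),
                decay_halflife_h=float(row["decay_halflife_h"]),
                spike_magnitude=float(row["spike_magnitude"]),
            )
        )
    return panel


def panel_msi_levels(panel: Sequence[BiomarkerSpec]) -> dict[str, int]:
    from .chem import assign_msi_level

    return {
        spec.compound_name: assign_msi_level(
            **{flag: True for flag in spec.msi_evidence}
        )
        for spec in panel
    }


# ---------------------------------------------------------------------------
# exposures


@dataclass(frozen=True)
class ExposureEvent:
    participant_id: str
    week: int
    day: int
    slot: str
    food_name: str
    food_group: str
    consumed_fraction: float
    meal_end_h: float  # hours from start of the study week's day 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.consumed_fraction <= 1.0:
            raise ValueError("consumed fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ComplianceProfile:
    """Probabilities over the five self-reported consumption levels.

    The default puts 88% of items at fully eaten, giving an overall
    compliance fraction around 0.94, comfortably above the >80% the design
    anticipates.
    """

    probabilities: Mapping[int, float] = field(
        default_factory=lambda: {100: 0.88, 75: 0.07, 50: 0.03, 25: 0.01, 0: 0.01}
    )

    def __post_init__(self) -> None:
        probs = dict(self.probabilities)
        if set(probs) != set(COMPLIANCE_LEVELS):
            raise ValueError(f"probabilities must cover levels {COMPLIANCE_LEVELS}")
        total = sum(probs.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"probabilities must sum to 1, got {total}")

    def levels_and_probs(self) -> tuple[list[int], list[float]]:
        levels = sorted(self.probabilities)
        return levels, [self.probabilities[l] for l in levels]


ZERO_COMPLIANCE = ComplianceProfile({100: 0.0, 75: 0.0, 50: 0.0, 25: 0.0, 0: 1.0})


def simulate_exposures(
    cohort: Cohort,
    assignments: Sequence[StudyAssignment],
    menu_plans: Mapping[int, MenuPlan],
    compliance: ComplianceProfile | None = None,
    seed: int = 0,
    weeks: Optional[Sequence[int]] = None,
) -> list[ExposureEvent]:
    """One exposure event per participant x week x day x meal slot x food item.

    Consumed fractions are drawn from the five-level self-report scale with
    the compliance profile's probabilities; meal end times are drawn
    uniformly inside each slot's scheduled window.
    """
    compliance = compliance or ComplianceProfile()
    by_id = {a.participant_id: a for a in assignments}
    missing = [pid for pid in cohort.ids if pid not in by_id]
    if missing:
        raise ValueError(f"no assignment for participants: {missing}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20]))
    levels, probs = compliance.levels_and_probs()
    events: list[ExposureEvent] = []
    for pid in cohort.ids:
        assignment = by_id[pid]
        week_range = weeks or range(1, assignment.n_weeks + 1)
        for week in week_range:
            schedule = build_week_schedule(assignment, week)
            for meal in schedule.meals:
                if meal.plan_id is None:
                    continue  # "Pre"-day dinner is not a menu-plan meal
                plan = menu_plans.get(meal.plan_id)
                if plan is None:
                    raise ValueError(f"missing menu plan {meal.plan_id}")
                meal_end = float(rng.uniform(meal.window_start, meal.window_end))
                for item in plan.meals[meal.slot]:
                    level = int(rng.choice(levels, p=probs))
                    events.append(
                        ExposureEvent(
                            participant_id=pid,
                            week=week,
                            day=meal.day,
                            slot=meal.slot,
                            food_name=item.name,
                            food_group=item.food_group,
                            consumed_fraction=level / 100.0,
                            meal_end_h=meal.day * HOURS_PER_DAY + meal_end,
                        )
                    )
    return events


def exposures_to_frame(events: Sequence[ExposureEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [e.participant_id for e in events],
            "week": [e.week for e in events],
            "day": [e.day for e in events],
            "slot": [e.slot for e in events],
            "food_name": [e.food_name for e in events],
            "food_group": [e.food_group for e in events],
            "consumed_fraction": [e.consumed_fraction for e in events],
            "meal_end_h": [e.meal_end_h for e in events],
        }
    )


def compliance_records_from_events(
    events: Sequence[ExposureEvent],
) -> list[design.ComplianceRecord]:
    return [
        design.ComplianceRecord(
            participant_id=e.participant_id,
            item=e.food_name,
            amount_eaten_percent=int(round(e.consumed_fraction * 100)),
        )
        for e in events
    ]


# ---------------------------------------------------------------------------
# fingerprints


@dataclass(frozen=True)
class SampleMeta:
    participant_id: str
    week: int
    day: int
    urine_type: str
    time_h: float  # hours from start of the week's day 0
    dilution_factor: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.urine_type not in URINE_TIMES:
            raise ValueError(f"unknown urine type {self.urine_type!r}")
        if self.dilution_factor <= 0:
            raise ValueError(
                f"sample {self.sample_id or '?'}: dilution factor must be positive"
            )


@dataclass
class FingerprintMatrix:
    """Samples x m/z-bin intensity matrix with per-sample metadata."""

    mz_bins: np.ndarray  # ascending bin centers, Da
    intensities: np.ndarray  # (n_samples, n_bins), non-negative
    sample_meta: list[SampleMeta]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.mz_bins = np.asarray(self.mz_bins, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz_bins.ndim != 1 or np.any(np.diff(self.mz_bins) <= 0):
            raise ValueError("mz_bins must be strictly ascending")
        if self.intensities.shape != (len(self.sample_meta), self.mz_bins.size):
            raise ValueError(
                f"intensity shape {self.intensities.shape} inconsistent with "
                f"{len(self.sample_meta)} samples x {self.mz_bins.size} bins"
            )
        if np.any(self.intensities < 0):
            raise ValueError("negative intensities are not allowed")

    @property
    def n_samples(self) -> int:
        return len(self.sample_meta)

    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.sample_meta]

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [m.sample_id for m in self.sample_meta],
                "participant_id": [m.participant_id for m in self.sample_meta],
                "week": [m.week for m in self.sample_meta],
                "day": [m.day for m in self.sample_meta],
                "urine_type": [m.urine_type for m in self.sample_meta],
                "time_h": [m.time_h for m in self.sample_meta],
                "dilution_factor": [m.dilution_factor for m in self.sample_meta],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.intensities, columns=[f"{mz:.5f}" for mz in self.mz_bins]
        )
        df.insert(0, "sample_id", self.sample_ids())
        return df

    def bin_index(self, mz: float) -> int:
        idx = int(np.argmin(np.abs(self.mz_bins - mz)))
        return idx


def bin_center(mz: float, bin_width: float) -> float:
    """Center of the half-open bin [k*w, (k+1)*w) containing ``mz``."""
    k = math.floor(mz / bin_width)
    return (k + 0.5) * bin_width


def marker_bin_map(
    panel: Sequence[BiomarkerSpec], bin_width: float = 0.01
) -> dict[str, list[float]]:
    """Bin centers of every ionization product of every panel compound.

    Raises if two different compounds collide in the same bin at the
    configured grid resolution, since their simulated signals would then be
    indistinguishable.
    """
    owner: dict[float, str] = {}
    out: dict[str, list[float]] = {}
    for spec in panel:
        centers: list[float] = []
        for rule in spec.ionization_products:
            center = round(bin_center(ion_mz(spec.formula, rule), bin_width), 9)
            prev = owner.get(center)
            if prev is not None and prev != spec.compound_name:
                raise ValueError(
                    f"m/z bin collision at {center:.5f}: "
                    f"{prev!r} vs {spec.compound_name!r}"
                )
            owner[center] = spec.compound_name
            if center not in centers:
                centers.append(center)
        out[spec.compound_name] = centers
    return out


@dataclass(frozen=True)
class BackgroundSpec:
    """Uninformative background features: count, m/z range, baseline scale."""

    n_features: int = 2000
    mz_min: float = 80.0
    mz_max: float = 600.0
    log_mean: float = math.log(1000.0)  # feature-level median intensity (a.u.)
    log_sigma_feature: float = 1.0  # between-feature spread of medians
    log_sigma_participant: float = 0.3  # between-participant spread per feature


def spike_multiplier(
    spec: BiomarkerSpec, t_h: float, meal_end_h: float, fraction: float
) -> float:
    """Fold-change over baseline at time ``t_h`` from one exposure event."""
    dt = t_h - meal_end_h - spec.appearance_lag_h
    if dt < 0 or fraction <= 0:
        return 1.0
    decay = math.exp(-dt * math.log(2.0) / spec.decay_halflife_h)
    return 1.0 + (spec.spike_magnitude - 1.0) * fraction * decay


def simulate_fingerprints(
    exposures: Sequence[ExposureEvent],
    panel: Sequence[BiomarkerSpec],
    assignments: Sequence[StudyAssignment],
    background: BackgroundSpec | None = None,
    noise_cv: float = 0.2,
    dilution_cv: float = 0.3,
    bin_width: float = 0.01,
    seed: int = 0,
    weeks: Optional[Sequence[int]] = None,
) -> tuple[FingerprintMatrix, pd.DataFrame]:
    """Simulate spot-urine fingerprints for every scheduled urine sample.

    Returns the fingerprint matrix and a truth table with one row per sample
    and one indicator column per food (``food:<name>``) and per food group
    (``group:<name>``): 1 if the sample was collected after a (partially)
    consumed meal containing that food earlier the same day.
    """
    background = background or BackgroundSpec()
    if noise_cv < 0 or dilution_cv < 0:
        raise ValueError("noise and dilution CVs must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 30]))

    # --- m/z grid: background bins plus one bin per marker ion product
    marker_bins = marker_bin_map(panel, bin_width)
    marker_centers = sorted({c for centers in marker_bins.values() for c in centers})
    n_grid = int(round((background.mz_max - background.mz_min) / bin_width))
    taken = {int(round(c / bin_width - 0.5)) for c in marker_centers}
    k0 = int(round(background.mz_min / bin_width))
    free = np.array(
        [k for k in range(k0, k0 + n_grid) if k not in taken], dtype=int
    )
    if background.n_features > free.size:
        raise ValueError(
            f"cannot place {background.n_features} background bins on the grid"
        )
    chosen = np.sort(rng.choice(free, size=background.n_features, replace=False))
    bg_centers = (chosen + 0.5) * bin_width
    mz_bins = np.sort(np.concatenate([bg_centers, np.array(marker_centers)]))
    n_bins = mz_bins.size
    is_marker = np.isin(mz_bins, np.array(marker_centers))
    marker_idx: dict[str, list[int]] = {
        name: [int(np.searchsorted(mz_bins, c)) for c in centers]
        for name, centers in marker_bins.items()
    }

    # --- per-participant baselines (feature medians shared across the cohort)
    pids = sorted({a.participant_id for a in assignments})
    feat_median = np.exp(
        rng.normal(background.log_mean, background.log_sigma_feature, size=n_bins)
    )
    baselines = {
        pid: feat_median
        * np.exp(rng.normal(0.0, background.log_sigma_participant, size=n_bins))
        for pid in pids
    }

    # --- exposures grouped per participant-week, markers by source group
    specs_by_group: dict[str, list[BiomarkerSpec]] = {}
    for spec in panel:
        for group in spec.source_groups:
            specs_by_group.setdefault(group, []).append(spec)
    events_by_pw: dict[tuple[str, int], list[ExposureEvent]] = {}
    for ev in exposures:
        events_by_pw.setdefault((ev.participant_id, ev.week), []).append(ev)

    by_id = {a.participant_id: a for a in assignments}
    rows: list[np.ndarray] = []
    meta: list[SampleMeta] = []
    truth_rows: list[dict[str, object]] = []
    food_names = sorted({e.food_name for e in exposures})
    group_names = sorted({e.food_group for e in exposures})

    for pid in pids:
        assignment = by_id[pid]
        week_range = weeks or range(1, assignment.n_weeks + 1)
        for week in week_range:
            schedule = build_week_schedule(assignment, week)
            events = events_by_pw.get((pid, week), [])
            for slot in schedule.urine_slots:
                t_abs = slot.day * HOURS_PER_DAY + slot.time
                sample_id = f"{pid}_w{week}_d{slot.day}_{slot.urine_type}"
                dilution = float(
                    np.exp(rng.normal(0.0, _lognorm_sigma(dilution_cv)))
                )
                x = baselines[pid].copy()
                for ev in events:
                    if ev.meal_end_h > t_abs:
                        continue
                    for spec in specs_by_group.get(ev.food_group, []):
                        mult = spike_multiplier(
                            spec, t_abs, ev.meal_end_h, ev.consumed_fraction
                        )
                        if mult != 1.0:
                            for j in marker_idx[spec.compound_name]:
                                x[j] *= mult
                x *= dilution
                if noise_cv > 0:
                    x *= np.exp(
                        rng.normal(0.0, _lognorm_sigma(noise_cv), size=n_bins)
                    )
                rows.append(x)
                meta.append(
                    SampleMeta(
                        participant_id=pid,
                        week=week,
                        day=slot.day,
                        urine_type=slot.urine_type,
                        time_h=t_abs,
                        dilution_factor=dilution,
                        sample_id=sample_id,
                    )
                )
                truth: dict[str, object] = {"sample_id": sample_id}
                for food in food_names:
                    truth[f"food:{food}"] = int(
                        any(
                            ev.food_name == food
                            and ev.day == slot.day
                            and ev.meal_end_h <= t_abs
                            and ev.consumed_fraction > 0
                            for ev in events
                        )
                    )
                for group in group_names:
                    truth[f"group:{group}"] = int(
                        any(
                            ev.food_group == group
                            and ev.day == slot.day
                            and ev.meal_end_h <= t_abs
                            and ev.consumed_fraction > 0
                            for ev in events
                        )
                    )
                truth_rows.append(truth)

    matrix = FingerprintMatrix(
        mz_bins=mz_bins,
        intensities=np.vstack(rows) if rows else np.empty((0, n_bins)),
        sample_meta=meta,
    )
    truth_df = pd.DataFrame(truth_rows)
    return matrix, truth_df


def _lognorm_sigma(cv: float) -> float:
    """Log-scale sigma of a log-normal with unit median and the given CV."""
    return math.sqrt(math.log(1.0 + cv * cv))


LEGUME_FOODS = ("garden peas", "baked beans", "peanuts", "tofu stir fry")


def shared_legume_marker(fold: float = 5.0) -> BiomarkerSpec:
    """A pyrogallol-sulfate-like marker shared by all legume foods.

    One ionization product ([M-H]1-, the 204.985 bin), fold-change ``fold``
    at peak, appearance lag 0.5 h and a 3 h half-life: strongly elevated in
    bed-time urine a few hours after an evening legume meal, and largely
    washed out of the next morning's first morning void.
    """
    return BiomarkerSpec(
        compound_name="pyrogallol sulfate",
        formula=ChemicalFormula.parse("C6H6O6S"),
        ionization_products=(RULES_BY_LABEL["[M-H]1-"],),
        food_sources="beans;peanuts;peas;soy",
        source_groups=("legumes",),
        msi_evidence=("standard_mass_match", "standard_rt_match", "msn_match"),
        appearance_lag_h=0.5,
        decay_halflife_h=3.0,
        spike_magnitude=fold,
    )


def _legume_scenario_menus() -> dict[int, "design.MenuPlan"]:
    """Three study-2 plans with each legume food in the evening meal.

    Mirrors the discovery schematic, where the legume exposure was a dinner
    (peas in the evening meal) contrasted against the same day's first
    morning void.  Non-dinner items carry no marker in the scenario panel.
    """
    from .design import FoodItem, MenuPlan

    def plan(pid: int, dinner: list[FoodItem]) -> MenuPlan:
        return MenuPlan(
            plan_id=pid,
            meals={
                "breakfast": (FoodItem("porridge oats", "wholegrain"),),
                "lunch": (FoodItem("cheese sandwich", "dairy"),),
                "snack": (FoodItem("apple", "fruit"),),
                "dinner": tuple(dinner),
            },
        )

    return {
        4: plan(4, [FoodItem("baked beans", "legumes"),
                    FoodItem("toasted wholemeal bread", "toasted_grain")]),
        5: plan(5, [FoodItem("garden peas", "legumes"),
                    FoodItem("peanuts", "legumes"),
                    FoodItem("grilled white fish", "fish")]),
        6: plan(6, [FoodItem("tofu stir fry", "legumes"),
                    FoodItem("white rice", "grain")]),
    }


def legume_recovery_scenario(
    seed: int,
    n_participants: int = 10,
    fold: float = 5.0,
    n_background: int = 2000,
    noise_cv: float = 0.2,
    dilution_cv: float = 0.3,
) -> tuple[FingerprintMatrix, "pd.DataFrame", float]:
    """The packaged marker-recovery scenario.

    A study-2 simulation (three menu plans over three weeks) in which a
    single shared legume marker is spiked on top of ``n_background``
    uninformative bins; each plan carries one or two legume foods in its
    evening meal.  Ten participants over three weeks give each legume food
    30 exposed bed-time urines against 30 same-day first morning voids.
    Returns ``(matrix, truth, marker_bin_mz)``.
    """
    from .design import randomize_study2

    panel = [shared_legume_marker(fold)]
    base = STUDY_PROFILES["study2"]
    profile = CohortProfile(
        n=n_participants, female_fraction=base.female_fraction, age=base.age,
        weight_kg=base.weight_kg, height_cm=base.height_cm, waist_cm=base.waist_cm,
    )
    cohort = generate_cohort(profile, seed=seed)
    assignments = randomize_study2(cohort.ids, seed=seed)
    exposures = simulate_exposures(
        cohort, assignments, _legume_scenario_menus(), seed=seed
    )
    matrix, truth = simulate_fingerprints(
        exposures, panel, assignments,
        background=BackgroundSpec(n_features=n_background),
        noise_cv=noise_cv, dilution_cv=dilution_cv, seed=seed,
    )
    marker_mz = marker_bin_map(panel)["pyrogallol sulfate"][0]
    return matrix, truth, marker_mz


def two_class_spike_scenario(
    n_per_class: int = 30,
    n_features: int = 2000,
    fold: float = 5.0,
    noise_cv: float = 0.2,
    dilution_cv: float = 0.3,
    spike_index: int = 0,
    background: BackgroundSpec | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Minimal two-class fingerprint: one spiked feature among nulls.

    Baseline and exposed samples share per-sample log-normal baselines,
    dilution variation and multiplicative noise; in exposed samples the
    feature at ``spike_index`` is multiplied by ``fold``.  Returns
    ``(X, labels, spike_index)`` with labels "baseline"/"exposed" — the
    distilled form of a post-meal contrast, used for recovery and null
    calibration experiments (``fold=1`` gives pure null data).
    """
    if n_per_class < 1 or n_features < 1:
        raise ValueError("n_per_class and n_features must be >= 1")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    background = background or BackgroundSpec()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 40]))
    n = 2 * n_per_class
    feat_median = np.exp(
        rng.normal(background.log_mean, background.log_sigma_feature, n_features)
    )
    X = feat_median * np.exp(
        rng.normal(0.0, background.log_sigma_participant, size=(n, n_features))
    )
    labels = np.array(["baseline"] * n_per_class + ["exposed"] * n_per_class)
    X[labels == "exposed", spike_index] *= fold
    if dilution_cv > 0:
        X *= np.exp(rng.normal(0.0, _lognorm_sigma(dilution_cv), size=(n, 1)))
    if noise_cv > 0:
        X *= np.exp(rng.normal(0.0, _lognorm_sigma(noise_cv), size=(n, n_features)))
    return np.log1p(X), labels, spike_index
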