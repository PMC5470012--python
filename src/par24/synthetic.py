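"""Synthetic paired diary + accelerometer cohorts with known ground truth.

Each simulated participant gets (1) a true minute-by-minute intensity
schedule built from alternating activity bouts on a 5-min grid; (2) an
accelerometer count stream whose per-minute counts are drawn from
class-conditional distributions truncated to that class's cpm interval, so
the criterion pipeline recovers the truth by construction; and (3) one or
two recall diaries derived from the truth and then distorted with the
misreporting structure seen in recall instruments: a fraction of true light
activity re-reported as moderate-to-vigorous (over-reporting of exercise),
a further fraction under-reported as sedentary, and optional random
class confusion near intensity boundaries (the replicate-to-replicate
noise knob, off by default).

Default schedule targets sit near the criterion medians of a free-living
adult day (roughly 1025 / 385 / 30 min sedentary / light / MVPA after
renormalisation to 1440), and the default misreport factors move about
90 min of light activity into MVPA and about 30 min into sedentary time in
expectation, i.e. a -120 min light / +90 min MVPA reporting bias.

Reproducibility: one master seed; participant *i* draws from the
substream ``SeedSequence(seed, spawn_key=(i,))``, so a cohort can be
extended without changing existing participants.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .accelerometry import (
    MVPA_CPM_MIN,
    SEDENTARY_CPM_MAX,
    CountSeries,
    write_counts_csv,
)
from .catalog import Catalog, demo_catalog, met_for_entry
from .diary import (
    MINUTES_PER_DAY,
    ActivityEntry,
    DiaryDay,
    IntensityClass,
    INTENSITY_CLASSES,
    classify_met,
    write_diary_csv,
)
from .errors import ValidationError

GRID_MIN = 5
GRID_UNITS = MINUTES_PER_DAY // GRID_MIN  # 288 five-minute slots


@dataclass(frozen=True)
class ScheduleModel:
    """Daily minute targets per intensity class (renormalised to 1440)."""

    mean_minutes: Mapping[str, float] = field(
        default_factory=lambda: {"sedentary": 1025.0, "light": 385.0, "mvpa": 30.0}
    )
    sd_minutes: Mapping[str, float] = field(
        default_factory=lambda: {"sedentary": 110.0, "light": 100.0, "mvpa": 25.0}
    )
    typical_bout_min: Mapping[str, float] = field(
        default_factory=lambda: {"sedentary": 60.0, "light": 30.0, "mvpa": 15.0}
    )

    def __post_init__(self) -> None:
        for mapping in (self.mean_minutes, self.sd_minutes, self.typical_bout_min):
            if set(mapping) != set(INTENSITY_CLASSES):
                raise ValidationError("schedule model needs all three intensity classes")
            if any(v < 0 for v in mapping.values()):
                raise ValidationError("schedule parameters must be nonnegative")
        if sum(self.mean_minutes.values()) <= 0:
            raise ValidationError("schedule targets must not all be zero")


@dataclass(frozen=True)
class CountsModel:
    """Class-conditional counts-per-minute emission.

    Values are truncated to the class's cpm interval ([0, 100), [100, 1952),
    [1952, max]), so true classes stay identifiable by construction; a zero
    SD gives degenerate (constant, class-typical) emission.
    """

    mean_cpm: Mapping[str, float] = field(
        default_factory=lambda: {"sedentary": 30.0, "light": 650.0, "mvpa": 3000.0}
    )
    sd_cpm: Mapping[str, float] = field(
        default_factory=lambda: {"sedentary": 30.0, "light": 400.0, "mvpa": 800.0}
    )
    max_mvpa_cpm: float = 15000.0
    epoch_seconds: int = 60

    def class_interval(self, intensity: IntensityClass) -> tuple[float, float]:
        return {
            "sedentary": (0.0, SEDENTARY_CPM_MAX - 1.0),
            "light": (float(SEDENTARY_CPM_MAX), MVPA_CPM_MIN - 1.0),
            "mvpa": (float(MVPA_CPM_MIN), self.max_mvpa_cpm),
        }[intensity]


@dataclass(frozen=True)
class MisreportModel:
    """Diary distortion applied on top of the true schedule.

    ``mvpa_overreport_factor`` is the probability that a true light bout is
    re-reported as an MVPA-coded activity; ``light_underreport_factor`` the
    probability that it is reported as sedentary instead.  The defaults
    (0.234, 0.078) move ~90 and ~30 expected minutes out of the default
    385-min light schedule.  ``boundary_confusion_prob`` flips a reported
    bout to an adjacent intensity class — replicate-administration noise,
    off by default so the expected validity transfers are exactly the
    configured ones.
    """

    mvpa_overreport_factor: float = 90.0 / 385.0
    light_underreport_factor: float = 30.0 / 385.0
    granularity_min: int = GRID_MIN
    boundary_confusion_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mvpa_overreport_factor", "light_underreport_factor", "boundary_confusion_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.mvpa_overreport_factor + self.light_underreport_factor > 1.0:
            raise ValidationError("light-transfer probabilities must sum to <= 1")
        if self.granularity_min != GRID_MIN:
            raise ValidationError(f"granularity_min must be {GRID_MIN}")


@dataclass(frozen=True)
class CovariateModel:
    """Cohort covariates: adult ages, balanced gender, population-like BMI."""

    age_min: int = 22
    age_max: int = 70
    p_female: float = 0.5
    bmi_mean: float = 26.1
    bmi_sd: float = 4.4
    bmi_min: float = 18.1
    bmi_max: float = 41.2


@dataclass(frozen=True)
class WearModel:
    """Non-wear bout injection (off by default: day-and-night wear protocol)."""

    nonwear_bout_prob: float = 0.0
    bout_min_minutes: int = 30
    bout_max_minutes: int = 120

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonwear_bout_prob <= 1.0:
            raise ValidationError("nonwear_bout_prob must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 67
    seed: int = 0
    schedule: ScheduleModel = field(default_factory=ScheduleModel)
    counts: CountsModel = field(default_factory=CountsModel)
    misreport: MisreportModel = field(default_factory=MisreportModel)
    covariates: CovariateModel = field(default_factory=CovariateModel)
    wear: WearModel = field(default_factory=WearModel)

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValidationError("n_participants must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(
            n_participants=raw.get("n_participants", 67),
            seed=raw.get("seed", 0),
            schedule=ScheduleModel(**raw.get("schedule", {})),
            counts=CountsModel(**raw.get("counts", {})),
            misreport=MisreportModel(**raw.get("misreport", {})),
            covariates=CovariateModel(**raw.get("covariates", {})),
            wear=WearModel(**raw.get("wear", {})),
        )


@dataclass(frozen=True)
class Covariates:
    age: int
    gender: str
    bmi: float


@dataclass(frozen=True)
class SimulatedParticipant:
    participant_id: str
    truth: np.ndarray  # length-1440 array of class labels
    diary: DiaryDay  # first administration
    diary_replicate: DiaryDay  # second administration, same truth
    counts: CountSeries
    covariates: Covariates

    def truth_minutes(self, intensity: IntensityClass) -> int:
        return int(np.count_nonzero(self.truth == intensity))


@dataclass(frozen=True)
class SimulatedCohort:
    config: SimulationConfig
    participants: tuple[SimulatedParticipant, ...]
    diaries_csv: Path | None = None
    counts_csv: Path | None = None
    covariates_csv: Path | None = None
    truth_csv: Path | None = None


@lru_cache(maxsize=1)
def _activity_pools() -> dict[IntensityClass, tuple[tuple[str, str | None, float | None], ...]]:
    """Per-class pools of (code, effort, standing_fraction) parameterisations
    of the bundled catalog, keyed by the class their MET falls in."""
    catalog = demo_catalog()
    pools: dict[IntensityClass, list[tuple[str, str | None, float | None]]] = {
        c: [] for c in INTENSITY_CLASSES
    }
    for code, definition in catalog.definitions.items():
        if definition.effort_ranked:
            options = [(code, effort, None) for effort in ("light", "medium", "hard")]
        elif definition.posture_adjustable:
            options = [(code, None, f) for f in (0.0, 0.25, 0.5, 0.75, 1.0)]
        else:
            options = [(code, None, None)]
        for code_, effort, standing in options:
            met = met_for_entry(definition, effort, standing)
            pools[classify_met(met)].append((code_, effort, standing))
    return {c: tuple(v) for c, v in pools.items()}


def _draw_schedule_bouts(
    model: ScheduleModel, rng: np.random.Generator
) -> list[tuple[IntensityClass, int]]:
    """Alternating (class, minutes) bouts on the 5-min grid summing to 1440."""
    targets = np.array(
        [max(0.0, rng.normal(model.mean_minutes[c], model.sd_minutes[c])) for c in INTENSITY_CLASSES]
    )
    if targets.sum() == 0:
        targets = np.array([float(model.mean_minutes[c]) for c in INTENSITY_CLASSES])
    targets *= MINUTES_PER_DAY / targets.sum()
    # largest-remainder rounding to whole 5-min units, preserving the total
    units = targets / GRID_MIN
    floor = np.floor(units).astype(int)
    remainder = GRID_UNITS - floor.sum()
    order = np.argsort(-(units - floor))
    floor[order[:remainder]] += 1
    bouts: list[tuple[IntensityClass, int]] = []
    for intensity, n_units in zip(INTENSITY_CLASSES, floor):
        if n_units == 0:
            continue
        typical_units = max(1.0, model.typical_bout_min[intensity] / GRID_MIN)
        n_bouts = int(min(n_units, max(1, round(n_units / typical_units))))
        extra = rng.multinomial(n_units - n_bouts, np.full(n_bouts, 1.0 / n_bouts))
        bouts.extend(
            (intensity, int((1 + e) * GRID_MIN)) for e in extra
        )
    rng.shuffle(bouts)
    return bouts


def _emit_counts(
    truth: np.ndarray, model: CountsModel, rng: np.random.Generator
) -> np.ndarray:
    """Per-minute integer counts from the class-conditional emission model."""
    cpm = np.zeros(MINUTES_PER_DAY)
    for intensity in INTENSITY_CLASSES:
        mask = truth == intensity
        n = int(mask.sum())
        if n == 0:
            continue
        lo, hi = model.class_interval(intensity)
        mean = float(model.mean_cpm[intensity])
        sd = float(model.sd_cpm[intensity])
        if sd == 0:
            values = np.full(n, np.clip(mean, lo, hi))
        else:
            a, b = (lo - mean) / sd, (hi - mean) / sd
            from scipy.stats import truncnorm

            values = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        cpm[mask] = np.clip(np.rint(values), lo, hi)
    return cpm.astype(np.int64)


def _report_class(
    true_class: IntensityClass, misreport: MisreportModel, rng: np.random.Generator
) -> IntensityClass:
    """Reported class of one bout after misreport transfers and confusion."""
    reported = true_class
    if true_class == "light":
        u = rng.random()
        if u < misreport.mvpa_overreport_factor:
            reported = "mvpa"
        elif u < misreport.mvpa_overreport_factor + misreport.light_underreport_factor:
            reported = "sedentary"
    if misreport.boundary_confusion_prob and rng.random() < misreport.boundary_confusion_prob:
        if reported == "sedentary":
            reported = "light"
        elif reported == "mvpa":
            reported = "light"
        else:
            reported = "sedentary" if rng.random() < 0.5 else "mvpa"
    return reported


def _build_diary(
    participant_id: str,
    bouts: Sequence[tuple[IntensityClass, int]],
    misreport: MisreportModel,
    recall_index: int,
    rng: np.random.Generator,
) -> DiaryDay:
    pools = _activity_pools()
    entries = []
    minute = 0
    for true_class, duration in bouts:
        reported = _report_class(true_class, misreport, rng)
        pool = pools[reported]
        code, effort, standing = pool[rng.integers(len(pool))]
        entries.append(
            ActivityEntry(
                code=code,
                start_min=minute,
                end_min=minute + duration,
                effort=effort,
                standing_fraction=standing,
            )
        )
        minute += duration
    return DiaryDay(
        participant_id=participant_id, entries=tuple(entries), recall_index=recall_index
    )


def _expand_epochs(
    cpm: np.ndarray, epoch_seconds: int, rng: np.random.Generator
) -> np.ndarray:
    """Split per-minute counts into sub-minute epochs (count-conserving)."""
    if epoch_seconds == 60:
        return cpm
    per_minute = 60 // epoch_seconds
    split = np.vstack(
        [rng.multinomial(int(c), np.full(per_minute, 1.0 / per_minute)) for c in cpm]
    )
    return split.reshape(-1)


def participant_rng(config: SimulationConfig, participant_index: int) -> np.random.Generator:
    """Per-participant substream of the master seed (stable under cohort growth)."""
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(participant_index,))
    )


def simulate_participant(
    config: SimulationConfig, participant_index: int
) -> SimulatedParticipant:
    """Draw one participant: truth schedule, counts, two recall diaries, covariates."""
    rng = participant_rng(config, participant_index)
    participant_id = f"P{participant_index + 1:03d}"
    bouts = _draw_schedule_bouts(config.schedule, rng)
    truth = np.concatenate(
        [np.full(duration, intensity, dtype=object) for intensity, duration in bouts]
    )
    cpm = _emit_counts(truth, config.counts, rng)
    epoch_counts = _expand_epochs(cpm, config.counts.epoch_seconds, rng)
    wear = np.ones(epoch_counts.size, dtype=bool)
    if config.wear.nonwear_bout_prob and rng.random() < config.wear.nonwear_bout_prob:
        length_min = int(
            rng.integers(config.wear.bout_min_minutes, config.wear.bout_max_minutes + 1)
        )
        start_min = int(rng.integers(0, MINUTES_PER_DAY - length_min + 1))
        per_minute = 60 // config.counts.epoch_seconds
        wear[start_min * per_minute : (start_min + length_min) * per_minute] = False
    counts = CountSeries(
        participant_id=participant_id,
        epoch_seconds=config.counts.epoch_seconds,
        counts=epoch_counts,
        wear=wear,
        day_start_index=0,
    )
    diary = _build_diary(participant_id, bouts, config.misreport, 1, rng)
    replicate = _build_diary(participant_id, bouts, config.misreport, 2, rng)
    age = int(rng.integers(config.covariates.age_min, config.covariates.age_max + 1))
    gender = "female" if rng.random() < config.covariates.p_female else "male"
    bmi = float(
        np.clip(
            rng.normal(config.covariates.bmi_mean, config.covariates.bmi_sd),
            config.covariates.bmi_min,
            config.covariates.bmi_max,
        )
    )
    return SimulatedParticipant(
        participant_id=participant_id,
        truth=truth,
        diary=diary,
        diary_replicate=replicate,
        counts=counts,
        covariates=Covariates(age=age, gender=gender, bmi=round(bmi, 1)),
    )


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulatedCohort:
    """Draw ``config.n_participants`` independent participants.

    With ``out_dir`` given, writes ``diaries.csv`` (both recalls),
    ``counts.csv``, ``covariates.csv`` and ``truth.csv`` in the dialects the
    diary/accelerometry readers accept.
    """
    participants = tuple(
        simulate_participant(config, i) for i in range(config.n_participants)
    )
    if out_dir is None:
        return SimulatedCohort(config=config, participants=participants)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    diaries_csv = out_dir / "diaries.csv"
    counts_csv = out_dir / "counts.csv"
    covariates_csv = out_dir / "covariates.csv"
    truth_csv = out_dir / "truth.csv"
    write_diary_csv(
        [d for p in participants for d in (p.diary, p.diary_replicate)], diaries_csv
    )
    write_counts_csv({p.participant_id: p.counts for p in participants}, counts_csv)
    with covariates_csv.open("w", encoding="utf-8", newline="") as handle:
        handle.write("participant_id,age_years,gender,bmi\n")
        for p in participants:
            c = p.covariates
            handle.write(f"{p.participant_id},{c.age},{c.gender},{c.bmi}\n")
    with truth_csv.open("w", encoding="utf-8", newline="") as handle:
        handle.write("participant_id,sedentary_min,light_min,mvpa_min\n")
        for p in participants:
            handle.write(
                f"{p.participant_id},{p.truth_minutes('sedentary')},"
                f"{p.truth_minutes('light')},{p.truth_minutes('mvpa')}\n"
            )
    return SimulatedCohort(
        config=config,
        participants=participants,
        diaries_csv=diaries_csv,
        counts_csv=counts_csv,
        covariates_csv=covariates_csv,
        truth_csv=truth_csv,
    )
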