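"""24-hour activity diary: representation, validation and MET scoring.

A diary day covers midnight to midnight on a 1-minute grid with half-open
bout intervals ``[start_min, end_min)`` in 0-based minutes since midnight.
Bouts are entered in multiples of 5 minutes (minimal bout 5 min) and up to
two activities may be reported for the same time slot (a main activity plus
one performed in parallel).  Every minute of a valid day is covered by one
or two entries, for a total of 1440 logged minutes.

Scoring assigns each minute a MET value via the activity catalog and
classifies it as sedentary (MET <= 1.5), light (1.5 < MET < 3.0) or
moderate-to-vigorous (MET >= 3.0).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .catalog import Catalog, met_for_entry
from .errors import ContractError, FormatError, ValidationError

MINUTES_PER_DAY = 1440
BOUT_GRANULARITY_MIN = 5

#: Intensity boundaries on the MET scale.  A minute at exactly 1.5 MET counts
#: as sedentary; a minute at exactly 3.0 MET counts as moderate-to-vigorous.
SEDENTARY_MET_MAX = 1.5
MVPA_MET_MIN = 3.0

IntensityClass = Literal["sedentary", "light", "mvpa"]
INTENSITY_CLASSES: tuple[IntensityClass, ...] = ("sedentary", "light", "mvpa")

DIARY_COLUMNS = (
    "participant_id",
    "recall_index",
    "code",
    "start_min",
    "end_min",
    "effort",
    "standing_pct",
)


@dataclass(frozen=True)
class ActivityEntry:
    """One timed diary entry over ``[start_min, end_min)``."""

    code: str
    start_min: int
    end_min: int
    effort: str | None = None
    standing_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start_min < self.end_min <= MINUTES_PER_DAY:
            raise ValidationError(
                f"{self.code}: interval [{self.start_min}, {self.end_min}) is not a "
                f"valid sub-interval of [0, {MINUTES_PER_DAY})"
            )

    @property
    def duration_min(self) -> int:
        return self.end_min - self.start_min


@dataclass(frozen=True)
class DiaryDay:
    """A participant's ordered 24-h set of timed activity entries.

    ``recall_index`` distinguishes the first administration (1) from the
    replicate (2) used in test-retest reliability analyses.
    """

    participant_id: str
    entries: tuple[ActivityEntry, ...]
    recall_index: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if self.recall_index not in (1, 2):
            raise ValidationError(f"recall_index must be 1 or 2, got {self.recall_index}")


@dataclass(frozen=True)
class Violation:
    """One diary defect found by :func:`validate_diary` (data, not an exception)."""

    kind: Literal["gap", "overlap", "granularity", "unknown_code", "parameter"]
    start_min: int
    end_min: int
    message: str


@dataclass(frozen=True)
class MinuteMETProfile:
    """1440 per-minute MET values for one diary day."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (MINUTES_PER_DAY,):
            raise ValidationError(
                f"profile must have exactly {MINUTES_PER_DAY} values, got {values.shape}"
            )
        if not np.all(values > 0):
            raise ValidationError("all per-minute MET values must be > 0")


@dataclass(frozen=True)
class IntensitySummary:
    """Minutes per intensity class plus average MET for one participant-day.

    ``avg_met`` is None for accelerometer summaries: counts are never
    converted to MET.  ``included_min`` is 1440 for diaries and the number of
    wear minutes for accelerometer days.
    """

    sedentary_min: int
    light_min: int
    mvpa_min: int
    included_min: int
    avg_met: float | None = None

    def __post_init__(self) -> None:
        total = self.sedentary_min + self.light_min + self.mvpa_min
        if total != self.included_min:
            raise ValidationError(
                f"class minutes sum to {total}, expected included_min={self.included_min}"
            )
        if self.avg_met is not None and not self.avg_met > 0:
            raise ValidationError("avg_met must be > 0 when present")

    def minutes(self, intensity: IntensityClass) -> int:
        return {
            "sedentary": self.sedentary_min,
            "light": self.light_min,
            "mvpa": self.mvpa_min,
        }[intensity]


def classify_met(met: float) -> IntensityClass:
    """Intensity class of a MET value: <=1.5 sedentary, <3.0 light, else MVPA."""
    if not met > 0:
        raise ValidationError(f"MET must be > 0, got {met}")
    if met <= SEDENTARY_MET_MAX:
        return "sedentary"
    if met < MVPA_MET_MIN:
        return "light"
    return "mvpa"


def classify_met_array(values: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_met`; returns an array of class labels."""
    values = np.asarray(values, dtype=float)
    if not np.all(values > 0):
        raise ValidationError("MET values must be > 0")
    out = np.full(values.shape, "light", dtype=object)
    out[values <= SEDENTARY_MET_MAX] = "sedentary"
    out[values >= MVPA_MET_MIN] = "mvpa"
    return out


def validate_diary(day: DiaryDay, catalog: Catalog) -> list[Violation]:
    """Check a diary against the full-coverage and granularity rules.

    Returns an empty list iff the day is scoreable: every minute covered by
    1–2 entries, all bouts on the 5-min grid, all codes known to ``catalog``
    and parameterised consistently with their scoring mode.
    """
    violations: list[Violation] = []
    coverage = np.zeros(MINUTES_PER_DAY, dtype=int)
    for entry in day.entries:
        coverage[entry.start_min : entry.end_min] += 1
        if (
            entry.start_min % BOUT_GRANULARITY_MIN
            or entry.end_min % BOUT_GRANULARITY_MIN
            or entry.duration_min < BOUT_GRANULARITY_MIN
        ):
            violations.append(
                Violation(
                    "granularity",
                    entry.start_min,
                    entry.end_min,
                    f"{entry.code}: bouts must be >= {BOUT_GRANULARITY_MIN} min on a "
                    f"{BOUT_GRANULARITY_MIN}-min grid",
                )
            )
        if entry.code not in catalog:
            violations.append(
                Violation(
                    "unknown_code",
                    entry.start_min,
                    entry.end_min,
                    f"unknown activity code {entry.code!r}",
                )
            )
            continue
        definition = catalog[entry.code]
        if definition.effort_ranked != (entry.effort is not None):
            expected = "requires" if definition.effort_ranked else "does not take"
            violations.append(
                Violation(
                    "parameter",
                    entry.start_min,
                    entry.end_min,
                    f"{entry.code} {expected} an effort level",
                )
            )
        if definition.posture_adjustable != (entry.standing_fraction is not None):
            expected = "requires" if definition.posture_adjustable else "does not take"
            violations.append(
                Violation(
                    "parameter",
                    entry.start_min,
                    entry.end_min,
                    f"{entry.code} {expected} a standing fraction",
                )
            )
        elif entry.standing_fraction is not None and not (
            0.0 <= entry.standing_fraction <= 1.0
        ):
            violations.append(
                Violation(
                    "parameter",
                    entry.start_min,
                    entry.end_min,
                    f"{entry.code}: standing_fraction {entry.standing_fraction} "
                    "outside [0, 1]",
                )
            )
    for kind, mask in (("gap", coverage == 0), ("overlap", coverage > 2)):
        violations.extend(
            Violation(
                kind,
                start,
                end,
                f"minutes [{start}, {end}) covered by "
                f"{'no entry' if kind == 'gap' else 'more than 2 entries'}",
            )
            for start, end in _runs(mask)
        )
    return violations


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean array."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def minute_met_profile(
    day: DiaryDay,
    catalog: Catalog,
    overlap_rule: Literal["max", "mean"] = "max",
) -> MinuteMETProfile:
    """Score a valid diary into 1440 per-minute MET values.

    Where two entries cover the same minute their METs are combined by
    ``overlap_rule``: ``"max"`` (default — the dominant activity determines
    the minute's intensity) or ``"mean"``.
    """
    if overlap_rule not in ("max", "mean"):
        raise ValidationError(f"unknown overlap_rule {overlap_rule!r}")
    violations = validate_diary(day, catalog)
    if violations:
        raise ContractError(
            f"diary for {day.participant_id} has {len(violations)} violation(s); "
            "run validate_diary and fix them before scoring"
        )
    acc = np.zeros(MINUTES_PER_DAY)
    count = np.zeros(MINUTES_PER_DAY, dtype=int)
    for entry in day.entries:
        met = met_for_entry(catalog[entry.code], entry.effort, entry.standing_fraction)
        window = slice(entry.start_min, entry.end_min)
        if overlap_rule == "max":
            acc[window] = np.maximum(acc[window], met)
        else:
            acc[window] += met
        count[window] += 1
    if overlap_rule == "mean":
        acc /= count
    return MinuteMETProfile(acc)


def diary_summary(profile: MinuteMETProfile) -> IntensitySummary:
    """Total minutes per intensity class and 24-h average MET."""
    values = profile.values
    sedentary = int(np.count_nonzero(values <= SEDENTARY_MET_MAX))
    mvpa = int(np.count_nonzero(values >= MVPA_MET_MIN))
    light = MINUTES_PER_DAY - sedentary - mvpa
    return IntensitySummary(
        sedentary_min=sedentary,
        light_min=light,
        mvpa_min=mvpa,
        included_min=MINUTES_PER_DAY,
        avg_met=float(values.mean()),
    )


def score_diary(
    day: DiaryDay, catalog: Catalog, overlap_rule: Literal["max", "mean"] = "max"
) -> IntensitySummary:
    """Convenience: :func:`minute_met_profile` then :func:`diary_summary`."""
    return diary_summary(minute_met_profile(day, catalog, overlap_rule))


def read_diary_csv(path: str | Path) -> list[DiaryDay]:
    """Read diary days from CSV.

    Expected header: ``participant_id,recall_index,code,start_min,end_min,
    effort,standing_pct`` with one row per entry; ``standing_pct`` is an
    integer 0–100 and empty cells mean "absent".  Rows are grouped into one
    :class:`DiaryDay` per (participant, recall).
    """
    path = Path(path)
    grouped: dict[tuple[str, int], list[ActivityEntry]] = {}
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or tuple(reader.fieldnames) != DIARY_COLUMNS:
            raise FormatError(
                f"{path}: header must be {','.join(DIARY_COLUMNS)}, got {reader.fieldnames}"
            )
        for row_number, row in enumerate(reader, start=2):
            try:
                participant = row["participant_id"].strip()
                recall = int(row["recall_index"])
                standing_pct = row["standing_pct"].strip()
                entry = ActivityEntry(
                    code=row["code"].strip(),
                    start_min=int(row["start_min"]),
                    end_min=int(row["end_min"]),
                    effort=row["effort"].strip() or None,
                    standing_fraction=float(standing_pct) / 100.0 if standing_pct else None,
                )
            except (KeyError, ValueError, AttributeError):
                raise FormatError(f"{path}: row {row_number}: malformed diary row") from None
            except ValidationError as err:
                raise FormatError(f"{path}: row {row_number}: {err}") from None
            grouped.setdefault((participant, recall), []).append(entry)
    return [
        DiaryDay(participant_id=participant, entries=tuple(entries), recall_index=recall)
        for (participant, recall), entries in grouped.items()
    ]


def write_diary_csv(days: Iterable[DiaryDay], path: str | Path) -> None:
    """Write diary days in the CSV dialect accepted by :func:`read_diary_csv`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(DIARY_COLUMNS)
        for day in days:
            for entry in day.entries:
                writer.writerow(
                    [
                        day.participant_id,
                        day.recall_index,
                        entry.code,
                        entry.start_min,
                        entry.end_min,
                        entry.effort or "",
                        ""
                        if entry.standing_fraction is None
                        else round(entry.standing_fraction * 100),
                    ]
                )
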