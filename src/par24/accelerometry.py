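"""Accelerometer criterion pipeline: counts per minute and cut-point classes.

The criterion device (a hip-worn tri-axial accelerometer) integrates raw
acceleration into activity counts per epoch; this module reduces epoch
counts to counts per minute (cpm) over the recall day, applies the
participant-reported wear mask, and classifies each wear minute by the
Freedson/Matthews vertical-axis cut-points: sedentary below 100 cpm, light
from 100 to 1951 cpm, moderate-to-vigorous at 1952 cpm and above.  Days
with less than 12 h (720 min, 50%) of wear time are excluded.

Counts are carried in a plain-text CSV (one counts column, interpreted as
vertical-axis counts); binary device formats are out of scope.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .diary import MINUTES_PER_DAY, IntensityClass, IntensitySummary
from .errors import ContractError, FormatError, ValidationError

SECONDS_PER_DAY = 86_400
VALID_EPOCH_SECONDS = (1, 5, 10, 15, 30, 60)

#: Cut-points on the counts-per-minute scale: below ``SEDENTARY_CPM_MAX`` is
#: sedentary (Matthews), at or above ``MVPA_CPM_MIN`` is moderate-to-vigorous
#: (Freedson); light in between.
SEDENTARY_CPM_MAX = 100
MVPA_CPM_MIN = 1952

#: Minimum wear minutes for a recall day to enter analysis (12 h of 24).
MIN_WEAR_MINUTES = 720

COUNTS_COLUMNS = ("participant_id", "timestamp_iso8601", "epoch_seconds", "counts", "wear")


@dataclass(frozen=True)
class CountSeries:
    """Epoch-level counts with a wear mask for one participant.

    ``day_start_index`` points at the first epoch of the recall day; the
    series must contain the full 24-h window from there.
    """

    participant_id: str
    epoch_seconds: int
    counts: np.ndarray
    wear: np.ndarray
    day_start_index: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        wear = np.asarray(self.wear, dtype=bool)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "wear", wear)
        if self.epoch_seconds not in VALID_EPOCH_SECONDS:
            raise ValidationError(
                f"epoch_seconds must be one of {VALID_EPOCH_SECONDS}, "
                f"got {self.epoch_seconds}"
            )
        if counts.ndim != 1 or counts.shape != wear.shape:
            raise ValidationError("counts and wear must be 1-D and equal length")
        if np.any(counts < 0):
            raise ValidationError("counts must be nonnegative")
        day_epochs = SECONDS_PER_DAY // self.epoch_seconds
        if not 0 <= self.day_start_index <= counts.size - day_epochs:
            raise ValidationError(
                f"recall-day window [{self.day_start_index}, "
                f"{self.day_start_index + day_epochs}) outside series of "
                f"length {counts.size}"
            )

    @property
    def epochs_per_day(self) -> int:
        return SECONDS_PER_DAY // self.epoch_seconds


@dataclass(frozen=True)
class MinuteCounts:
    """1440 counts-per-minute values for the recall day; NaN marks non-wear."""

    cpm: np.ndarray

    def __post_init__(self) -> None:
        cpm = np.asarray(self.cpm, dtype=float)
        object.__setattr__(self, "cpm", cpm)
        if cpm.shape != (MINUTES_PER_DAY,):
            raise ValidationError(
                f"cpm must have exactly {MINUTES_PER_DAY} values, got {cpm.shape}"
            )
        present = cpm[~np.isnan(cpm)]
        if np.any(present < 0):
            raise ValidationError("present cpm values must be >= 0")

    @property
    def wear_minutes(self) -> int:
        return int(np.count_nonzero(~np.isnan(self.cpm)))


@dataclass(frozen=True)
class WearDecision:
    """Keep/exclude decision for one recall day with its wear-minute count."""

    keep: bool
    wear_minutes: int


def read_counts_csv(
    path: str | Path,
    participant_id: str | None = None,
    recall_date: str | None = None,
) -> CountSeries:
    """Read one participant's epoch counts from CSV.

    Expected header: ``participant_id,timestamp_iso8601,epoch_seconds,counts,
    wear`` with rows time-ordered and contiguous (no missing epochs, one
    constant epoch length).  ``recall_date`` (``YYYY-MM-DD``) selects the
    24-h window; without it the series must start at the recall day's first
    epoch.  If the file holds several participants, ``participant_id`` picks
    one.
    """
    series = read_counts_csv_cohort(path, recall_date=recall_date)
    if participant_id is None:
        if len(series) != 1:
            raise FormatError(
                f"{path}: file holds {len(series)} participants; pass participant_id"
            )
        return next(iter(series.values()))
    try:
        return series[participant_id]
    except KeyError:
        raise FormatError(f"{path}: no rows for participant {participant_id!r}") from None


def read_counts_csv_cohort(
    path: str | Path, recall_date: str | None = None
) -> dict[str, CountSeries]:
    """Read a cohort counts CSV into one :class:`CountSeries` per participant."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"participant_id": str})
    if tuple(frame.columns) != COUNTS_COLUMNS:
        raise FormatError(
            f"{path}: header must be {','.join(COUNTS_COLUMNS)}, "
            f"got {list(frame.columns)}"
        )
    out: dict[str, CountSeries] = {}
    for participant, rows in frame.groupby("participant_id", sort=False):
        epoch_values = rows["epoch_seconds"].unique()
        if len(epoch_values) != 1:
            raise FormatError(f"{path}: {participant}: mixed epoch lengths {epoch_values}")
        epoch_seconds = int(epoch_values[0])
        if epoch_seconds not in VALID_EPOCH_SECONDS:
            raise FormatError(f"{path}: {participant}: bad epoch length {epoch_seconds}")
        timestamps = pd.to_datetime(rows["timestamp_iso8601"], format="ISO8601")
        steps = timestamps.diff().dropna().dt.total_seconds()
        if np.any(steps != epoch_seconds):
            bad = int(np.argmax(steps.to_numpy() != epoch_seconds))
            raise FormatError(
                f"{path}: {participant}: epoch sequence gap after "
                f"{timestamps.iloc[bad].isoformat()}"
            )
        counts = rows["counts"].to_numpy()
        if np.any(counts < 0):
            raise FormatError(f"{path}: {participant}: negative counts")
        wear = rows["wear"].to_numpy()
        if not np.isin(wear, (0, 1)).all():
            raise FormatError(f"{path}: {participant}: wear must be 0 or 1")
        if recall_date is None:
            day_start_index = 0
        else:
            midnight = pd.Timestamp(recall_date)
            matches = np.flatnonzero(timestamps.to_numpy() == midnight.to_numpy())
            if matches.size == 0:
                raise FormatError(
                    f"{path}: {participant}: no epoch at midnight of {recall_date}"
                )
            day_start_index = int(matches[0])
        try:
            out[str(participant)] = CountSeries(
                participant_id=str(participant),
                epoch_seconds=epoch_seconds,
                counts=counts,
                wear=wear.astype(bool),
                day_start_index=day_start_index,
            )
        except ValidationError as err:
            raise FormatError(f"{path}: {participant}: {err}") from None
    return out


def write_counts_csv(
    series_by_participant: dict[str, CountSeries],
    path: str | Path,
    start_timestamp: str = "2011-07-12T00:00:00",
) -> None:
    """Write count series in the CSV dialect accepted by :func:`read_counts_csv`.

    Timestamps are synthesised from ``start_timestamp`` minus the recall-day
    offset, so the recall day starts exactly at ``start_timestamp``.
    """
    path = Path(path)
    origin = pd.Timestamp(start_timestamp)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(COUNTS_COLUMNS)
        for participant, series in series_by_participant.items():
            step = pd.Timedelta(seconds=series.epoch_seconds)
            first = origin - series.day_start_index * step
            for i, (count, worn) in enumerate(zip(series.counts, series.wear)):
                writer.writerow(
                    [
                        participant,
                        (first + i * step).isoformat(),
                        series.epoch_seconds,
                        int(count),
                        int(worn),
                    ]
                )


def to_minute_counts(series: CountSeries) -> MinuteCounts:
    """Reduce the recall-day epochs to counts per minute.

    cpm of minute *m* is the sum of its ``60/epoch_seconds`` epoch counts; a
    minute containing any non-wear epoch is wholly non-wear (NaN), avoiding
    partial-minute count inflation.
    """
    day_slice = slice(series.day_start_index, series.day_start_index + series.epochs_per_day)
    per_minute = 60 // series.epoch_seconds
    counts = series.counts[day_slice].reshape(MINUTES_PER_DAY, per_minute)
    wear = series.wear[day_slice].reshape(MINUTES_PER_DAY, per_minute)
    cpm = counts.sum(axis=1).astype(float)
    cpm[~wear.all(axis=1)] = np.nan
    return MinuteCounts(cpm)


def classify_cpm(cpm: float) -> IntensityClass:
    """Intensity class of a cpm value: <100 sedentary, <1952 light, else MVPA."""
    if cpm < 0:
        raise ValidationError(f"cpm must be >= 0, got {cpm}")
    if cpm < SEDENTARY_CPM_MAX:
        return "sedentary"
    if cpm < MVPA_CPM_MIN:
        return "light"
    return "mvpa"


def wear_time_filter(minutes: MinuteCounts) -> WearDecision:
    """Keep the day iff it has at least 12 h (720 min) of wear time."""
    wear = minutes.wear_minutes
    return WearDecision(keep=wear >= MIN_WEAR_MINUTES, wear_minutes=wear)


def accelerometer_summary(minutes: MinuteCounts) -> IntensitySummary:
    """Intensity minutes over wear minutes only; no count-to-MET conversion."""
    decision = wear_time_filter(minutes)
    if not decision.keep:
        raise ContractError(
            f"day excluded: {decision.wear_minutes} wear minutes "
            f"< {MIN_WEAR_MINUTES}; check wear_time_filter before summarising"
        )
    cpm = minutes.cpm[~np.isnan(minutes.cpm)]
    sedentary = int(np.count_nonzero(cpm < SEDENTARY_CPM_MAX))
    mvpa = int(np.count_nonzero(cpm >= MVPA_CPM_MIN))
    light = cpm.size - sedentary - mvpa
    return IntensitySummary(
        sedentary_min=sedentary,
        light_min=light,
        mvpa_min=mvpa,
        included_min=decision.wear_minutes,
        avg_met=None,
    )


def detect_nonwear_minutes(minutes: MinuteCounts, min_run: int = 60) -> np.ndarray:
    """Optional convenience detector: runs of >= ``min_run`` consecutive
    zero-cpm minutes are flagged as non-wear.

    The study design takes wear interruptions from participant reports (the
    ``wear`` input column); this detector is provided for data lacking such
    reports and is never applied implicitly.
    """
    zero = np.nan_to_num(minutes.cpm, nan=-1.0) == 0.0
    flagged = np.zeros(MINUTES_PER_DAY, dtype=bool)
    padded = np.concatenate(([False], zero, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start >= min_run:
            flagged[start:end] = True
    return flagged
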