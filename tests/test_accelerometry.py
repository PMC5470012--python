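"""Count ingestion, minute reduction, cut-point classes and wear filtering."""

import numpy as np
import pandas as pd
import pytest

from par24.accelerometry import (
    CountSeries,
    MinuteCounts,
    accelerometer_summary,
    classify_cpm,
    detect_nonwear_minutes,
    read_counts_csv,
    read_counts_csv_cohort,
    to_minute_counts,
    wear_time_filter,
    write_counts_csv,
)
from par24.errors import ContractError, FormatError, ValidationError


def counts_csv(tmp_path, counts, epoch_seconds=60, wear=None, drop_row=None,
               participant="P001"):
    n = len(counts)
    wear = [1] * n if wear is None else wear
    times = pd.date_range("2011-07-12", periods=n, freq=f"{epoch_seconds}s")
    lines = ["participant_id,timestamp_iso8601,epoch_seconds,counts,wear"]
    for i in range(n):
        if i == drop_row:
            continue
        lines.append(f"{participant},{times[i].isoformat()},{epoch_seconds},{counts[i]},{wear[i]}")
    path = tmp_path / "counts.csv"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


class TestReadCountsCsv:
    def test_full_day_of_one_second_epochs(self, tmp_path):
        path = counts_csv(tmp_path, [0] * 86400, epoch_seconds=1)
        series = read_counts_csv(path)
        assert series.counts.size == 86400
        assert series.epoch_seconds == 1

    def test_missing_epoch_row_is_a_gap(self, tmp_path):
        path = counts_csv(tmp_path, [0] * 1440, drop_row=100)
        with pytest.raises(FormatError, match="gap"):
            read_counts_csv(path)

    def test_negative_counts_rejected(self, tmp_path):
        counts = [0] * 1440
        counts[7] = -5
        path = counts_csv(tmp_path, counts)
        with pytest.raises(FormatError, match="negative"):
            read_counts_csv(path)

    def test_mixed_epoch_lengths_rejected(self, tmp_path):
        path = tmp_path / "counts.csv"
        path.write_text(
            "participant_id,timestamp_iso8601,epoch_seconds,counts,wear\n"
            "P001,2011-07-12T00:00:00,60,0,1\n"
            "P001,2011-07-12T00:01:00,30,0,1\n",
            encoding="utf-8",
        )
        with pytest.raises(FormatError, match="mixed"):
            read_counts_csv(path)

    def test_recall_date_selects_window(self, tmp_path):
        # one hour before midnight, then a full day
        times = pd.date_range("2011-07-11T23:00:00", periods=60 + 1440, freq="60s")
        lines = ["participant_id,timestamp_iso8601,epoch_seconds,counts,wear"]
        lines += [f"P001,{t.isoformat()},60,5,1" for t in times]
        path = tmp_path / "counts.csv"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        series = read_counts_csv(path, recall_date="2011-07-12")
        assert series.day_start_index == 60

    def test_round_trip_through_writer(self, tmp_path):
        rng = np.random.default_rng(0)
        original = CountSeries("P001", 60, rng.integers(0, 4000, 1440), np.ones(1440, bool))
        path = tmp_path / "counts.csv"
        write_counts_csv({"P001": original}, path)
        restored = read_counts_csv_cohort(path)["P001"]
        assert np.array_equal(restored.counts, original.counts)
        assert np.array_equal(restored.wear, original.wear)


class TestToMinuteCounts:
    def test_sums_epochs_within_the_minute(self):
        series = CountSeries("P", 1, np.full(86400, 2), np.ones(86400, bool))
        minutes = to_minute_counts(series)
        assert np.all(minutes.cpm == 120)

    def test_minute_with_any_nonwear_epoch_is_absent(self):
        wear = np.ones(86400, bool)
        wear[30] = False  # one second of non-wear in minute 0
        series = CountSeries("P", 1, np.full(86400, 2), wear)
        minutes = to_minute_counts(series)
        assert np.isnan(minutes.cpm[0])
        assert minutes.wear_minutes == 1439

    def test_sixty_second_epochs_pass_through(self):
        counts = np.arange(1440)
        series = CountSeries("P", 60, counts, np.ones(1440, bool))
        assert np.array_equal(to_minute_counts(series).cpm, counts)

    @pytest.mark.parametrize("epoch_seconds", [1, 5, 10, 15, 30, 60])
    def test_total_counts_conserved_over_wear_minutes(self, epoch_seconds):
        rng = np.random.default_rng(epoch_seconds)
        n = 86400 // epoch_seconds
        series = CountSeries("P", epoch_seconds, rng.integers(0, 100, n), np.ones(n, bool))
        minutes = to_minute_counts(series)
        assert minutes.cpm.sum() == series.counts.sum()


class TestClassifyCpm:
    @pytest.mark.parametrize(
        "cpm, expected", [(99, "sedentary"), (100, "light"), (1951, "light"), (1952, "mvpa"), (0, "sedentary")]
    )
    def test_boundaries(self, cpm, expected):
        assert classify_cpm(cpm) == expected

    def test_negative_cpm_rejected(self):
        with pytest.raises(ValidationError):
            classify_cpm(-1)

    def test_step_function_is_monotone_in_class_order(self):
        order = {"sedentary": 0, "light": 1, "mvpa": 2}
        classes = [order[classify_cpm(c)] for c in range(0, 4000, 7)]
        assert classes == sorted(classes)


class TestWearFilter:
    @pytest.mark.parametrize("wear_minutes, keep", [(719, False), (720, True), (1440, True)])
    def test_twelve_hour_rule(self, wear_minutes, keep):
        cpm = np.full(1440, np.nan)
        cpm[:wear_minutes] = 0.0
        decision = wear_time_filter(MinuteCounts(cpm))
        assert decision.keep is keep
        assert decision.wear_minutes == wear_minutes


class TestAccelerometerSummary:
    def make_minutes(self, nonwear_sedentary=0):
        cpm = np.concatenate([np.full(1000, 50.0), np.full(400, 500.0), np.full(40, 3000.0)])
        if nonwear_sedentary:
            cpm[:nonwear_sedentary] = np.nan
        return MinuteCounts(cpm)

    def test_all_zero_day_is_fully_sedentary(self):
        summary = accelerometer_summary(MinuteCounts(np.zeros(1440)))
        assert summary.sedentary_min == 1440
        assert summary.avg_met is None

    def test_hand_counted_three_class_day(self):
        summary = accelerometer_summary(self.make_minutes())
        assert (summary.sedentary_min, summary.light_min, summary.mvpa_min) == (1000, 400, 40)
        assert summary.included_min == 1440

    def test_nonwear_minutes_drop_from_totals(self):
        summary = accelerometer_summary(self.make_minutes(nonwear_sedentary=10))
        assert (summary.sedentary_min, summary.light_min, summary.mvpa_min) == (990, 400, 40)
        assert summary.included_min == 1430

    def test_excluded_day_is_a_contract_error(self):
        cpm = np.full(1440, np.nan)
        cpm[:700] = 0.0
        with pytest.raises(ContractError, match="700 wear minutes"):
            accelerometer_summary(MinuteCounts(cpm))

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_on_random_kept_days(self, seed):
        rng = np.random.default_rng(seed)
        cpm = rng.integers(0, 4000, 1440).astype(float)
        cpm[rng.random(1440) < 0.2] = np.nan
        minutes = MinuteCounts(cpm)
        summary = accelerometer_summary(minutes)
        total = summary.sedentary_min + summary.light_min + summary.mvpa_min
        assert total == summary.included_min == minutes.wear_minutes


class TestNonwearDetector:
    def test_long_zero_runs_flagged_short_ones_kept(self):
        cpm = np.full(1440, 200.0)
        cpm[100:180] = 0.0  # 80 zero minutes -> flagged
        cpm[500:530] = 0.0  # 30 zero minutes -> kept
        flagged = detect_nonwear_minutes(MinuteCounts(cpm))
        assert flagged[100:180].all()
        assert not flagged[500:530].any()
        assert flagged.sum() == 80
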