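"""End-to-end validity and reliability studies from input CSVs to reports.

The validity study compares each participant's scored recall diary against
the accelerometer criterion for the same 24-h period, per intensity class,
overall and within age / gender / BMI strata.  The reliability study
compares the two replicate recall administrations of the same day, per
intensity class plus the 24-h average MET.  Reports carry, per row, the
medians under both methods, the median of per-participant differences with
its percent version, the signed-rank p-value, the Spearman correlation and
the Bland-Altman bias with 95% limits of agreement; stratified blocks add
the between-strata rank-sum p-value.

Every input participant either contributes to the report or appears in the
exclusion log with a reason — no silent drops.  Reports contain no
timestamps, so identical inputs and configuration give byte-identical
output files.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .accelerometry import (
    read_counts_csv_cohort,
    to_minute_counts,
    accelerometer_summary,
    wear_time_filter,
)
from .catalog import Catalog, load_catalog
from .concordance import (
    AgreementResult,
    PairedObservation,
    PercentDenominator,
    method_agreement,
    stratified_comparison,
)
from .diary import DiaryDay, IntensitySummary, read_diary_csv, score_diary, validate_diary
from .errors import ContractError, PipelineError, ValidationError

STRATIFIERS = ("age", "gender", "bmi")

REPORT_COLUMNS = (
    "quantity",
    "stratum",
    "stratifier",
    "n",
    "median_a",
    "median_b",
    "median_diff",
    "median_pct_diff",
    "p_diff",
    "spearman_r",
    "bias",
    "loa_lower",
    "loa_upper",
    "between_strata_p",
)


@dataclass(frozen=True)
class StudyConfig:
    """Paths and scoring conventions for one study run."""

    catalog_path: str | Path
    diaries_path: str | Path
    counts_path: str | Path | None = None
    covariates_path: str | Path | None = None
    recall_date: str | None = None
    overlap_rule: Literal["max", "mean"] = "max"
    percent_denominator: PercentDenominator = "per_pair"
    out_dir: str | Path | None = None


@dataclass(frozen=True)
class ParticipantCovariates:
    age: float | None = None
    gender: str | None = None
    bmi: float | None = None


@dataclass
class StudyReport:
    """Agreement table plus the audit trail of one study run."""

    kind: Literal["validity", "reliability"]
    table: pd.DataFrame
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def n_analyzed(self) -> int:
        return int(self.table.loc[self.table["stratum"] == "all", "n"].iloc[0])


def load_covariates(path: str | Path) -> dict[str, ParticipantCovariates]:
    """Read the covariates CSV: ``participant_id,age_years,gender,bmi``."""
    path = Path(path)
    out: dict[str, ParticipantCovariates] = {}
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        expected = ("participant_id", "age_years", "gender", "bmi")
        if reader.fieldnames is None or tuple(reader.fieldnames) != expected:
            raise ValidationError(f"{path}: header must be {','.join(expected)}")
        for row in reader:
            age = row["age_years"].strip()
            bmi = row["bmi"].strip()
            out[row["participant_id"].strip()] = ParticipantCovariates(
                age=float(age) if age else None,
                gender=row["gender"].strip() or None,
                bmi=float(bmi) if bmi else None,
            )
    return out


def _result_row(result: AgreementResult, quantity: str, stratum: str,
                stratifier: str = "", between_p: float = float("nan")) -> dict:
    return {
        "quantity": quantity,
        "stratum": stratum,
        "stratifier": stratifier,
        "n": result.n,
        "median_a": result.median_a,
        "median_b": result.median_b,
        "median_diff": result.median_diff,
        "median_pct_diff": result.median_pct_diff,
        "p_diff": result.p_method_diff,
        "spearman_r": result.spearman_r,
        "bias": result.bias,
        "loa_lower": result.loa_lower,
        "loa_upper": result.loa_upper,
        "between_strata_p": between_p,
    }


def agreement_table(
    pairs_by_quantity: Mapping[str, Sequence[PairedObservation]],
    denominator: PercentDenominator = "per_pair",
) -> tuple[pd.DataFrame, list[str]]:
    """One report row per quantity x stratum (overall + 2 per stratifier).

    Stratified blocks that cannot be computed (an empty stratum, or a
    degenerate constant vector within a stratum) are skipped with a note;
    the overall row always computes or the error propagates.
    """
    rows: list[dict] = []
    notes: list[str] = []
    for quantity, pairs in pairs_by_quantity.items():
        rows.append(_result_row(method_agreement(pairs, label=quantity, denominator=denominator),
                                quantity, "all"))
        for stratifier in STRATIFIERS:
            try:
                comparison = stratified_comparison(pairs, stratifier, denominator=denominator)
            except (ValidationError, ContractError) as err:
                notes.append(f"{quantity}/{stratifier}: stratified block skipped ({err})")
                continue
            for stratum, result in comparison.strata.items():
                rows.append(
                    _result_row(result, quantity, stratum, stratifier,
                                comparison.between_strata_p)
                )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS), notes


def _score_diaries(
    diaries: Sequence[DiaryDay],
    catalog: Catalog,
    overlap_rule: Literal["max", "mean"],
    exclusions: list[tuple[str, str]],
) -> dict[tuple[str, int], IntensitySummary]:
    scored: dict[tuple[str, int], IntensitySummary] = {}
    for day in diaries:
        violations = validate_diary(day, catalog)
        if violations:
            exclusions.append(
                (
                    day.participant_id,
                    f"recall {day.recall_index} diary invalid "
                    f"({len(violations)} violation(s), first: {violations[0].message})",
                )
            )
            continue
        scored[(day.participant_id, day.recall_index)] = score_diary(
            day, catalog, overlap_rule
        )
    return scored


def run_validity_study(config: StudyConfig) -> StudyReport:
    """Diary (method A) vs accelerometer criterion (method B), recall day only."""
    if config.counts_path is None:
        raise PipelineError("validity study needs an accelerometer counts file")
    catalog = load_catalog(config.catalog_path)
    diaries = read_diary_csv(config.diaries_path)
    counts = read_counts_csv_cohort(config.counts_path, recall_date=config.recall_date)
    covariates = (
        load_covariates(config.covariates_path) if config.covariates_path else {}
    )
    exclusions: list[tuple[str, str]] = []
    scored = _score_diaries(diaries, catalog, config.overlap_rule, exclusions)
    first_recalls = {pid: s for (pid, recall), s in scored.items() if recall == 1}

    accel_summaries: dict[str, IntensitySummary] = {}
    for participant_id, series in counts.items():
        minutes = to_minute_counts(series)
        decision = wear_time_filter(minutes)
        if not decision.keep:
            exclusions.append(
                (
                    participant_id,
                    f"accelerometer day excluded: {decision.wear_minutes} wear minutes < 720",
                )
            )
            continue
        accel_summaries[participant_id] = accelerometer_summary(minutes)
        if participant_id not in first_recalls:
            exclusions.append((participant_id, "no valid recall-1 diary"))

    pairs_by_quantity: dict[str, list[PairedObservation]] = {
        q: [] for q in ("sedentary", "light", "mvpa")
    }
    n_matched = 0
    for participant_id, diary_summary_ in first_recalls.items():
        if participant_id not in accel_summaries:
            if participant_id not in {pid for pid, _ in exclusions}:
                exclusions.append((participant_id, "no accelerometer data"))
            continue
        n_matched += 1
        cov = covariates.get(participant_id, ParticipantCovariates())
        accel = accel_summaries[participant_id]
        for quantity in pairs_by_quantity:
            pairs_by_quantity[quantity].append(
                PairedObservation(
                    participant_id=participant_id,
                    value_a=diary_summary_.minutes(quantity),
                    value_b=accel.minutes(quantity),
                    age=cov.age,
                    gender=cov.gender,
                    bmi=cov.bmi,
                )
            )
    if n_matched == 0:
        raise PipelineError("no participant has both a valid diary and a kept accelerometer day")
    table, notes = agreement_table(pairs_by_quantity, config.percent_denominator)
    return StudyReport(kind="validity", table=table, exclusions=exclusions, notes=notes)


def run_reliability_study(config: StudyConfig) -> StudyReport:
    """First recall (method A) vs replicate recall (method B) of the same day."""
    catalog = load_catalog(config.catalog_path)
    diaries = read_diary_csv(config.diaries_path)
    covariates = (
        load_covariates(config.covariates_path) if config.covariates_path else {}
    )
    exclusions: list[tuple[str, str]] = []
    scored = _score_diaries(diaries, catalog, config.overlap_rule, exclusions)
    participants = sorted(
        {pid for pid, _ in scored}, key=lambda pid: [d.participant_id for d in diaries].index(pid)
    )
    pairs_by_quantity: dict[str, list[PairedObservation]] = {
        q: [] for q in ("sedentary", "light", "mvpa", "avg_met")
    }
    n_matched = 0
    for participant_id in participants:
        first = scored.get((participant_id, 1))
        second = scored.get((participant_id, 2))
        if first is None or second is None:
            missing = 1 if first is None else 2
            exclusions.append((participant_id, f"missing recall {missing}"))
            continue
        n_matched += 1
        cov = covariates.get(participant_id, ParticipantCovariates())
        for quantity in ("sedentary", "light", "mvpa"):
            pairs_by_quantity[quantity].append(
                PairedObservation(
                    participant_id=participant_id,
                    value_a=first.minutes(quantity),
                    value_b=second.minutes(quantity),
                    age=cov.age,
                    gender=cov.gender,
                    bmi=cov.bmi,
                )
            )
        pairs_by_quantity["avg_met"].append(
            PairedObservation(
                participant_id=participant_id,
                value_a=first.avg_met,
                value_b=second.avg_met,
                age=cov.age,
                gender=cov.gender,
                bmi=cov.bmi,
            )
        )
    if n_matched == 0:
        raise PipelineError("no participant has both recall administrations")
    table, notes = agreement_table(pairs_by_quantity, config.percent_denominator)
    return StudyReport(kind="reliability", table=table, exclusions=exclusions, notes=notes)


def write_report(report: StudyReport, out_dir: str | Path) -> dict[str, Path]:
    """Write ``<kind>_report.csv`` / ``.json`` and ``<kind>_exclusions.log``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{report.kind}_report.csv"
    json_path = out_dir / f"{report.kind}_report.json"
    log_path = out_dir / f"{report.kind}_exclusions.log"
    report.table.to_csv(csv_path, index=False, float_format="%.6g")
    payload = {
        "kind": report.kind,
        "rows": report.table.replace({np.nan: None}).to_dict(orient="records"),
        "exclusions": [
            {"participant_id": pid, "reason": reason} for pid, reason in report.exclusions
        ],
        "notes": report.notes,
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")
    log_path.write_text(
        "".join(f"{pid}\t{reason}\n" for pid, reason in report.exclusions)
        + "".join(f"NOTE\t{note}\n" for note in report.notes),
        encoding="utf-8",
    )
    return {"csv": csv_path, "json": json_path, "log": log_path}
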