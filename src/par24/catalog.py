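"""Activity catalog: codes, categories and MET assignment.

Every reportable activity carries one or more MET (metabolic equivalent of
task) values, dimensionless multiples of resting metabolic rate, taken from
the Ainsworth compendium of physical activities.  An activity is scored in
exactly one of three modes:

* *plain* — a single MET value (``met_none``);
* *effort-ranked* — three MET values for light / medium / hard effort
  (e.g. cycling, Nordic walking), the respondent picks the effort level;
* *posture-adjustable* — sitting and standing MET values combined linearly
  by the reported standing-time fraction (0–100% scale), i.e. a
  time-weighted average of the two postural states.

Activities belong to one of 13 broad categories (sleeping and reclining,
personal care, food preparation and eating, walking/transportation,
household chores, occupational activity, shopping and errands, leisure and
hobbies, sports, family and social life, outdoor activities, lawn and
garden, miscellaneous).
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ContractError, FormatError, ValidationError

N_CATEGORIES = 13

EFFORT_LEVELS = ("light", "medium", "hard")

CATALOG_COLUMNS = (
    "code",
    "name",
    "category",
    "met_none",
    "met_light",
    "met_medium",
    "met_hard",
    "met_sitting",
    "met_standing",
)


@dataclass(frozen=True)
class ActivityDefinition:
    """One catalog activity with its MET value(s).

    Exactly one scoring mode must be populated: ``met_by_effort['none']``
    (plain), the three effort levels (effort-ranked), or the
    sitting/standing pair (posture-adjustable).
    """

    code: str
    name: str
    category: int
    met_by_effort: Mapping[str, float] = field(default_factory=dict)
    met_sitting: float | None = None
    met_standing: float | None = None

    def __post_init__(self) -> None:
        if not self.code:
            raise ValidationError("activity code must be non-empty")
        if not 1 <= self.category <= N_CATEGORIES:
            raise ValidationError(
                f"{self.code}: category {self.category} outside 1..{N_CATEGORIES}"
            )
        for level, met in self.met_by_effort.items():
            if level not in ("none",) + EFFORT_LEVELS:
                raise ValidationError(f"{self.code}: unknown effort level {level!r}")
            if not met > 0:
                raise ValidationError(f"{self.code}: MET for {level!r} must be > 0")
        for label, met in (("sitting", self.met_sitting), ("standing", self.met_standing)):
            if met is not None and not met > 0:
                raise ValidationError(f"{self.code}: MET {label} must be > 0")
        if (self.met_sitting is None) != (self.met_standing is None):
            raise ValidationError(
                f"{self.code}: posture-adjustable activities need both sitting and "
                "standing MET values"
            )
        modes = [
            "none" in self.met_by_effort,
            self.effort_ranked,
            self.posture_adjustable,
        ]
        if sum(modes) != 1:
            raise ValidationError(
                f"{self.code}: exactly one of met_none, the three effort columns, "
                "or the sitting/standing pair must be given"
            )
        if self.effort_ranked:
            light, medium, hard = (self.met_by_effort[e] for e in EFFORT_LEVELS)
            if not (light <= medium <= hard):
                raise ValidationError(
                    f"{self.code}: effort METs must be nondecreasing "
                    f"(light={light}, medium={medium}, hard={hard})"
                )

    @property
    def effort_ranked(self) -> bool:
        return all(level in self.met_by_effort for level in EFFORT_LEVELS)

    @property
    def posture_adjustable(self) -> bool:
        return self.met_sitting is not None and self.met_standing is not None


@dataclass(frozen=True)
class Catalog:
    """Immutable collection of :class:`ActivityDefinition` keyed by code."""

    definitions: Mapping[str, ActivityDefinition]

    def __post_init__(self) -> None:
        if not self.definitions:
            raise ValidationError("catalog must not be empty")
        for code, definition in self.definitions.items():
            if code != definition.code:
                raise ValidationError(f"catalog key {code!r} != definition code")

    def __contains__(self, code: str) -> bool:
        return code in self.definitions

    def __len__(self) -> int:
        return len(self.definitions)

    def __getitem__(self, code: str) -> ActivityDefinition:
        try:
            return self.definitions[code]
        except KeyError:
            raise KeyError(f"unknown activity code {code!r}") from None

    @classmethod
    def from_definitions(cls, definitions: Iterable[ActivityDefinition]) -> "Catalog":
        mapping: dict[str, ActivityDefinition] = {}
        for definition in definitions:
            if definition.code in mapping:
                raise FormatError(f"duplicate activity code {definition.code!r}")
            mapping[definition.code] = definition
        return cls(mapping)


def met_for_entry(
    definition: ActivityDefinition,
    effort: str | None = None,
    standing_fraction: float | None = None,
) -> float:
    """MET value of one diary entry for ``definition``.

    ``effort`` must be given iff the activity is effort-ranked;
    ``standing_fraction`` (in [0, 1]) iff it is posture-adjustable, in which
    case the MET is the time-weighted average
    ``standing_fraction * met_standing + (1 - standing_fraction) * met_sitting``.
    """
    if definition.effort_ranked:
        if effort is None:
            raise ContractError(f"{definition.code}: effort level required")
        if effort not in EFFORT_LEVELS:
            raise ValidationError(f"{definition.code}: unknown effort level {effort!r}")
        return definition.met_by_effort[effort]
    if effort is not None:
        raise ContractError(f"{definition.code}: effort given for non-ranked activity")
    if definition.posture_adjustable:
        if standing_fraction is None:
            raise ContractError(f"{definition.code}: standing_fraction required")
        if not 0.0 <= standing_fraction <= 1.0:
            raise ValidationError(
                f"{definition.code}: standing_fraction {standing_fraction} outside [0, 1]"
            )
        return (
            standing_fraction * definition.met_standing
            + (1.0 - standing_fraction) * definition.met_sitting
        )
    if standing_fraction is not None:
        raise ContractError(
            f"{definition.code}: standing_fraction given for fixed-posture activity"
        )
    return definition.met_by_effort["none"]


def _parse_met(cell: str, column: str, row_number: int) -> float | None:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise FormatError(f"row {row_number}: {column} is not a number: {cell!r}") from None


def load_catalog(path: str | Path) -> Catalog:
    """Load a catalog from CSV.

    Expected header: ``code,name,category,met_none,met_light,met_medium,
    met_hard,met_sitting,met_standing``; empty cells mean "absent".
    Duplicate codes and invariant violations are rejected with the row named.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or tuple(reader.fieldnames) != CATALOG_COLUMNS:
            raise FormatError(
                f"{path}: header must be {','.join(CATALOG_COLUMNS)}, "
                f"got {reader.fieldnames}"
            )
        definitions: dict[str, ActivityDefinition] = {}
        for row_number, row in enumerate(reader, start=2):
            code = (row["code"] or "").strip()
            if not code:
                raise FormatError(f"{path}: row {row_number}: missing activity code")
            if code in definitions:
                raise FormatError(f"{path}: row {row_number}: duplicate code {code!r}")
            try:
                category = int(row["category"])
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: row {row_number}: category is not an integer"
                ) from None
            met_by_effort = {}
            for level in ("none",) + EFFORT_LEVELS:
                value = _parse_met(row[f"met_{level}"], f"met_{level}", row_number)
                if value is not None:
                    met_by_effort[level] = value
            try:
                definitions[code] = ActivityDefinition(
                    code=code,
                    name=row["name"].strip(),
                    category=category,
                    met_by_effort=met_by_effort,
                    met_sitting=_parse_met(row["met_sitting"], "met_sitting", row_number),
                    met_standing=_parse_met(row["met_standing"], "met_standing", row_number),
                )
            except ValidationError as err:
                raise ValidationError(f"{path}: row {row_number}: {err}") from None
    return Catalog(definitions)


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write ``catalog`` in the CSV dialect accepted by :func:`load_catalog`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CATALOG_COLUMNS)
        for definition in catalog.definitions.values():
            effort = definition.met_by_effort
            writer.writerow(
                [
                    definition.code,
                    definition.name,
                    definition.category,
                    *(effort.get(level, "") for level in ("none",) + EFFORT_LEVELS),
                    definition.met_sitting if definition.met_sitting is not None else "",
                    definition.met_standing if definition.met_standing is not None else "",
                ]
            )


def demo_catalog() -> Catalog:
    """Bundled demonstration catalog (~30 activities across all 13 categories).

    A reduced fixture with MET values sourced from the public Ainsworth
    compendium; any user catalog in the documented CSV dialect can be used
    instead.
    """
    resource = importlib.resources.files("par24").joinpath("data/demo_catalog.csv")
    with importlib.resources.as_file(resource) as path:
        return load_catalog(path)
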