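"""Item-level food-log records for app-vs-weighed validation studies.

One :class:`ItemRecord` pairs a served food (staff-assigned FNDDS code,
covertly weighed kcal) with the two app log entries for the same food:
the *automated* entry (the app's AI output, unedited) and the
*semiautomated* entry (after user correction of identity/portion).
Mixed dishes logged as components appear as one record per component,
with distinct item identifiers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from .codes import FnddsCode

MENU_TYPES = ("chicken", "hamburger", "pizza", "pork_chop", "salad")

#: Beverage items excluded from the "without beverages" analyses.
DEFAULT_BEVERAGES = frozenset({"1% milk", "Coca Cola", "Diet Coke", "sweet tea"})


class Mode(str, enum.Enum):
    """Logging mode: raw AI output vs. user-corrected entry."""

    AUTOMATED = "automated"
    SEMIAUTOMATED = "semiautomated"


@dataclass(frozen=True)
class LogEntry:
    """One app log entry for a served item, in one mode.

    ``estimated_kcal`` is present exactly when the item was scanned, a
    food code was logged, and the app had nutrient information for it;
    otherwise the entry is an omission.
    """

    mode: Mode
    logged_code: Optional[FnddsCode] = None
    estimated_kcal: Optional[float] = None
    scanned: bool = True
    nutrient_available: bool = True

    @property
    def is_omission(self) -> bool:
        return (
            not self.scanned
            or not self.nutrient_available
            or self.logged_code is None
            or self.estimated_kcal is None
        )

    def check(self) -> list[str]:
        """Return invariant-violation messages (empty when consistent)."""
        problems = []
        complete = (
            self.logged_code is not None
            and self.scanned
            and self.nutrient_available
        )
        if (self.estimated_kcal is not None) != complete:
            problems.append(
                f"{self.mode.value}: estimated_kcal must be present iff "
                "logged_code present, scanned and nutrient_available"
            )
        if self.estimated_kcal is not None and self.estimated_kcal < 0:
            problems.append(f"{self.mode.value}: negative estimated_kcal")
        return problems


@dataclass(frozen=True)
class ItemRecord:
    """A served food item with its weighed kcal and both log entries."""

    participant_id: str
    meal_id: str
    menu_type: str
    menu_variant_kcal: int
    item_id: str
    item_name: str
    served_code: FnddsCode
    weighed_kcal: float
    automated: LogEntry
    semiautomated: LogEntry
    weighed_grams: Optional[float] = None
    is_beverage: bool = False

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.participant_id, self.meal_id, self.item_id)

    def entry(self, mode: Mode) -> LogEntry:
        return self.automated if mode is Mode.AUTOMATED else self.semiautomated

    def check(self) -> list[str]:
        problems = []
        if self.weighed_kcal < 0:
            problems.append("weighed_kcal is negative")
        if self.weighed_grams is not None and self.weighed_grams < 0:
            problems.append("weighed_grams is negative")
        if self.menu_type not in MENU_TYPES:
            problems.append(f"unknown menu_type {self.menu_type!r}")
        if self.automated.mode is not Mode.AUTOMATED:
            problems.append("automated entry carries wrong mode")
        if self.semiautomated.mode is not Mode.SEMIAUTOMATED:
            problems.append("semiautomated entry carries wrong mode")
        problems.extend(self.automated.check())
        problems.extend(self.semiautomated.check())
        return problems


@dataclass
class StudyDataset:
    """A collection of item records plus participant metadata."""

    items: list[ItemRecord] = field(default_factory=list)
    participants: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ItemRecord]:
        return iter(self.items)

    def participant_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.items:
            seen.setdefault(rec.participant_id, None)
        return list(seen)

    def meals(self) -> list[tuple[str, str]]:
        """Distinct (participant_id, meal_id) pairs, in first-seen order."""
        seen: dict[tuple[str, str], None] = {}
        for rec in self.items:
            seen.setdefault((rec.participant_id, rec.meal_id), None)
        return list(seen)

    def omission_count(self, mode: Optional[Mode] = None) -> int:
        """Items omitted in ``mode`` (or in either mode when ``None``)."""
        if mode is None:
            return sum(
                1
                for r in self.items
                if r.automated.is_omission or r.semiautomated.is_omission
            )
        return sum(1 for r in self.items if r.entry(mode).is_omission)

    def filtered(self, records: Iterable[ItemRecord]) -> "StudyDataset":
        return StudyDataset(items=list(records), participants=self.participants)


@dataclass(frozen=True)
class Violation:
    key: tuple[str, str, str]
    field: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_dataset(ds: StudyDataset) -> ValidationReport:
    """Check record invariants and key uniqueness; never raises.

    Violations are reported, not raised, so a partially dirty dataset can
    still be inspected.  The dataset is not modified.
    """
    report = ValidationReport()
    seen: set[tuple[str, str, str]] = set()
    for rec in ds.items:
        if rec.key in seen:
            report.violations.append(
                Violation(rec.key, "key", "duplicate (participant, meal, item) key")
            )
        seen.add(rec.key)
        for msg in rec.check():
            report.violations.append(Violation(rec.key, "record", msg))
    return report


def set_beverage_flags(
    ds: StudyDataset, beverage_names: Iterable[str] = DEFAULT_BEVERAGES
) -> StudyDataset:
    """Return a dataset with ``is_beverage`` recomputed from item names."""
    names = set(beverage_names)
    return ds.filtered(
        replace(rec, is_beverage=rec.item_name in names) for rec in ds.items
    )


@dataclass
class SurveyResponses:
    """Per-participant Likert vectors for the two usability instruments.

    CSUQ: 19 items on a 7-point scale, lower = more favorable.
    USS: 5 quantitative items on a 6-point scale, higher = more favorable.
    """

    csuq: dict[str, list[int]] = field(default_factory=dict)
    uss: dict[str, list[int]] = field(default_factory=dict)
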