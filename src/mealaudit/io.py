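"""Delimited-text I/O for item-level food logs and survey responses.

The on-disk schema is a flat, UTF-8, comma-delimited table with one row
per served item (``items.csv``) and a long-format survey table
(``surveys.csv``).  Parsing is strict: a missing required column, an
unparseable kcal value or a duplicate item key is an error that names
the offending row.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import IO, Iterable, Optional, Union

import numpy as np
import pandas as pd

from .codes import FnddsCode, parse_fndds_code
from .records import (
    DEFAULT_BEVERAGES,
    ItemRecord,
    LogEntry,
    Mode,
    StudyDataset,
    SurveyResponses,
)

logger = logging.getLogger(__name__)

Source = Union[str, Path, IO[str]]

ITEM_COLUMNS = [
    "participant_id",
    "meal_id",
    "menu_type",
    "menu_variant_kcal",
    "item_id",
    "item_name",
    "served_fndds",
    "weighed_kcal",
    "weighed_grams",
    "is_beverage",
    "auto_scanned",
    "auto_fndds",
    "auto_kcal",
    "auto_nutrients_available",
    "semi_fndds",
    "semi_kcal",
    "semi_nutrients_available",
]

SURVEY_COLUMNS = ["participant_id", "instrument", "item_number", "score"]


class SchemaError(ValueError):
    """Input file does not match the documented column schema."""


def _opt_code(value, row: int, col: str) -> Optional[FnddsCode]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        return parse_fndds_code(str(value))
    except ValueError as exc:
        raise SchemaError(f"row {row}: column {col}: {exc}") from exc


def _opt_float(value, row: int, col: str) -> Optional[float]:
    if value is None or value == "":
        return None
    try:
        out = float(value)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"row {row}: column {col}: not a number: {value!r}") from exc
    return None if np.isnan(out) else out


def _bool(value, row: int, col: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise SchemaError(f"row {row}: column {col}: not a boolean: {value!r}")


def read_dataset(
    source: Source,
    beverage_names: Iterable[str] = DEFAULT_BEVERAGES,
) -> StudyDataset:
    """Read an ``items.csv`` table into a :class:`StudyDataset`.

    Beverage flags are recomputed from ``beverage_names`` (the stored
    ``is_beverage`` column is advisory).  A row-count / omission-count
    summary is logged at INFO level.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in ITEM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    beverages = set(beverage_names)
    items: list[ItemRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        scanned = _bool(row.auto_scanned, i, "auto_scanned")
        auto = LogEntry(
            mode=Mode.AUTOMATED,
            logged_code=_opt_code(row.auto_fndds, i, "auto_fndds"),
            estimated_kcal=_opt_float(row.auto_kcal, i, "auto_kcal"),
            scanned=scanned,
            nutrient_available=_bool(
                row.auto_nutrients_available, i, "auto_nutrients_available"
            ),
        )
        semi = LogEntry(
            mode=Mode.SEMIAUTOMATED,
            logged_code=_opt_code(row.semi_fndds, i, "semi_fndds"),
            estimated_kcal=_opt_float(row.semi_kcal, i, "semi_kcal"),
            scanned=scanned,
            nutrient_available=_bool(
                row.semi_nutrients_available, i, "semi_nutrients_available"
            ),
        )
        weighed = _opt_float(row.weighed_kcal, i, "weighed_kcal")
        if weighed is None:
            raise SchemaError(f"row {i}: column weighed_kcal: value required")
        rec = ItemRecord(
            participant_id=str(row.participant_id),
            meal_id=str(row.meal_id),
            menu_type=str(row.menu_type),
            menu_variant_kcal=int(float(row.menu_variant_kcal)),
            item_id=str(row.item_id),
            item_name=str(row.item_name),
            served_code=parse_fndds_code(str(row.served_fndds))
            if row.served_fndds
            else _raise_required(i, "served_fndds"),
            weighed_kcal=weighed,
            weighed_grams=_opt_float(row.weighed_grams, i, "weighed_grams"),
            is_beverage=str(row.item_name) in beverages,
            automated=auto,
            semiautomated=semi,
        )
        if rec.key in seen:
            raise SchemaError(f"row {i}: duplicate item key {rec.key}")
        seen.add(rec.key)
        items.append(rec)

    ds = StudyDataset(items=items)
    logger.info(
        "read %d items; omissions: %d automated, %d semiautomated",
        len(items),
        ds.omission_count(Mode.AUTOMATED),
        ds.omission_count(Mode.SEMIAUTOMATED),
    )
    return ds


def _raise_required(row: int, col: str):
    raise SchemaError(f"row {row}: column {col}: value required")


def dataset_frame(ds: StudyDataset) -> pd.DataFrame:
    """Flatten a dataset to the documented ``items.csv`` column layout."""
    rows = []
    for r in ds.items:
        rows.append(
            {
                "participant_id": r.participant_id,
                "meal_id": r.meal_id,
                "menu_type": r.menu_type,
                "menu_variant_kcal": r.menu_variant_kcal,
                "item_id": r.item_id,
                "item_name": r.item_name,
                "served_fndds": str(r.served_code),
                "weighed_kcal": r.weighed_kcal,
                "weighed_grams": "" if r.weighed_grams is None else r.weighed_grams,
                "is_beverage": r.is_beverage,
                "auto_scanned": r.automated.scanned,
                "auto_fndds": r.automated.logged_code or "",
                "auto_kcal": ""
                if r.automated.estimated_kcal is None
                else r.automated.estimated_kcal,
                "auto_nutrients_available": r.automated.nutrient_available,
                "semi_fndds": r.semiautomated.logged_code or "",
                "semi_kcal": ""
                if r.semiautomated.estimated_kcal is None
                else r.semiautomated.estimated_kcal,
                "semi_nutrients_available": r.semiautomated.nutrient_available,
            }
        )
    return pd.DataFrame(rows, columns=ITEM_COLUMNS)


def write_dataset(ds: StudyDataset, dest: Source) -> None:
    dataset_frame(ds).to_csv(dest, index=False)


def read_surveys(source: Source) -> SurveyResponses:
    """Read a long-format ``surveys.csv`` (instrument CSUQ or USS)."""
    df = pd.read_csv(source)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = SurveyResponses()
    for (pid, instrument), sub in df.groupby(["participant_id", "instrument"], sort=False):
        sub = sub.sort_values("item_number")
        scores = [int(s) for s in sub["score"]]
        if instrument == "CSUQ":
            out.csuq[str(pid)] = scores
        elif instrument == "USS":
            out.uss[str(pid)] = scores
        else:
            raise SchemaError(f"unknown instrument {instrument!r}")
    return out


def surveys_frame(responses: SurveyResponses) -> pd.DataFrame:
    rows = []
    for pid, scores in responses.csuq.items():
        for i, s in enumerate(scores, start=1):
            rows.append((pid, "CSUQ", i, s))
    for pid, scores in responses.uss.items():
        for i, s in enumerate(scores, start=1):
            rows.append((pid, "USS", i, s))
    return pd.DataFrame(rows, columns=SURVEY_COLUMNS)


def write_surveys(responses: SurveyResponses, dest: Source) -> None:
    surveys_frame(responses).to_csv(dest, index=False)
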