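"""Energy percent-error and bounds analyses at meal and item level.

Percent error is signed and relative to the weighed (criterion) value:

    percent error = 100 * (estimated kcal - weighed kcal) / weighed kcal

so overestimation is positive.  Two aggregate error measures are
deliberately distinct:

* ``summarize_*`` report the mean of per-unit percent errors
  ("mean of ratios", the per-row error columns of the report tables);
* :func:`elevation_of_means` reports how much the *mean* estimated
  energy exceeds the *mean* weighed energy ("ratio of means", the
  headline "x% higher than weighed" number).

Items omitted in either mode are excluded from meal totals in all three
columns (weighed, automated, semiautomated) so the totals cover
identical item sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .codes import major_group
from .identification import exclude_beverages
from .records import Mode, StudyDataset

logger = logging.getLogger(__name__)

DEFAULT_BOUNDS = (10.0, 25.0)


def percent_error(estimated: float, weighed: float) -> float:
    """Signed percent error of an estimate against the weighed value.

    Returns ``nan`` when ``weighed`` is zero (undefined; excluded from
    means downstream with a logged warning).
    """
    if weighed == 0:
        logger.warning("percent_error undefined for weighed_kcal == 0")
        return math.nan
    return 100.0 * (estimated - weighed) / weighed


@dataclass(frozen=True)
class MealEnergy:
    """Per-meal kcal totals by mode with percent errors and bounds flags."""

    participant_id: str
    meal_id: str
    menu_type: str
    n_items: int
    weighed_kcal_total: float
    auto_kcal_total: float
    semi_kcal_total: float

    @property
    def pct_error_auto(self) -> float:
        return percent_error(self.auto_kcal_total, self.weighed_kcal_total)

    @property
    def pct_error_semi(self) -> float:
        return percent_error(self.semi_kcal_total, self.weighed_kcal_total)

    def pct_error(self, mode: Mode) -> float:
        return self.pct_error_auto if mode is Mode.AUTOMATED else self.pct_error_semi

    def total(self, mode: Mode) -> float:
        return self.auto_kcal_total if mode is Mode.AUTOMATED else self.semi_kcal_total

    def within(self, bound: float, mode: Mode) -> bool:
        """Closed bound: |percent error| <= bound."""
        err = self.pct_error(mode)
        return bool(abs(err) <= bound) if not math.isnan(err) else False

    @property
    def within_10_auto(self) -> bool:
        return self.within(10.0, Mode.AUTOMATED)

    @property
    def within_10_semi(self) -> bool:
        return self.within(10.0, Mode.SEMIAUTOMATED)

    @property
    def within_25_auto(self) -> bool:
        return self.within(25.0, Mode.AUTOMATED)

    @property
    def within_25_semi(self) -> bool:
        return self.within(25.0, Mode.SEMIAUTOMATED)


def meal_totals(ds: StudyDataset, include_beverages: bool = True) -> list[MealEnergy]:
    """Sum kcal per meal over items present (non-omitted) in both modes.

    Meals left with zero included items are dropped with a warning.
    """
    if not include_beverages:
        ds = exclude_beverages(ds)
    meals: dict[tuple[str, str], dict] = {}
    for rec in ds.items:
        if rec.automated.is_omission or rec.semiautomated.is_omission:
            continue
        key = (rec.participant_id, rec.meal_id)
        acc = meals.setdefault(
            key,
            {"menu_type": rec.menu_type, "n": 0, "w": 0.0, "a": 0.0, "s": 0.0},
        )
        acc["n"] += 1
        acc["w"] += rec.weighed_kcal
        acc["a"] += rec.automated.estimated_kcal
        acc["s"] += rec.semiautomated.estimated_kcal
    out = []
    for (pid, mid), acc in meals.items():
        if acc["n"] == 0:
            logger.warning("meal (%s, %s) has no included items; dropped", pid, mid)
            continue
        out.append(
            MealEnergy(
                participant_id=pid,
                meal_id=mid,
                menu_type=acc["menu_type"],
                n_items=acc["n"],
                weighed_kcal_total=acc["w"],
                auto_kcal_total=acc["a"],
                semi_kcal_total=acc["s"],
            )
        )
    return out


def elevation_of_means(meals: Sequence[MealEnergy], mode: Mode) -> float:
    """Percent by which mean estimated energy exceeds mean weighed energy.

    100 * (mean(estimated totals) - mean(weighed totals)) / mean(weighed
    totals); equal, by algebra, to the same expression on sums.
    """
    if not meals:
        raise ValueError("elevation_of_means requires at least one meal")
    w = float(np.mean([m.weighed_kcal_total for m in meals]))
    e = float(np.mean([m.total(mode) for m in meals]))
    return 100.0 * (e - w) / w


def mean_difference(meals: Sequence[MealEnergy], mode: Mode) -> tuple[float, float]:
    """Mean and SD (n-1) of per-meal (estimated - weighed) kcal."""
    diffs = np.array([m.total(mode) - m.weighed_kcal_total for m in meals], float)
    sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else math.nan
    return float(np.mean(diffs)), sd


@dataclass(frozen=True)
class EnergySummary:
    """Mean/SD energy and error statistics within one stratum.

    ``n`` counts meals (meal-level strata) or items (food-group strata).
    SDs use the n-1 denominator and are ``nan`` for single-unit strata.
    """

    stratum_label: str
    n: int
    weighed_mean: float
    weighed_sd: float
    auto_mean: float
    auto_sd: float
    semi_mean: float
    semi_sd: float
    pct_error_auto_mean: float
    pct_error_auto_sd: float
    pct_error_semi_mean: float
    pct_error_semi_sd: float
    n_within_10_auto: int
    n_within_10_semi: int
    n_within_25_auto: int
    n_within_25_semi: int

    def pct_within(self, bound: int, mode: Mode) -> float:
        n = {
            (10, Mode.AUTOMATED): self.n_within_10_auto,
            (10, Mode.SEMIAUTOMATED): self.n_within_10_semi,
            (25, Mode.AUTOMATED): self.n_within_25_auto,
            (25, Mode.SEMIAUTOMATED): self.n_within_25_semi,
        }[(bound, mode)]
        return 100.0 * n / self.n if self.n else math.nan


def _summarize(label: str, rows: list[tuple[float, float, float]]) -> EnergySummary:
    """Summarise (weighed, auto, semi) kcal triples for one stratum."""
    w = np.array([r[0] for r in rows], float)
    a = np.array([r[1] for r in rows], float)
    s = np.array([r[2] for r in rows], float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pe_a = np.where(w != 0, 100.0 * (a - w) / w, np.nan)
        pe_s = np.where(w != 0, 100.0 * (s - w) / w, np.nan)
    n_undef = int(np.isnan(pe_a).sum())
    if n_undef:
        logger.warning(
            "stratum %r: %d unit(s) with weighed kcal 0 excluded from error means",
            label, n_undef,
        )

    def _mean(x):
        x = x[~np.isnan(x)]
        return float(np.mean(x)) if len(x) else math.nan

    def _sd(x):
        x = x[~np.isnan(x)]
        return float(np.std(x, ddof=1)) if len(x) > 1 else math.nan

    def _n_within(pe, bound):
        return int(np.sum(np.abs(pe[~np.isnan(pe)]) <= bound))

    return EnergySummary(
        stratum_label=label,
        n=len(rows),
        weighed_mean=_mean(w), weighed_sd=_sd(w),
        auto_mean=_mean(a), auto_sd=_sd(a),
        semi_mean=_mean(s), semi_sd=_sd(s),
        pct_error_auto_mean=_mean(pe_a), pct_error_auto_sd=_sd(pe_a),
        pct_error_semi_mean=_mean(pe_s), pct_error_semi_sd=_sd(pe_s),
        n_within_10_auto=_n_within(pe_a, 10.0),
        n_within_10_semi=_n_within(pe_s, 10.0),
        n_within_25_auto=_n_within(pe_a, 25.0),
        n_within_25_semi=_n_within(pe_s, 25.0),
    )


def summarize_overall(meals: Sequence[MealEnergy]) -> EnergySummary:
    rows = [
        (m.weighed_kcal_total, m.auto_kcal_total, m.semi_kcal_total) for m in meals
    ]
    return _summarize("all meals", rows)


def summarize_by_menu_type(meals: Sequence[MealEnergy]) -> list[EnergySummary]:
    """Meal-level summaries per menu type (mean-of-ratios error columns)."""
    groups: dict[str, list] = {}
    for m in meals:
        groups.setdefault(m.menu_type, []).append(
            (m.weighed_kcal_total, m.auto_kcal_total, m.semi_kcal_total)
        )
    return [_summarize(label, rows) for label, rows in groups.items()]


def summarize_by_food_group(
    ds: StudyDataset, include_beverages: bool = True
) -> list[EnergySummary]:
    """Item-level summaries stratified by the served code's major group.

    Items omitted in either mode are excluded; empty groups are skipped.
    """
    if not include_beverages:
        ds = exclude_beverages(ds)
    groups: dict[str, list] = {}
    for rec in ds.items:
        if rec.automated.is_omission or rec.semiautomated.is_omission:
            continue
        label = major_group(rec.served_code).label
        groups.setdefault(label, []).append(
            (
                rec.weighed_kcal,
                rec.automated.estimated_kcal,
                rec.semiautomated.estimated_kcal,
            )
        )
    return [_summarize(label, rows) for label, rows in groups.items()]
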