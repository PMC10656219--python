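"""Hierarchical FNDDS match classification and paired-proportions tests.

A logged food is compared with the served food through the FNDDS code
hierarchy:

* **exact** — all 8 digits agree;
* **far** — only the first digit (major food group) agrees;
* **intrusion** — the first digits differ;
* **omission** — the item was never scanned, or the app had no nutrient
  information for what was logged.  Omissions are excluded from the
  denominators of all match tables.

Automated and semiautomated logging of the same items form natural
matched pairs, so mode differences in category membership are tested
with McNemar's test on the discordant pairs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from statsmodels.stats.contingency_tables import mcnemar

from .codes import FnddsCode, major_group
from .records import ItemRecord, LogEntry, Mode, StudyDataset


class MatchCategory(str, enum.Enum):
    EXACT = "exact"
    FAR = "far"
    INTRUSION = "intrusion"
    OMISSION = "omission"


class Stratifier(str, enum.Enum):
    OVERALL = "overall"
    BY_MEAL_TYPE = "by_meal_type"
    BY_FOOD_GROUP = "by_food_group"


def classify_match(served: FnddsCode, entry: LogEntry) -> MatchCategory:
    """Classify one log entry against the served food's code.

    The four categories are mutually exclusive and exhaustive: "far"
    excludes "exact", and anything unscanned / without nutrient data is
    an omission regardless of the code logged.
    """
    if entry.is_omission:
        return MatchCategory.OMISSION
    logged = entry.logged_code
    if logged == served:
        return MatchCategory.EXACT
    if logged[0] == served[0]:
        return MatchCategory.FAR
    return MatchCategory.INTRUSION


@dataclass(frozen=True)
class MatchTable:
    """Counts and percentages of match outcomes within one stratum.

    Percentages are computed on classified items only (omissions are
    excluded from the denominator) and are ``nan`` when the stratum is
    empty after exclusions.
    """

    stratum_label: str
    mode: Mode
    n_classified: int
    n_exact: int
    n_far: int
    n_intrusion: int
    n_omitted: int

    def __post_init__(self) -> None:
        if self.n_exact + self.n_far + self.n_intrusion != self.n_classified:
            raise ValueError("match counts do not sum to n_classified")

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.n_classified if self.n_classified else math.nan

    @property
    def pct_exact(self) -> float:
        return self._pct(self.n_exact)

    @property
    def pct_far(self) -> float:
        return self._pct(self.n_far)

    @property
    def pct_intrusion(self) -> float:
        return self._pct(self.n_intrusion)


def exclude_beverages(ds: StudyDataset) -> StudyDataset:
    """Dataset restricted to non-beverage items; the input is untouched."""
    return ds.filtered(r for r in ds.items if not r.is_beverage)


def _stratum_of(rec: ItemRecord, stratifier: Stratifier) -> str:
    if stratifier is Stratifier.OVERALL:
        return "overall"
    if stratifier is Stratifier.BY_MEAL_TYPE:
        return rec.menu_type
    return major_group(rec.served_code).label


def tabulate_matches(
    ds: StudyDataset,
    mode: Mode,
    stratifier: Stratifier = Stratifier.OVERALL,
    include_beverages: bool = True,
) -> list[MatchTable]:
    """One :class:`MatchTable` per stratum for the given logging mode.

    Items classified as omissions in ``mode`` are counted but excluded
    from the percentage denominators.  When ``include_beverages`` is
    false the beverage exclusion is applied before stratification.
    """
    if not include_beverages:
        ds = exclude_beverages(ds)
    counts: dict[str, dict[MatchCategory, int]] = {}
    for rec in ds.items:
        stratum = _stratum_of(rec, stratifier)
        cat = classify_match(rec.served_code, rec.entry(mode))
        bucket = counts.setdefault(stratum, {c: 0 for c in MatchCategory})
        bucket[cat] += 1
    tables = []
    for stratum, bucket in counts.items():
        classified = (
            bucket[MatchCategory.EXACT]
            + bucket[MatchCategory.FAR]
            + bucket[MatchCategory.INTRUSION]
        )
        tables.append(
            MatchTable(
                stratum_label=stratum,
                mode=mode,
                n_classified=classified,
                n_exact=bucket[MatchCategory.EXACT],
                n_far=bucket[MatchCategory.FAR],
                n_intrusion=bucket[MatchCategory.INTRUSION],
                n_omitted=bucket[MatchCategory.OMISSION],
            )
        )
    return tables


@dataclass(frozen=True)
class PairedPropResult:
    """McNemar comparison of category membership between the two modes."""

    category: MatchCategory
    n_pairs: int
    b: int  # automated-only positives
    c: int  # semiautomated-only positives
    statistic: float
    p_value: float
    method: str
    degenerate: bool = False


def paired_proportions_test(
    ds: StudyDataset,
    category: MatchCategory,
    stratifier: Stratifier = Stratifier.OVERALL,
    stratum: Optional[str] = None,
    include_beverages: bool = True,
    method: str = "auto",
) -> PairedPropResult:
    """Test whether membership in ``category`` differs between modes.

    Items omitted in either mode are excluded so both indicator vectors
    cover the same items.  ``method``: "exact" (binomial McNemar),
    "chi2" (continuity-corrected), or "auto" (exact unless the number of
    discordant pairs exceeds 25).
    """
    if not include_beverages:
        ds = exclude_beverages(ds)
    b = c = n = 0
    for rec in ds.items:
        cat_auto = classify_match(rec.served_code, rec.automated)
        cat_semi = classify_match(rec.served_code, rec.semiautomated)
        if MatchCategory.OMISSION in (cat_auto, cat_semi):
            continue
        if stratum is not None and _stratum_of(rec, stratifier) != stratum:
            continue
        n += 1
        in_auto = cat_auto is category
        in_semi = cat_semi is category
        if in_auto and not in_semi:
            b += 1
        elif in_semi and not in_auto:
            c += 1

    if b + c == 0:
        return PairedPropResult(
            category, n, b, c, statistic=math.nan, p_value=1.0,
            method="degenerate (no discordant pairs)", degenerate=True,
        )
    exact = method == "exact" or (method == "auto" and b + c <= 25)
    table = np.array([[0, b], [c, 0]])  # only discordant cells matter
    res = mcnemar(table, exact=exact, correction=True)
    label = "exact binomial (McNemar)" if exact else "chi-square with continuity correction (McNemar)"
    return PairedPropResult(
        category, n, b, c,
        statistic=float(res.statistic), p_value=float(res.pvalue), method=label,
    )
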