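"""Full-pipeline orchestration: from item/survey tables to report surfaces.

``run_pipeline`` reproduces the report structure of an app-validation
study: identification match tables (overall / by meal type / by food
group, with and without beverages) with paired-proportions tests,
meal- and item-level energy summaries with ±10%/±25% bounds, headline
elevation-of-means numbers, Bland–Altman and calibration results per
(mode × beverage-inclusion) cell, and survey scores.  Every percentage
in the report sits beside the counts it was computed from.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .agreement import bland_altman, calibration_ols
from .energy import (
    elevation_of_means,
    meal_totals,
    mean_difference,
    summarize_by_food_group,
    summarize_by_menu_type,
    summarize_overall,
)
from .identification import (
    MatchCategory,
    Stratifier,
    paired_proportions_test,
    tabulate_matches,
)
from .io import read_dataset, read_surveys
from .records import (
    DEFAULT_BEVERAGES,
    Mode,
    StudyDataset,
    SurveyResponses,
    validate_dataset,
)
from .surveys import score_csuq, score_uss
from .util import ROUNDING

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Analysis options shared by the pipeline stages."""

    beverage_names: tuple[str, ...] = tuple(sorted(DEFAULT_BEVERAGES))
    bounds: tuple[float, ...] = (10.0, 25.0)
    rounding: str = "half-up"
    mcnemar_method: str = "auto"
    loa_multiplier: float = 1.96

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kw = {k: v for k, v in raw.items() if k in known}
        for key in ("beverage_names", "bounds"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)


@dataclass
class PipelineReport:
    """All report surfaces as flat, JSON-serialisable row lists."""

    match_rows: list[dict] = field(default_factory=list)
    energy_meals: list[dict] = field(default_factory=list)
    energy_summaries: list[dict] = field(default_factory=list)
    elevations: list[dict] = field(default_factory=list)
    agreement: list[dict] = field(default_factory=list)
    survey_scores: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineReport":
        return cls(**d)


def _match_section(ds: StudyDataset, config: AnalysisConfig) -> list[dict]:
    rows = []
    for include_bev in (True, False):
        for strat in Stratifier:
            tables = {
                mode: {
                    t.stratum_label: t
                    for t in tabulate_matches(ds, mode, strat, include_bev)
                }
                for mode in Mode
            }
            strata = list(tables[Mode.AUTOMATED])
            for stratum in strata:
                row = {
                    "beverages_included": include_bev,
                    "stratifier": strat.value,
                    "stratum": stratum,
                }
                for mode in Mode:
                    t = tables[mode][stratum]
                    prefix = "auto" if mode is Mode.AUTOMATED else "semi"
                    row.update(
                        {
                            f"{prefix}_n_classified": t.n_classified,
                            f"{prefix}_n_exact": t.n_exact,
                            f"{prefix}_n_far": t.n_far,
                            f"{prefix}_n_intrusion": t.n_intrusion,
                            f"{prefix}_n_omitted": t.n_omitted,
                            f"{prefix}_pct_exact": t.pct_exact,
                            f"{prefix}_pct_far": t.pct_far,
                            f"{prefix}_pct_intrusion": t.pct_intrusion,
                        }
                    )
                for cat in (
                    MatchCategory.EXACT,
                    MatchCategory.FAR,
                    MatchCategory.INTRUSION,
                ):
                    res = paired_proportions_test(
                        ds,
                        cat,
                        stratifier=strat,
                        stratum=None if strat is Stratifier.OVERALL else stratum,
                        include_beverages=include_bev,
                        method=config.mcnemar_method,
                    )
                    row[f"p_{cat.value}"] = res.p_value
                    row[f"method_{cat.value}"] = res.method
                rows.append(row)
    return rows


def _check_consistency(rows: list[dict]) -> None:
    """Overall counts must equal the sum of per-meal-type counts."""
    for include_bev in (True, False):
        sub = [r for r in rows if r["beverages_included"] == include_bev]
        overall = next(r for r in sub if r["stratifier"] == "overall")
        by_meal = [r for r in sub if r["stratifier"] == "by_meal_type"]
        for col in ("auto_n_exact", "auto_n_classified", "semi_n_exact"):
            total = sum(r[col] for r in by_meal)
            if total != overall[col]:
                raise AssertionError(
                    f"inconsistent report: {col} overall {overall[col]} != "
                    f"sum over meal types {total}"
                )


def _energy_sections(
    ds: StudyDataset, config: AnalysisConfig
) -> tuple[list[dict], list[dict], list[dict], list[dict]]:
    meal_rows, summary_rows, elevation_rows, agreement_rows = [], [], [], []
    for include_bev in (True, False):
        meals = meal_totals(ds, include_beverages=include_bev)
        for m in meals:
            meal_rows.append(
                {
                    "beverages_included": include_bev,
                    "participant_id": m.participant_id,
                    "meal_id": m.meal_id,
                    "menu_type": m.menu_type,
                    "n_items": m.n_items,
                    "weighed_kcal_total": m.weighed_kcal_total,
                    "auto_kcal_total": m.auto_kcal_total,
                    "semi_kcal_total": m.semi_kcal_total,
                    "pct_error_auto": m.pct_error_auto,
                    "pct_error_semi": m.pct_error_semi,
                    "within_10_auto": m.within_10_auto,
                    "within_10_semi": m.within_10_semi,
                    "within_25_auto": m.within_25_auto,
                    "within_25_semi": m.within_25_semi,
                }
            )
        summaries = (
            [("overall", summarize_overall(meals))]
            + [("by_menu_type", s) for s in summarize_by_menu_type(meals)]
            + [
                ("by_food_group", s)
                for s in summarize_by_food_group(ds, include_beverages=include_bev)
            ]
        )
        for level, s in summaries:
            row = {"beverages_included": include_bev, "level": level}
            row.update(dataclasses.asdict(s))
            summary_rows.append(row)
        for mode in Mode:
            elev = elevation_of_means(meals, mode)
            md, sd = mean_difference(meals, mode)
            elevation_rows.append(
                {
                    "beverages_included": include_bev,
                    "mode": mode.value,
                    "n_meals": len(meals),
                    "elevation_pct": elev,
                    "mean_diff_kcal": md,
                    "sd_diff_kcal": sd,
                }
            )
            pairs = [(m.weighed_kcal_total, m.total(mode)) for m in meals]
            ba = bland_altman(pairs, loa_multiplier=config.loa_multiplier)
            cal = calibration_ols(pairs)
            row = {"beverages_included": include_bev, "mode": mode.value}
            row.update({f"ba_{k}": v for k, v in dataclasses.asdict(ba).items()})
            row.update({f"cal_{k}": v for k, v in dataclasses.asdict(cal).items()})
            agreement_rows.append(row)
    return meal_rows, summary_rows, elevation_rows, agreement_rows


def build_report(
    ds: StudyDataset,
    surveys: Optional[SurveyResponses] = None,
    config: Optional[AnalysisConfig] = None,
    seed: Optional[int] = None,
) -> PipelineReport:
    """Run every analysis stage on an in-memory dataset."""
    config = config or AnalysisConfig()
    validation = validate_dataset(ds)
    if not validation.ok:
        for v in validation.violations[:20]:
            logger.warning("validation: %s %s: %s", v.key, v.field, v.message)
        raise ValueError(
            f"dataset failed validation with {len(validation.violations)} violation(s)"
        )

    report = PipelineReport()
    report.match_rows = _match_section(ds, config)
    _check_consistency(report.match_rows)
    (
        report.energy_meals,
        report.energy_summaries,
        report.elevations,
        report.agreement,
    ) = _energy_sections(ds, config)

    if surveys is not None and (surveys.csuq or surveys.uss):
        scores = []
        if surveys.csuq:
            scores.extend(score_csuq(surveys))
        if surveys.uss:
            scores.extend(score_uss(surveys))
        report.survey_scores = [dataclasses.asdict(s) for s in scores]

    n_omitted = ds.omission_count()
    logger.info("omissions: %d of %d items excluded", n_omitted, len(ds))
    config_hash = hashlib.sha256(
        json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    report.provenance = {
        "version": __version__,
        "config_hash": config_hash,
        "seed": seed,
        "n_items": len(ds),
        "n_omitted": n_omitted,
        "n_participants": len(ds.participant_ids()),
        "n_meals": len(ds.meals()),
    }
    return report


def run_pipeline(
    items_path: Union[str, Path],
    surveys_path: Optional[Union[str, Path]] = None,
    config: Optional[AnalysisConfig] = None,
    seed: Optional[int] = None,
) -> PipelineReport:
    """Read the input tables and build the full report."""
    config = config or AnalysisConfig()
    ds = read_dataset(items_path, beverage_names=config.beverage_names)
    surveys = read_surveys(surveys_path) if surveys_path else None
    return build_report(ds, surveys, config, seed=seed)


CSV_BUNDLE = {
    "match_tables.csv": "match_rows",
    "energy_meals.csv": "energy_meals",
    "energy_summary.csv": "energy_summaries",
    "agreement.csv": "agreement",
    "survey_scores.csv": "survey_scores",
}


def render_report(
    report: PipelineReport,
    outdir: Union[str, Path],
    fmt: str = "csv_bundle",
    rounding: str = "half-up",
    display_decimals: int = 1,
) -> list[Path]:
    """Write the report as a CSV bundle or a single JSON file.

    JSON keeps full precision; CSVs round floats for display with the
    configured rounding mode.  Output is bit-stable for equal reports.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "json":
        path = outdir / "report.json"
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        return [path]
    if fmt != "csv_bundle":
        raise ValueError(f"unknown format {fmt!r}")

    rounder = ROUNDING[rounding]
    for filename, attr in CSV_BUNDLE.items():
        rows = getattr(report, attr)
        df = pd.DataFrame(rows)
        for col in df.columns:
            if df[col].dtype == float:
                df[col] = df[col].map(
                    lambda x: x if pd.isna(x) else rounder(x, display_decimals)
                )
        path = outdir / filename
        df.to_csv(path, index=False)
        written.append(path)
    path = outdir / "provenance.json"
    path.write_text(json.dumps(report.provenance, indent=2, sort_keys=True))
    written.append(path)
    return written


def report_from_json(path: Union[str, Path]) -> PipelineReport:
    with open(path) as fh:
        return PipelineReport.from_dict(json.load(fh))
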