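"""Seeded synthetic food-log studies for end-to-end pipeline testing.

The generator emulates a laboratory validation study of an AI dietary
assessment app: 24 participants each log 2 meals drawn from 10 menus
(5 meal types x 2 energy levels, ~420-800 kcal), built from 32 distinct
foods with staff-assigned FNDDS codes and covertly weighed kcal.  Every
menu includes one beverage.  For each served item the generator samples:

* a match outcome (exact / far / intrusion) per logging mode, from
  configurable category probabilities, with a small omission rate;
* a logged FNDDS code consistent with the outcome, drawn from a
  per-code candidate pool (far = same first digit, different remainder;
  intrusion = different first digit);
* an estimated kcal from a multiplicative log-normal error model with
  food-group-specific bias (beverages grossly overestimated under
  automated logging), or an additive model for null testing;
* semiautomated entries by *conditional correction*: a correct
  automated entry is kept unchanged with the coupling probability,
  anything else is re-logged, so that the configured semiautomated
  category probabilities are the marginal distribution.

Menu compositions are invented placeholders at realistic energy levels;
they are configuration data, not ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .codes import FnddsCode, major_group, parse_fndds_code
from .records import (
    ItemRecord,
    LogEntry,
    Mode,
    StudyDataset,
    SurveyResponses,
)


@dataclass(frozen=True)
class MenuItem:
    name: str
    code: str
    kcal: float
    is_beverage: bool = False


# (menu_type, variant target kcal) -> served items; kcal sum to the target.
DEFAULT_MENUS: dict[tuple[str, int], tuple[MenuItem, ...]] = {
    ("chicken", 450): (
        MenuItem("baked chicken breast", "24120110", 180),
        MenuItem("wild rice", "56205310", 90),
        MenuItem("green beans", "75215000", 35),
        MenuItem("dinner roll", "51320500", 80),
        MenuItem("hard butter", "81101000", 35),
        MenuItem("sweet tea", "92510610", 30, is_beverage=True),
    ),
    ("chicken", 700): (
        MenuItem("baked chicken breast", "24120110", 260),
        MenuItem("wild rice", "56205310", 130),
        MenuItem("green beans", "75215000", 50),
        MenuItem("buttermilk biscuit", "52101010", 110),
        MenuItem("hard butter", "81101000", 50),
        MenuItem("sweet tea", "92510610", 40, is_beverage=True),
        MenuItem("chocolate chip cookie", "53206500", 60),
    ),
    ("hamburger", 500): (
        MenuItem("cheeseburger", "27510170", 300),
        MenuItem("french fries", "71401030", 120),
        MenuItem("ketchup", "74401010", 20),
        MenuItem("apple slices", "63101210", 30),
        MenuItem("Coca Cola", "92410310", 30, is_beverage=True),
    ),
    ("hamburger", 750): (
        MenuItem("cheeseburger", "27510170", 430),
        MenuItem("onion rings", "71403010", 180),
        MenuItem("ketchup", "74401010", 20),
        MenuItem("apple slices", "63101210", 50),
        MenuItem("Coca Cola", "92410310", 70, is_beverage=True),
    ),
    ("pizza", 500): (
        MenuItem("cheese pizza", "58106210", 345),
        MenuItem("garden side salad", "75113000", 25),
        MenuItem("ranch dressing", "83107000", 70),
        MenuItem("grapes", "63123000", 58),
        MenuItem("Diet Coke", "92410520", 2, is_beverage=True),
    ),
    ("pizza", 800): (
        MenuItem("cheese pizza", "58106210", 560),
        MenuItem("garden side salad", "75113000", 25),
        MenuItem("ranch dressing", "83107000", 98),
        MenuItem("breadstick", "51301510", 115),
        MenuItem("Diet Coke", "92410520", 2, is_beverage=True),
    ),
    ("pork_chop", 520): (
        MenuItem("grilled pork chop", "22101110", 200),
        MenuItem("mashed potatoes", "71501010", 110),
        MenuItem("glazed carrots", "73101010", 40),
        MenuItem("cornbread", "52302010", 70),
        MenuItem("1% milk", "11112210", 100, is_beverage=True),
    ),
    ("pork_chop", 720): (
        MenuItem("grilled pork chop", "22101110", 290),
        MenuItem("mashed potatoes", "71501010", 160),
        MenuItem("glazed carrots", "73101010", 60),
        MenuItem("apple pie slice", "53301110", 100),
        MenuItem("1% milk", "11112210", 110, is_beverage=True),
    ),
    ("salad", 420): (
        MenuItem("romaine salad mix", "75113080", 30),
        MenuItem("grilled chicken strips", "24198740", 120),
        MenuItem("croutons", "51501010", 60),
        MenuItem("italian dressing", "83200310", 80),
        MenuItem("cheddar cheese", "14104100", 80),
        MenuItem("sweet tea", "92510610", 50, is_beverage=True),
    ),
    ("salad", 620): (
        MenuItem("romaine salad mix", "75113080", 45),
        MenuItem("grilled chicken strips", "24198740", 180),
        MenuItem("croutons", "51501010", 90),
        MenuItem("italian dressing", "83200310", 120),
        MenuItem("boiled egg", "31103010", 110),
        MenuItem("sweet tea", "92510610", 75, is_beverage=True),
    ),
}

# Mean multiplicative bias (estimated/weighed) per (mode, major group),
# chosen so beverages are grossly overestimated by the raw AI output and
# largely fixed by user correction; groups 3 and 4 default to mild
# overestimation.
DEFAULT_BIAS_RATIO = {
    Mode.AUTOMATED: {1: 0.69, 2: 1.42, 3: 1.20, 4: 1.20, 5: 1.02, 6: 1.02,
                     7: 1.96, 8: 0.75, 9: 4.03},
    Mode.SEMIAUTOMATED: {1: 1.02, 2: 1.30, 3: 1.15, 4: 1.15, 5: 1.95, 6: 1.21,
                         7: 0.93, 8: 1.04, 9: 0.85},
}

# Log-scale spread of the multiplicative error per (mode, major group).
DEFAULT_SIGMA = {
    Mode.AUTOMATED: {1: 0.40, 2: 0.80, 3: 0.50, 4: 0.50, 5: 0.90, 6: 0.30,
                     7: 1.00, 8: 1.00, 9: 1.00},
    Mode.SEMIAUTOMATED: {1: 0.40, 2: 0.60, 3: 0.50, 4: 0.50, 5: 1.00, 6: 0.25,
                         7: 0.90, 8: 0.80, 9: 0.55},
}

DEFAULT_MATCH_PROBS = {
    Mode.AUTOMATED: (0.46, 0.41, 0.13),
    Mode.SEMIAUTOMATED: (0.87, 0.13, 0.00),
}

DEFAULT_USS_MEANS = ((4.1, 1.3), (4.0, 1.5), (4.2, 1.4), (4.0, 1.6), (5.5, 0.7))


class GenerationError(RuntimeError):
    pass


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study; a pure function input for
    :func:`generate` (same config -> identical output)."""

    n_participants: int = 24
    meals_per_participant: int = 2
    menu_table: dict[tuple[str, int], tuple[MenuItem, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MENUS)
    )
    #: (p_exact, p_far, p_intrusion) per mode; for the semiautomated mode
    #: this is the *marginal* target after conditional correction.
    match_probs: dict[Mode, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MATCH_PROBS)
    )
    omission_rate: float = 0.02
    #: log-scale (mu, sigma) per (mode, group); mu defaults derived from
    #: DEFAULT_BIAS_RATIO so that E[estimated/weighed] equals the ratio.
    energy_error: dict[Mode, dict[int, tuple[float, float]]] = field(
        default_factory=lambda: {
            mode: {
                g: (
                    math.log(DEFAULT_BIAS_RATIO[mode][g])
                    - DEFAULT_SIGMA[mode][g] ** 2 / 2.0,
                    DEFAULT_SIGMA[mode][g],
                )
                for g in range(1, 10)
            }
            for mode in Mode
        }
    )
    #: "multiplicative" (log-normal, proportional bias) or "additive"
    #: (kcal-scale normal offset, for null testing of proportional bias).
    error_model: str = "multiplicative"
    #: probability that a correct automated entry is left unchanged.
    semiautomated_coupling: float = 0.8
    seed: int = 0
    # survey response model; None -> uniform sampling within range
    csuq_item_mean: Optional[float] = 2.4
    csuq_item_sd: float = 0.9
    csuq_participant_sd: float = 0.2
    uss_question_means: Optional[tuple[tuple[float, float], ...]] = DEFAULT_USS_MEANS

    def check(self) -> None:
        for mode, probs in self.match_probs.items():
            if len(probs) != 3 or any(p < 0 for p in probs):
                raise ValueError(f"{mode.value}: bad match probability vector")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{mode.value}: match probabilities must sum to 1")
        for mode, per_group in self.energy_error.items():
            for g, (mu, sigma) in per_group.items():
                if sigma < 0:
                    raise ValueError(f"{mode.value} group {g}: sigma < 0")
        if not 0 <= self.omission_rate < 1:
            raise ValueError("omission_rate must be in [0, 1)")
        if not 0 <= self.semiautomatic_resample_exact() <= 1:
            raise ValueError(
                "semiautomated target exact probability is unreachable given "
                "the automated probabilities and coupling"
            )
        for (mtype, target), items in self.menu_table.items():
            total = sum(i.kcal for i in items)
            if abs(total - target) > 1e-6:
                raise ValueError(
                    f"menu ({mtype}, {target}): item kcal sum to {total}"
                )
            for item in items:
                parse_fndds_code(item.code)

    def semiautomatic_resample_exact(self) -> float:
        """Exact-probability of the internal resampling distribution.

        Derived so the marginal semiautomated exact fraction equals the
        configured target:  p_t = c*q + (1 - c*q) * r.
        """
        q = self.match_probs[Mode.AUTOMATED][0]
        p_t = self.match_probs[Mode.SEMIAUTOMATED][0]
        kept = self.semiautomated_coupling * q
        if kept >= 1.0:
            return 0.0
        return (p_t - kept) / (1.0 - kept)

    def _resample_probs(self) -> tuple[float, float, float]:
        r_exact = self.semiautomatic_resample_exact()
        _, far_t, intr_t = self.match_probs[Mode.SEMIAUTOMATED]
        rest = far_t + intr_t
        if rest == 0:
            return (r_exact, (1 - r_exact), 0.0) if r_exact < 1 else (1.0, 0.0, 0.0)
        return (
            r_exact,
            (1 - r_exact) * far_t / rest,
            (1 - r_exact) * intr_t / rest,
        )

    def n_distinct_foods(self) -> int:
        return len({i.name for items in self.menu_table.values() for i in items})


def default_study_config(seed: int = 0) -> GeneratorConfig:
    """The default study conditions (24 participants, 10 menus, ~260 items)."""
    cfg = GeneratorConfig(seed=seed)
    cfg.check()
    return cfg


@dataclass(frozen=True)
class CodePool:
    """Candidate logged codes per served code, by match category."""

    far: dict[str, tuple[FnddsCode, ...]]
    intrusion: dict[str, tuple[FnddsCode, ...]]

    @classmethod
    def build(cls, codes: list[str], n_candidates: int = 3) -> "CodePool":
        far: dict[str, tuple[FnddsCode, ...]] = {}
        intr: dict[str, tuple[FnddsCode, ...]] = {}
        for code in codes:
            code = parse_fndds_code(code)
            head, tail = code[0], int(code[1:])
            far[code] = tuple(
                FnddsCode(head + f"{(tail + k * 1111111) % 10**7:07d}")
                for k in range(1, n_candidates + 1)
            )
            d = int(head)
            intr[code] = tuple(
                FnddsCode(str((d - 1 + k) % 9 + 1) + code[1:])
                for k in range(1, n_candidates + 1)
            )
        return cls(far=far, intrusion=intr)


def _draw_kcal(
    rng: np.random.Generator,
    weighed: float,
    mu: float,
    sigma: float,
    model: str,
) -> float:
    if model == "multiplicative":
        return weighed * math.exp(mu + sigma * rng.standard_normal())
    if model == "additive":
        return max(0.0, weighed + mu + sigma * rng.standard_normal())
    raise ValueError(f"unknown error model {model!r}")


def _likert(rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), lo, hi))


def generate(config: GeneratorConfig) -> tuple[StudyDataset, SurveyResponses]:
    """Generate a seeded study dataset plus survey responses.

    Deterministic: the output is a pure function of the config
    (including its seed).
    """
    config.check()
    rng = np.random.default_rng(config.seed)
    menus = list(config.menu_table.keys())
    pool = CodePool.build([i.code for items in config.menu_table.values() for i in items])
    resample = config._resample_probs()
    p_auto = config.match_probs[Mode.AUTOMATED]

    items: list[ItemRecord] = []
    participants = []
    for p in range(1, config.n_participants + 1):
        pid = f"P{p:02d}"
        participants.append({"id": pid})
        chosen = rng.choice(
            len(menus), size=config.meals_per_participant, replace=False
        )
        for m, menu_idx in enumerate(chosen, start=1):
            menu_type, variant = menus[menu_idx]
            meal_id = f"{pid}-m{m}"
            for item in config.menu_table[(menu_type, variant)]:
                served = parse_fndds_code(item.code)
                group = major_group(served).id
                rec_kw = dict(
                    participant_id=pid,
                    meal_id=meal_id,
                    menu_type=menu_type,
                    menu_variant_kcal=variant,
                    item_id=item.name.replace(" ", "_"),
                    item_name=item.name,
                    served_code=served,
                    weighed_kcal=float(item.kcal),
                    weighed_grams=round(item.kcal * 0.7, 1),
                    is_beverage=item.is_beverage,
                )

                if rng.random() < config.omission_rate:
                    # item-level omission: never scanned (60%) or no
                    # nutrient data for the logged food (40%)
                    if rng.random() < 0.6:
                        auto = LogEntry(Mode.AUTOMATED, scanned=False)
                        semi = LogEntry(Mode.SEMIAUTOMATED, scanned=False)
                    else:
                        auto = LogEntry(
                            Mode.AUTOMATED, logged_code=served,
                            nutrient_available=False,
                        )
                        semi = LogEntry(
                            Mode.SEMIAUTOMATED, logged_code=served,
                            nutrient_available=False,
                        )
                    items.append(ItemRecord(automated=auto, semiautomated=semi, **rec_kw))
                    continue

                cat_auto = rng.choice(3, p=p_auto)
                code_auto = _pick_code(rng, pool, served, cat_auto)
                mu_a, sig_a = config.energy_error[Mode.AUTOMATED][group]
                kcal_auto = _draw_kcal(
                    rng, item.kcal, mu_a, sig_a, config.error_model
                )
                auto = LogEntry(
                    Mode.AUTOMATED, logged_code=code_auto, estimated_kcal=kcal_auto
                )

                if cat_auto == 0 and rng.random() < config.semiautomated_coupling:
                    semi = LogEntry(
                        Mode.SEMIAUTOMATED,
                        logged_code=code_auto,
                        estimated_kcal=kcal_auto,
                    )
                else:
                    cat_semi = rng.choice(3, p=resample)
                    code_semi = _pick_code(rng, pool, served, cat_semi)
                    mu_s, sig_s = config.energy_error[Mode.SEMIAUTOMATED][group]
                    kcal_semi = _draw_kcal(
                        rng, item.kcal, mu_s, sig_s, config.error_model
                    )
                    semi = LogEntry(
                        Mode.SEMIAUTOMATED,
                        logged_code=code_semi,
                        estimated_kcal=kcal_semi,
                    )
                items.append(ItemRecord(automated=auto, semiautomated=semi, **rec_kw))

    surveys = _generate_surveys(rng, config)
    return StudyDataset(items=items, participants=participants), surveys


def _pick_code(
    rng: np.random.Generator, pool: CodePool, served: FnddsCode, category: int
) -> FnddsCode:
    if category == 0:
        return served
    candidates = pool.far[served] if category == 1 else pool.intrusion[served]
    if not candidates:
        raise GenerationError(f"no candidate codes for served code {served}")
    return candidates[rng.integers(len(candidates))]


def _generate_surveys(
    rng: np.random.Generator, config: GeneratorConfig
) -> SurveyResponses:
    out = SurveyResponses()
    for p in range(1, config.n_participants + 1):
        pid = f"P{p:02d}"
        if config.csuq_item_mean is None:
            out.csuq[pid] = [int(rng.integers(1, 8)) for _ in range(19)]
        else:
            effect = rng.normal(0.0, config.csuq_participant_sd)
            out.csuq[pid] = [
                _likert(rng, config.csuq_item_mean + effect, config.csuq_item_sd, 1, 7)
                for _ in range(19)
            ]
        if config.uss_question_means is None:
            out.uss[pid] = [int(rng.integers(1, 7)) for _ in range(5)]
        else:
            out.uss[pid] = [
                _likert(rng, mean, sd, 1, 6)
                for mean, sd in config.uss_question_means
            ]
    return out


#: The four worked-example pairs: a cheeseburger logged as itself (exact),
#: as a turkey burger (far), as a croissant sandwich (intrusion), and
#: never scanned (omission).
WORKED_EXAMPLES = (
    ("exact", "Cheeseburger", "27510170"),
    ("far", "Turkey burger", "27545110"),
    ("intrusion", "Croissant sandwich", "58127310"),
    ("omission", None, None),
)


def inject_worked_examples(ds: StudyDataset) -> StudyDataset:
    """Append the four labeled reference pairs as fixture items."""
    served = parse_fndds_code("27510170")
    extra = []
    for label, logged_name, logged_code in WORKED_EXAMPLES:
        if logged_code is None:
            auto = LogEntry(Mode.AUTOMATED, scanned=False)
            semi = LogEntry(Mode.SEMIAUTOMATED, scanned=False)
        else:
            auto = LogEntry(
                Mode.AUTOMATED,
                logged_code=parse_fndds_code(logged_code),
                estimated_kcal=300.0,
            )
            semi = LogEntry(
                Mode.SEMIAUTOMATED, logged_code=served, estimated_kcal=300.0
            )
        extra.append(
            ItemRecord(
                participant_id="EXAMPLE",
                meal_id="worked-examples",
                menu_type="hamburger",
                menu_variant_kcal=500,
                item_id=f"example_{label}",
                item_name="Cheeseburger",
                served_code=served,
                weighed_kcal=300.0,
                automated=auto,
                semiautomated=semi,
            )
        )
    return StudyDataset(items=ds.items + extra, participants=ds.participants)


def config_to_dict(config: GeneratorConfig) -> dict:
    """JSON/YAML-safe representation (used for provenance hashing)."""
    d = asdict(config)
    d["menu_table"] = {
        f"{mtype}:{target}": [asdict(i) for i in items]
        for (mtype, target), items in config.menu_table.items()
    }
    d["match_probs"] = {
        mode.value: list(probs) for mode, probs in config.match_probs.items()
    }
    d["energy_error"] = {
        mode.value: {str(g): list(ms) for g, ms in per_group.items()}
        for mode, per_group in config.energy_error.items()
    }
    if d["uss_question_means"] is not None:
        d["uss_question_means"] = [list(q) for q in d["uss_question_means"]]
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    kw = dict(d)
    if "menu_table" in kw:
        table = {}
        for key, items in kw["menu_table"].items():
            mtype, target = key.rsplit(":", 1)
            table[(mtype, int(target))] = tuple(MenuItem(**i) for i in items)
        kw["menu_table"] = table
    if "match_probs" in kw:
        kw["match_probs"] = {
            Mode(mode): tuple(probs) for mode, probs in kw["match_probs"].items()
        }
    if "energy_error" in kw:
        kw["energy_error"] = {
            Mode(mode): {int(g): tuple(ms) for g, ms in per_group.items()}
            for mode, per_group in kw["energy_error"].items()
        }
    if kw.get("uss_question_means") is not None:
        kw["uss_question_means"] = tuple(tuple(q) for q in kw["uss_question_means"])
    cfg = GeneratorConfig(**kw)
    cfg.check()
    return cfg
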