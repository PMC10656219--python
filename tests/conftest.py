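import pytest

from mealaudit import (
    LogEntry,
    ItemRecord,
    Mode,
    StudyDataset,
    default_study_config,
    generate,
    parse_fndds_code,
)


def make_item(
    served="27510170",
    auto_code="27510170",
    semi_code="27510170",
    weighed=100.0,
    auto_kcal=100.0,
    semi_kcal=100.0,
    pid="P01",
    meal="P01-m1",
    item_id="item1",
    name="Cheeseburger",
    menu_type="hamburger",
    variant=500,
    beverage=False,
    auto_scanned=True,
    auto_available=True,
    semi_available=True,
):
    """Convenience constructor for one ItemRecord in tests."""
    auto = LogEntry(
        Mode.AUTOMATED,
        logged_code=parse_fndds_code(auto_code) if auto_code and auto_scanned else None,
        estimated_kcal=auto_kcal if auto_code and auto_scanned and auto_available else None,
        scanned=auto_scanned,
        nutrient_available=auto_available,
    )
    semi = LogEntry(
        Mode.SEMIAUTOMATED,
        logged_code=parse_fndds_code(semi_code) if semi_code and auto_scanned else None,
        estimated_kcal=semi_kcal if semi_code and auto_scanned and semi_available else None,
        scanned=auto_scanned,
        nutrient_available=semi_available,
    )
    return ItemRecord(
        participant_id=pid,
        meal_id=meal,
        menu_type=menu_type,
        menu_variant_kcal=variant,
        item_id=item_id,
        item_name=name,
        served_code=parse_fndds_code(served),
        weighed_kcal=weighed,
        is_beverage=beverage,
        automated=auto,
        semiautomated=semi,
    )


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (24 participants), shared read-only."""
    cfg = default_study_config(seed=7)
    ds, surveys = generate(cfg)
    return cfg, ds, surveys


@pytest.fixture()
def empty_dataset():
    return StudyDataset()
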