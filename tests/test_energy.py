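import math

import numpy as np
import pytest

from mealaudit import (
    Mode,
    StudyDataset,
    elevation_of_means,
    meal_totals,
    percent_error,
    summarize_by_food_group,
    summarize_by_menu_type,
    summarize_overall,
)
from mealaudit.energy import MealEnergy

from conftest import make_item


def _meal(w, a, s, menu="hamburger", pid="P01", mid="m1"):
    return MealEnergy(
        participant_id=pid, meal_id=mid, menu_type=menu, n_items=1,
        weighed_kcal_total=w, auto_kcal_total=a, semi_kcal_total=s,
    )


class TestPercentError:
    @pytest.mark.parametrize(
        "est,weighed,expected", [(100, 100, 0.0), (150, 100, 50.0), (75, 100, -25.0)]
    )
    def test_signed_percentage(self, est, weighed, expected):
        assert percent_error(est, weighed) == expected

    def test_zero_weighed_undefined(self):
        assert math.isnan(percent_error(50, 0))

    def test_scale_invariance(self):
        for k in (0.5, 3.0, 117.0):
            assert percent_error(150 * k, 100 * k) == pytest.approx(50.0)


class TestMealTotals:
    def test_direct_arithmetic(self):
        items = [
            make_item(item_id="a", weighed=100, auto_kcal=150, semi_kcal=100),
            make_item(item_id="b", weighed=200, auto_kcal=250, semi_kcal=200),
        ]
        [m] = meal_totals(StudyDataset(items=items))
        assert (m.weighed_kcal_total, m.auto_kcal_total) == (300, 400)
        assert m.pct_error_auto == pytest.approx(100 / 3)
        assert not m.within_25_auto
        assert m.pct_error_semi == 0.0 and m.within_10_semi

    def test_bound_edge_is_closed(self):
        [m] = meal_totals(
            StudyDataset(items=[make_item(weighed=100, auto_kcal=125)])
        )
        assert m.pct_error_auto == 25.0 and m.within_25_auto

    def test_item_omitted_in_either_mode_dropped_from_all_totals(self):
        items = [
            make_item(item_id="a", weighed=100, auto_kcal=110, semi_kcal=105),
            make_item(item_id="b", weighed=50, auto_scanned=False),
            make_item(item_id="c", weighed=70, semi_available=False),
        ]
        [m] = meal_totals(StudyDataset(items=items))
        assert m.n_items == 1
        assert m.weighed_kcal_total == 100  # b and c excluded everywhere

    def test_conservation_over_included_items(self, default_study):
        _, ds, _ = default_study
        meals = {(m.participant_id, m.meal_id): m for m in meal_totals(ds)}
        sums: dict = {}
        for rec in ds.items:
            if rec.automated.is_omission or rec.semiautomated.is_omission:
                continue
            acc = sums.setdefault((rec.participant_id, rec.meal_id), [0.0, 0.0, 0.0])
            acc[0] += rec.weighed_kcal
            acc[1] += rec.automated.estimated_kcal
            acc[2] += rec.semiautomated.estimated_kcal
        assert set(sums) == set(meals)
        for key, (w, a, s) in sums.items():
            assert meals[key].weighed_kcal_total == pytest.approx(w)
            assert meals[key].auto_kcal_total == pytest.approx(a)
            assert meals[key].semi_kcal_total == pytest.approx(s)

    def test_beverage_exclusion_changes_totals(self):
        items = [
            make_item(item_id="food", weighed=100),
            make_item(item_id="bev", weighed=50, beverage=True),
        ]
        ds = StudyDataset(items=items)
        [with_bev] = meal_totals(ds, include_beverages=True)
        [no_bev] = meal_totals(ds, include_beverages=False)
        assert with_bev.weighed_kcal_total == 150
        assert no_bev.weighed_kcal_total == 100


class TestElevationOfMeans:
    @pytest.mark.parametrize(
        "w_mean,e_mean,expected", [(577, 826, 43.15), (481, 560, 16.42)]
    )
    def test_from_mean_levels(self, w_mean, e_mean, expected):
        meals = [_meal(w_mean, e_mean, e_mean, mid=f"m{i}") for i in range(3)]
        assert elevation_of_means(meals, Mode.AUTOMATED) == pytest.approx(
            expected, abs=0.01
        )

    def test_equal_means_zero(self):
        meals = [_meal(500, 500, 500)]
        assert elevation_of_means(meals, Mode.AUTOMATED) == 0.0

    def test_algebraic_identity_with_sums(self, default_study):
        """Elevation equals 100*(sum(est)-sum(weighed))/sum(weighed)."""
        _, ds, _ = default_study
        meals = meal_totals(ds)
        w = sum(m.weighed_kcal_total for m in meals)
        a = sum(m.auto_kcal_total for m in meals)
        assert elevation_of_means(meals, Mode.AUTOMATED) == pytest.approx(
            100 * (a - w) / w
        )

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            elevation_of_means([], Mode.AUTOMATED)


class TestSummaries:
    def test_mean_of_ratios_three_meals(self):
        meals = [
            _meal(100, 100, 100, mid="m1"),
            _meal(100, 150, 100, mid="m2"),
            _meal(100, 50, 100, mid="m3"),
        ]
        [s] = summarize_by_menu_type(meals)
        assert s.pct_error_auto_mean == pytest.approx(0.0)
        assert s.n_within_25_auto == 1
        assert s.n == 3

    def test_identical_meals_sd_zero(self):
        meals = [_meal(100, 120, 110, mid=f"m{i}") for i in range(4)]
        [s] = summarize_by_menu_type(meals)
        assert s.pct_error_auto_sd == 0.0
        assert s.weighed_sd == 0.0

    def test_single_meal_stratum_sd_undefined(self):
        [s] = summarize_by_menu_type([_meal(100, 120, 110)])
        assert math.isnan(s.weighed_sd)

    def test_mean_of_ratios_equals_ratio_of_means_on_constant_weighed(self):
        meals = [_meal(200, a, a, mid=f"m{i}") for i, a in enumerate((220, 260, 300))]
        [s] = summarize_by_menu_type(meals)
        elev = elevation_of_means(meals, Mode.AUTOMATED)
        assert s.pct_error_auto_mean == pytest.approx(elev)

    def test_overall_summary_counts(self, default_study):
        _, ds, _ = default_study
        meals = meal_totals(ds)
        s = summarize_overall(meals)
        assert s.n == len(meals)
        assert 0 <= s.n_within_10_auto <= s.n_within_25_auto <= s.n


class TestFoodGroupSummaries:
    def test_uniform_doubling_gives_100pct_error(self):
        items = [
            make_item(item_id=f"i{i}", weighed=w, auto_kcal=2 * w, semi_kcal=w)
            for i, w in enumerate((50, 80, 120))
        ]
        [s] = summarize_by_food_group(StudyDataset(items=items))
        assert s.pct_error_auto_mean == pytest.approx(100.0)
        assert s.pct_error_semi_mean == pytest.approx(0.0)

    def test_single_item_group(self):
        items = [make_item(weighed=86, auto_kcal=88, semi_kcal=88)]
        [s] = summarize_by_food_group(StudyDataset(items=items))
        assert s.pct_error_auto_mean == pytest.approx(2.3256, abs=1e-3)
        assert s.n_within_10_auto == 1

    def test_beverage_exclusion_shrinks_their_groups(self):
        items = [
            make_item(item_id="milk", served="11112210", name="1% milk",
                      beverage=True),
            make_item(item_id="cheese", served="14104100", name="cheddar"),
            make_item(item_id="tea", served="92510610", name="sweet tea",
                      beverage=True),
        ]
        with_bev = {
            s.stratum_label: s.n
            for s in summarize_by_food_group(StudyDataset(items=items))
        }
        without = {
            s.stratum_label: s.n
            for s in summarize_by_food_group(
                StudyDataset(items=items), include_beverages=False
            )
        }
        assert with_bev["milk and milk products"] == 2
        assert without["milk and milk products"] == 1
        assert "sugars, sweets, and beverages" not in without  # empty group skipped

    def test_zero_weighed_item_excluded_from_error_mean(self):
        items = [
            make_item(item_id="z", weighed=0.0, auto_kcal=10, semi_kcal=10),
            make_item(item_id="n", weighed=100.0, auto_kcal=150, semi_kcal=100),
        ]
        [s] = summarize_by_food_group(StudyDataset(items=items))
        assert s.n == 2
        assert s.pct_error_auto_mean == pytest.approx(50.0)


def test_scale_invariance_of_percent_errors(default_study):
    _, ds, _ = default_study
    meals = meal_totals(ds)
    scaled = [
        _meal(3 * m.weighed_kcal_total, 3 * m.auto_kcal_total, 3 * m.semi_kcal_total,
              menu=m.menu_type, pid=m.participant_id, mid=m.meal_id)
        for m in meals
    ]
    orig = np.array([m.pct_error_auto for m in meals])
    new = np.array([m.pct_error_auto for m in scaled])
    assert np.allclose(orig, new)
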