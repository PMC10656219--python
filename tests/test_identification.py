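import math

import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mealaudit import (
    LogEntry,
    MatchCategory,
    Mode,
    Stratifier,
    StudyDataset,
    classify_match,
    exclude_beverages,
    paired_proportions_test,
    parse_fndds_code,
    tabulate_matches,
)

from conftest import make_item

valid_codes = st.from_regex(r"[1-9][0-9]{7}", fullmatch=True)


def _entry(code=None, scanned=True, available=True, kcal=100.0):
    return LogEntry(
        Mode.AUTOMATED,
        logged_code=parse_fndds_code(code) if code else None,
        estimated_kcal=kcal if (code and scanned and available) else None,
        scanned=scanned,
        nutrient_available=available,
    )


class TestClassifyMatch:
    served = parse_fndds_code("27510170")

    @pytest.mark.parametrize(
        "logged,expected",
        [
            ("27510170", MatchCategory.EXACT),
            ("27545110", MatchCategory.FAR),
            ("58127310", MatchCategory.INTRUSION),
        ],
    )
    def test_code_hierarchy(self, logged, expected):
        assert classify_match(self.served, _entry(logged)) is expected

    def test_unscanned_is_omission(self):
        assert (
            classify_match(self.served, _entry(scanned=False))
            is MatchCategory.OMISSION
        )

    def test_no_nutrient_info_is_omission(self):
        entry = _entry("27510170", available=False)
        assert classify_match(self.served, entry) is MatchCategory.OMISSION

    @given(valid_codes)
    def test_self_match_is_exact(self, code):
        assert classify_match(parse_fndds_code(code), _entry(code)) is MatchCategory.EXACT

    @given(valid_codes, valid_codes)
    def test_partition_exclusive_exhaustive(self, served, logged):
        cat = classify_match(parse_fndds_code(served), _entry(logged))
        if served == logged:
            assert cat is MatchCategory.EXACT
        elif served[0] == logged[0]:
            assert cat is MatchCategory.FAR
        else:
            assert cat is MatchCategory.INTRUSION


class TestTabulate:
    def test_fixture_counts_and_percentages(self):
        # 3 exact, 3 far, 2 intrusion, 1 omission -> 8 classified
        items = (
            [make_item(item_id=f"e{i}") for i in range(3)]
            + [make_item(item_id=f"f{i}", auto_code="27545110") for i in range(3)]
            + [make_item(item_id=f"i{i}", auto_code="58127310") for i in range(2)]
            + [make_item(item_id="o0", auto_scanned=False)]
        )
        [t] = tabulate_matches(StudyDataset(items=items), Mode.AUTOMATED)
        assert (t.n_classified, t.n_exact, t.n_far, t.n_intrusion, t.n_omitted) == (
            8, 3, 3, 2, 1,
        )
        assert (t.pct_exact, t.pct_far, t.pct_intrusion) == (37.5, 37.5, 25.0)
        assert t.pct_exact + t.pct_far + t.pct_intrusion == pytest.approx(100.0)

    def test_all_exact(self):
        items = [make_item(item_id=f"x{i}") for i in range(5)]
        [t] = tabulate_matches(StudyDataset(items=items), Mode.AUTOMATED)
        assert (t.pct_exact, t.pct_far, t.pct_intrusion) == (100.0, 0.0, 0.0)

    def test_empty_stratum_is_nan_not_crash(self, empty_dataset):
        assert tabulate_matches(empty_dataset, Mode.AUTOMATED) == []
        items = [make_item(auto_scanned=False)]
        [t] = tabulate_matches(StudyDataset(items=items), Mode.AUTOMATED)
        assert t.n_classified == 0 and math.isnan(t.pct_exact)

    def test_brute_force_oracle_on_random_fixture(self, default_study):
        """Tabulated counts equal direct counting of classify_match calls."""
        _, ds, _ = default_study
        for mode in Mode:
            for strat in Stratifier:
                tables = tabulate_matches(ds, mode, strat)
                direct = {}
                for rec in ds.items:
                    if strat is Stratifier.OVERALL:
                        key = "overall"
                    elif strat is Stratifier.BY_MEAL_TYPE:
                        key = rec.menu_type
                    else:
                        key = rec.served_code.group.label
                    cat = classify_match(rec.served_code, rec.entry(mode))
                    direct.setdefault(key, {c: 0 for c in MatchCategory})
                    direct[key][cat] += 1
                for t in tables:
                    d = direct[t.stratum_label]
                    assert t.n_exact == d[MatchCategory.EXACT]
                    assert t.n_far == d[MatchCategory.FAR]
                    assert t.n_intrusion == d[MatchCategory.INTRUSION]
                    assert t.n_omitted == d[MatchCategory.OMISSION]
                    assert (
                        t.n_classified
                        == t.n_exact + t.n_far + t.n_intrusion
                    )


class TestExcludeBeverages:
    def test_counts(self):
        items = [make_item(item_id=f"b{i}", beverage=True) for i in range(3)] + [
            make_item(item_id=f"f{i}") for i in range(4)
        ]
        ds = StudyDataset(items=items)
        out = exclude_beverages(ds)
        assert len(out) == 4
        assert len(ds) == 7  # original untouched

    def test_no_beverages_identity(self):
        ds = StudyDataset(items=[make_item()])
        assert exclude_beverages(ds).items == ds.items

    def test_all_beverages_empty(self):
        ds = StudyDataset(items=[make_item(beverage=True)])
        assert len(exclude_beverages(ds)) == 0


def _discordant_dataset(b, c, concordant=5):
    """b items exact under automated only, c under semiautomated only."""
    items = [
        make_item(item_id=f"b{i}", semi_code="27545110") for i in range(b)
    ] + [
        make_item(item_id=f"c{i}", auto_code="27545110") for i in range(c)
    ] + [
        make_item(item_id=f"n{i}") for i in range(concordant)
    ]
    return StudyDataset(items=items)


class TestPairedProportions:
    def test_no_discordance_degenerate(self):
        res = paired_proportions_test(_discordant_dataset(0, 0), MatchCategory.EXACT)
        assert res.p_value == 1.0 and res.degenerate

    def test_one_sided_discordance(self):
        res = paired_proportions_test(_discordant_dataset(0, 5), MatchCategory.EXACT)
        assert res.p_value == pytest.approx(0.0625)
        assert (res.b, res.c) == (0, 5)

    def test_symmetric_discordance(self):
        res = paired_proportions_test(_discordant_dataset(10, 10), MatchCategory.EXACT)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("b", range(0, 13))
    def test_exact_mcnemar_matches_binomial_enumeration(self, b):
        """Exact p equals brute-force enumeration of the Bin(b+c, 1/2) null."""
        for c in range(0, 13 - b):
            if b + c == 0:
                continue
            res = paired_proportions_test(
                _discordant_dataset(b, c), MatchCategory.EXACT, method="exact"
            )
            n = b + c
            pmf = [stats.binom.pmf(k, n, 0.5) for k in range(n + 1)]
            expected = sum(p for p in pmf if p <= pmf[b] * (1 + 1e-9))
            assert res.p_value == pytest.approx(min(1.0, expected), rel=1e-8)

    def test_chi_square_method_recorded(self):
        res = paired_proportions_test(
            _discordant_dataset(20, 20), MatchCategory.EXACT, method="chi2"
        )
        assert "chi-square" in res.method
        assert 0 <= res.p_value <= 1

    def test_omitted_items_excluded_from_pairs(self):
        ds = _discordant_dataset(0, 5)
        ds.items.append(make_item(item_id="omit", auto_scanned=False))
        res = paired_proportions_test(ds, MatchCategory.EXACT)
        assert res.n_pairs == 10  # 5 discordant + 5 concordant
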