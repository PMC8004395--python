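"""FSA-NPS scoring, diet index, meal quality and dietary derived variables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietmg.diet_quality import (
    aggregate_intake,
    excess_fructose,
    filter_implausible_energy,
    fodmap_outlier_mask,
    fsanps_class,
    fsanps_diet_index,
    fsanps_item_score,
    load_default_grids,
    meal_quality_profile,
    score_food_db,
)

GRIDS = load_default_grids()

BEST = {
    "energy_kj": 0, "sugars_g": 0, "saturated_fat_g": 0, "sodium_mg": 0,
    "fiber_g": 50, "protein_g": 50, "fruit_veg_pct": 100,
}
WORST = {
    "energy_kj": 4000, "sugars_g": 60, "saturated_fat_g": 20, "sodium_mg": 2000,
    "fiber_g": 0, "protein_g": 0, "fruit_veg_pct": 0,
}


def oracle_score(comp):
    """Independent brute-force grid lookup."""
    total = 0
    for name, (bp, pts) in GRIDS.unfavorable.items():
        got = 0
        for b, p in zip(bp, pts):
            if comp[name] > b:
                got = p
        total += got
    for name, (bp, pts) in GRIDS.favorable.items():
        got = 0
        for b, p in zip(bp, pts):
            if comp[name] > b:
                got = p
        total -= got
    return total


class TestItemScore:
    def test_extremes(self):
        assert fsanps_item_score(BEST, grids=GRIDS) == -15
        assert fsanps_item_score(WORST, grids=GRIDS) == 40

    def test_mid_grid_case_matches_oracle(self):
        comp = {
            "energy_kj": 1500, "sugars_g": 12.0, "saturated_fat_g": 3.5,
            "sodium_mg": 400, "fiber_g": 2.0, "protein_g": 5.0, "fruit_veg_pct": 50,
        }
        # hand lookup: energy 4, sugars 2, satfat 3, sodium 4 (=13);
        # fiber 2, protein 3, fruit/veg 1 (=6) -> 7
        assert fsanps_item_score(comp, grids=GRIDS) == 7 == oracle_score(comp)

    @settings(max_examples=200, deadline=None)
    @given(
        e=st.floats(0, 4000), su=st.floats(0, 60), sa=st.floats(0, 20),
        so=st.floats(0, 2000), fi=st.floats(0, 15), pr=st.floats(0, 40),
        fv=st.floats(0, 100),
    )
    def test_score_within_bounds_and_matches_oracle(self, e, su, sa, so, fi, pr, fv):
        comp = {
            "energy_kj": e, "sugars_g": su, "saturated_fat_g": sa,
            "sodium_mg": so, "fiber_g": fi, "protein_g": pr, "fruit_veg_pct": fv,
        }
        s = fsanps_item_score(comp, grids=GRIDS)
        assert -15 <= s <= 40
        assert s == oracle_score(comp)

    def test_negative_nutrient_raises(self):
        bad = dict(BEST, sugars_g=-1)
        with pytest.raises(ValueError):
            fsanps_item_score(bad, grids=GRIDS)


class TestClasses:
    @pytest.mark.parametrize(
        "score,is_drink,expected",
        [(2, False, "B"), (2, True, "C"), (-15, False, "A"), (-15, True, "A"),
         (40, False, "E"), (40, True, "E"), (0, False, "B"), (-1, False, "A"),
         (9, True, "E"), (17, False, "D")],
    )
    def test_thresholds(self, score, is_drink, expected):
        assert fsanps_class(score, is_drink) == expected

    def test_monotone_in_score(self):
        order = "ABCDE"
        for drink in (False, True):
            prev = 0
            for s in range(-15, 41):
                cur = order.index(fsanps_class(s, drink))
                assert cur >= prev
                prev = cur

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fsanps_class(41, False)
        with pytest.raises(ValueError):
            fsanps_class(-16, True)


class TestDietIndex:
    def _diary(self, items, grams):
        return pd.DataFrame(
            {"subject": "s", "day": 1, "meal": "lunch", "is_main": True,
             "item": items, "grams": grams}
        )

    def test_single_item_returns_its_score(self):
        d = self._diary(["x"], [100.0])
        assert fsanps_diet_index(d, {"x": 7}, {"x": 250.0}) == 7.0

    def test_equal_energy_average(self):
        d = self._diary(["x", "y"], [100.0, 100.0])
        di = fsanps_diet_index(d, {"x": 0, "y": 10}, {"x": 200.0, "y": 200.0})
        assert di == 5.0

    def test_three_to_one_energy_weighting(self):
        d = self._diary(["x", "y"], [300.0, 100.0])
        di = fsanps_diet_index(d, {"x": 4, "y": 8}, {"x": 100.0, "y": 100.0})
        assert di == pytest.approx(5.0)

    def test_splitting_a_portion_leaves_index_unchanged(self):
        d1 = self._diary(["x", "y"], [200.0, 100.0])
        d2 = self._diary(["x", "x", "y"], [100.0, 100.0, 100.0])
        s, e = {"x": 3, "y": 9}, {"x": 150.0, "y": 300.0}
        assert fsanps_diet_index(d1, s, e) == pytest.approx(fsanps_diet_index(d2, s, e))

    def test_zero_energy_raises(self):
        d = self._diary(["x"], [100.0])
        with pytest.raises(ValueError):
            fsanps_diet_index(d, {"x": 3}, {"x": 0.0})


class TestMealQuality:
    def _diary(self, classes_main, classes_snack=()):
        rows = []
        for i, c in enumerate(classes_main):
            rows.append({"subject": "s", "day": 1, "meal": "lunch",
                         "is_main": True, "item": f"m{i}", "grams": 100.0})
        for i, c in enumerate(classes_snack):
            rows.append({"subject": "s", "day": 1, "meal": "snack1",
                         "is_main": False, "item": f"s{i}", "grams": 50.0})
        classes = {f"m{i}": c for i, c in enumerate(classes_main)}
        classes.update({f"s{i}": c for i, c in enumerate(classes_snack)})
        return pd.DataFrame(rows), pd.Series(classes)

    def test_all_a_main_meals_have_zero_low_quality(self):
        d, cls = self._diary(["A", "A", "A"])
        prof = meal_quality_profile(d, cls)
        assert prof["prevalence"]["E"] == 0.0
        assert prof["counts"]["A"] == 3

    def test_five_a_one_e_ratio(self):
        d, cls = self._diary(["A"] * 5 + ["E"])
        assert meal_quality_profile(d, cls)["ratio"] == 5.0

    def test_snack_toggle_changes_counts(self):
        d, cls = self._diary(["A", "A"], ["E", "E"])
        main_only = meal_quality_profile(d, cls, include_snacks=False)
        with_snacks = meal_quality_profile(d, cls, include_snacks=True)
        assert main_only["counts"]["E"] == 0
        assert with_snacks["counts"]["E"] == 2

    def test_no_main_meals_raises(self):
        d, cls = self._diary([], ["E"])
        with pytest.raises(ValueError):
            meal_quality_profile(d, cls)


class TestDerivedVariables:
    def test_excess_fructose_rule(self):
        assert excess_fructose(3.0, 8.0) == 0.0  # glucose 5 > fructose
        assert excess_fructose(5.0, 8.0) == 2.0
        assert excess_fructose(4.0, 8.0) == 0.0  # boundary: fructose == glucose
        with pytest.raises(ValueError):
            excess_fructose(9.0, 8.0)

    def test_fodmap_outliers(self):
        assert not fodmap_outlier_mask([5.0] * 10).any()
        v = [0.0] * 20 + [100.0]
        mask = fodmap_outlier_mask(v)
        assert mask[-1] and mask.sum() == 1
        sym = np.concatenate([np.zeros(50), [30.0, -30.0]])
        m = fodmap_outlier_mask(sym)
        assert m[-1] and m[-2] and m.sum() == 2

    def test_energy_filter_boundaries(self):
        db = pd.DataFrame({"energy_kcal": [100.0]}, index=["x"])

        def diary(total_daily_g):
            return pd.DataFrame(
                {"subject": "s", "day": [1, 2, 3, 4], "meal": "lunch",
                 "is_main": True, "item": "x", "grams": total_daily_g}
            )

        for grams, keep in ((700.0, False), (800.0, True), (5000.0, False), (4500.0, True)):
            kept, rep = filter_implausible_energy(diary([grams] * 4), db)
            assert rep["excluded"].iloc[0] != keep
            assert kept.empty != keep

    def test_aggregate_intake_linearity_and_additivity(self, food_db):
        item = food_db.index[0]
        d = pd.DataFrame(
            {"subject": ["s", "s"], "day": [1, 1], "meal": ["lunch", "dinner"],
             "is_main": True, "item": item, "grams": [200.0, 100.0]}
        )
        agg = aggregate_intake(d, food_db)
        per_meal = agg["per_meal"]
        assert per_meal.loc[("s", 1, "lunch"), "protein_g"] == pytest.approx(
            2.0 * food_db.loc[item, "protein_g"]
        )
        pd.testing.assert_series_equal(
            agg["per_day"].loc[("s", 1)], per_meal.groupby(level=0).sum().loc["s"],
            check_names=False,
        )
        with pytest.raises(KeyError):
            aggregate_intake(d.assign(item="unknown_item"), food_db)


def test_worst_quality_quartile_has_more_low_quality_main_meal_items(food_db, diaries_truth):
    """Directional check: subjects with a worse planted quality latent eat
    more low-quality (D/E) items in their main meals."""
    diaries, truth = diaries_truth
    scored = score_food_db(food_db)
    qual = truth.subject_latents["quality_score"]
    lows = {}
    for subj, d in diaries.groupby("subject"):
        prof = meal_quality_profile(d, scored["class"])
        lows[subj] = prof["prevalence"][["D", "E"]].sum()
    lows = pd.Series(lows)
    worst = lows[qual >= qual.quantile(0.75)].mean()
    best = lows[qual <= qual.quantile(0.25)].mean()
    assert worst > best
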