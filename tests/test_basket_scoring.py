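import math

import numpy as np
import pytest

from foptrial.basket_scoring import (
    DomainError,
    average_nutriscore,
    component_intakes,
    modified_ahei,
    nutrient_summaries,
    per_day_per_person,
    score_orders,
    sodium_decile_cutpoints,
    sodium_decile_score,
)
from foptrial.catalog import Catalog, Condition
from foptrial.label_engines import NutriScoreResult, ScoringError

from conftest import make_order, make_participant, make_product

#: reference cohort sodium decile cut points (mg/person-day)
COHORT_SODIUM = list(range(100, 1000, 100))


def grade(letter):
    points = {"A": -5, "B": 0, "C": 5, "D": 15, "E": 25}[letter]
    return NutriScoreResult(max(points, 0), 0, points, letter)


def perfect_product():
    """One serving pushes every adequacy component past its optimal anchor
    when 35 servings/week are bought by a one-adult household."""
    return make_product(
        "GOOD",
        price=2.0,
        servings_per_pack=7.0,
        energy_kcal_per_100g=50.0,
        yields={
            "vegetables_servings": 1.0,   # 35/wk -> 5/day
            "fruit_servings": 0.8,        # -> 4/day
            "whole_grain_g": 18.0,        # -> 90 g/day
            "nuts_legumes_servings": 0.2, # -> 1/day
            "long_chain_n3_mg": 50.0,     # -> 250 mg/day
        },
    )


def worst_product():
    """One serving per day of this hits every worst anchor (14 servings/wk,
    two per day, for a one-adult household)."""
    return make_product(
        "BAD",
        price=2.0,
        servings_per_pack=7.0,
        energy_kcal_per_100g=100.0,  # 100 kcal/serving
        transfat_g_per_100g=0.5,
        fat_g_per_100g=1.0,
        yields={
            "ssb_juice_servings": 0.5,              # -> 1/day
            "red_processed_meat_servings": 0.75,    # -> 1.5/day
            "transfat_g": 0.5,                      # 4.5 kcal of 100 -> 4.5 % energy
            "sodium_mg": 2000.0,
        },
    )


class TestPerDayPerPerson:
    def test_arithmetic(self):
        assert per_day_per_person({"kcal": 2800.0}, 2)["kcal"] == pytest.approx(200.0)

    def test_single_adult_divides_by_seven(self):
        assert per_day_per_person({"x": 7.0}, 1)["x"] == pytest.approx(1.0)

    def test_homogeneity(self):
        a = per_day_per_person({"x": 100.0}, 1)
        b = per_day_per_person({"x": 200.0}, 2)
        assert a == b

    def test_rejects_zero_adults(self):
        with pytest.raises(DomainError):
            per_day_per_person({"x": 1.0}, 0)


class TestModifiedAhei:
    def test_perfect_basket_scores_90(self):
        catalog = Catalog([perfect_product()])
        order = make_order([("GOOD", 5)])  # 35 servings
        score, components = modified_ahei(order, catalog, 1, COHORT_SODIUM)
        assert score == pytest.approx(90.0)
        assert len(components) == 9
        assert all(c.score == pytest.approx(10.0) for c in components)

    def test_worst_basket_scores_0(self):
        catalog = Catalog([worst_product()])
        order = make_order([("BAD", 2)])  # 14 servings
        score, components = modified_ahei(order, catalog, 1, COHORT_SODIUM)
        assert score == pytest.approx(0.0)
        assert all(c.score == pytest.approx(0.0) for c in components)

    def test_vegetable_interpolation_midpoint(self):
        # 2.5 servings/person-day of vegetables, everything else at worst
        product = worst_product().model_copy(deep=True)
        product.ahei_yields.vegetables_servings = 1.25  # x14 servings /7 = 2.5/day
        catalog = Catalog([product])
        score, components = modified_ahei(make_order([("BAD", 2)]), catalog, 1, COHORT_SODIUM)
        by_name = {c.component: c for c in components}
        assert by_name["vegetables"].intake == pytest.approx(2.5)
        assert by_name["vegetables"].score == pytest.approx(5.0)
        assert score == pytest.approx(5.0)

    def test_empty_order_scores_zero_intakes(self):
        catalog = Catalog([perfect_product()])
        score, components = modified_ahei(make_order([]), catalog, 1, COHORT_SODIUM)
        by_name = {c.component: c.score for c in components}
        # absence components are optimal at zero, adequacy components at floor
        assert by_name["ssb_juice"] == 10.0
        assert by_name["red_processed_meat"] == 10.0
        assert by_name["trans_fat"] == 10.0
        assert by_name["sodium"] == 10.0
        assert by_name["vegetables"] == 0.0
        assert score == pytest.approx(40.0)

    def test_missing_yields_raise(self):
        product = perfect_product().model_copy(update={"ahei_yields": None})
        with pytest.raises(ScoringError, match="GOOD"):
            modified_ahei(make_order([("GOOD", 1)]), Catalog([product]), 1, COHORT_SODIUM)

    def test_ssb_monotone_and_vegetables_monotone(self):
        base = worst_product().model_copy(deep=True)
        catalog = Catalog([base])
        ref, _ = modified_ahei(make_order([("BAD", 1)]), catalog, 1, COHORT_SODIUM)
        more_ssb = base.model_copy(deep=True)
        more_ssb.ahei_yields.ssb_juice_servings += 1.0
        worse, _ = modified_ahei(make_order([("BAD", 1)]), Catalog([more_ssb]), 1, COHORT_SODIUM)
        assert worse <= ref
        more_veg = base.model_copy(deep=True)
        more_veg.ahei_yields.vegetables_servings += 1.0
        better, _ = modified_ahei(make_order([("BAD", 1)]), Catalog([more_veg]), 1, COHORT_SODIUM)
        assert better >= ref

    def test_sodium_decile_scoring(self):
        cuts = sodium_decile_cutpoints(np.arange(1.0, 101.0))
        assert sodium_decile_score(0.5, cuts) == pytest.approx(10.0)
        assert sodium_decile_score(1000.0, cuts) == pytest.approx(0.0)
        assert sodium_decile_score(50.0, cuts) == pytest.approx(10.0 * 5 / 9, abs=1.2)


class TestAverageNutriScore:
    def test_all_grade_a_basket_is_5(self, rng):
        products = [make_product(f"A{i}", servings_per_pack=float(rng.integers(1, 9)))
                    for i in range(4)]
        catalog = Catalog(products)
        grades = {p.product_id: grade("A") for p in products}
        order = make_order([(p.product_id, int(rng.integers(1, 4))) for p in products])
        assert average_nutriscore(order, catalog, grades) == pytest.approx(5.0)

    def test_equal_servings_a_and_e_average_3(self):
        catalog = Catalog([make_product("A1", servings_per_pack=3.0),
                           make_product("E1", servings_per_pack=3.0)])
        grades = {"A1": grade("A"), "E1": grade("E")}
        order = make_order([("A1", 1), ("E1", 1)])
        assert average_nutriscore(order, catalog, grades) == pytest.approx(3.0)

    def test_weighted_mean_2a_1c(self):
        catalog = Catalog([make_product("A1", servings_per_pack=1.0),
                           make_product("C1", servings_per_pack=1.0)])
        grades = {"A1": grade("A"), "C1": grade("C")}
        order = make_order([("A1", 2), ("C1", 1)])
        assert average_nutriscore(order, catalog, grades) == pytest.approx(13.0 / 3.0)

    def test_empty_order_is_nan(self, small_catalog):
        grades = {pid: grade("A") for pid in small_catalog.product_ids}
        assert math.isnan(average_nutriscore(make_order([]), small_catalog, grades))

    def test_invariant_to_splitting_a_line(self):
        catalog = Catalog([make_product("A1"), make_product("C1")])
        grades = {"A1": grade("A"), "C1": grade("C")}
        merged = average_nutriscore(make_order([("A1", 4), ("C1", 1)]), catalog, grades)
        split = average_nutriscore(
            make_order([("A1", 2), ("C1", 1), ("A1", 2)]), catalog, grades
        )
        assert split == pytest.approx(merged)

    def test_missing_grade_raises(self):
        catalog = Catalog([make_product("A1")])
        with pytest.raises(ScoringError, match="A1"):
            average_nutriscore(make_order([("A1", 1)]), catalog, {})


class TestNutrientSummaries:
    def test_single_product_arithmetic(self):
        product = make_product("F1", price=4.0, servings_per_pack=2.0,
                               energy_kcal_per_100g=100.0, serving_size_g=100.0)
        s = nutrient_summaries(make_order([("F1", 1)]), Catalog([product]))
        assert s.totals["energy_kcal"] == pytest.approx(200.0)
        assert s.per_serving_means["energy_kcal"] == pytest.approx(100.0)
        assert s.kcal_per_dollar == pytest.approx(50.0)
        assert s.total_spend_sgd == pytest.approx(4.0)

    def test_empty_order(self, small_catalog):
        s = nutrient_summaries(make_order([]), small_catalog)
        assert all(v == 0.0 for v in s.totals.values())
        assert all(math.isnan(v) for v in s.per_serving_means.values())
        assert math.isnan(s.kcal_per_dollar)

    def test_matches_per_line_accumulation_oracle(self, rng):
        products = [
            make_product(
                f"P{i}",
                price=float(rng.uniform(1, 15)),
                servings_per_pack=float(rng.integers(1, 9)),
                energy_kcal_per_100g=float(rng.uniform(10, 500)),
                sugar_g_per_100g=float(rng.uniform(0, 40)),
                sodium_mg_per_100g=float(rng.uniform(0, 900)),
                serving_size_g=float(rng.uniform(20, 300)),
            )
            for i in range(20)
        ]
        catalog = Catalog(products)
        lines = [(f"P{i}", int(rng.integers(1, 5))) for i in range(20)]
        s = nutrient_summaries(make_order(lines), catalog)
        # independent accumulation, line by line
        expect_kcal = expect_servings = expect_spend = 0.0
        for pid, qty in lines:
            p = catalog[pid]
            sv = qty * p.servings_per_pack
            expect_servings += sv
            expect_spend += qty * p.price_sgd
            expect_kcal += sv * p.panel.energy_kcal_per_100g * p.panel.serving_size_g / 100
        assert s.totals["energy_kcal"] == pytest.approx(expect_kcal)
        assert s.n_servings == pytest.approx(expect_servings)
        assert s.total_spend_sgd == pytest.approx(round(expect_spend, 2))
        assert s.per_serving_means["energy_kcal"] == pytest.approx(expect_kcal / expect_servings)

    def test_permuting_lines_changes_nothing(self, small_catalog, rng):
        lines = [("F1", 2), ("B1", 1), ("B2", 3)]
        a = nutrient_summaries(make_order(lines), small_catalog)
        b = nutrient_summaries(make_order(lines[::-1]), small_catalog)
        assert a == b


class TestScoreOrders:
    def test_one_row_per_shop_with_outcomes(self, small_catalog):
        participants = [make_participant("P1", n_adults=2)]
        orders = [
            make_order([("F1", 5)], shop=1, condition=Condition.CONTROL,
                       post_shop_mood=3, post_shop_hunger=2),
            make_order([("F1", 3), ("B2", 4)], shop=2, condition=Condition.NS),
        ]
        frame = score_orders(orders, small_catalog, participants)
        assert len(frame) == 2
        assert set(["modified_ahei", "avg_nutriscore", "total_energy_kcal",
                    "kcal_per_dollar"]).issubset(frame.columns)
        assert frame["modified_ahei"].between(0, 90).all()
        assert frame["avg_nutriscore"].between(1, 5).all()

    def test_strata_are_additive(self, small_catalog):
        participants = [make_participant("P1")]
        orders = [make_order([("F1", 2), ("B1", 1), ("B2", 3)])]
        full = score_orders(orders, small_catalog, participants, stratum="all")
        foods = score_orders(orders, small_catalog, participants, stratum="foods")
        bevs = score_orders(orders, small_catalog, participants, stratum="beverages")
        for col in ("total_energy_kcal", "total_sugar_g", "total_sodium_mg",
                    "total_spend_sgd"):
            assert full[col][0] == pytest.approx(foods[col][0] + bevs[col][0])
        assert foods["modified_ahei"].isna().all()

    def test_beverage_only_basket_under_foods_stratum_is_empty(self, small_catalog):
        participants = [make_participant("P1")]
        orders = [make_order([("B1", 2)])]
        frame = score_orders(orders, small_catalog, participants, stratum="foods")
        assert frame["avg_nutriscore"].isna().all()
        assert frame["total_energy_kcal"][0] == 0.0
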