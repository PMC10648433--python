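"""Price adjustment, daily cost, replacement cost, and group summaries."""

import numpy as np
import pandas as pd
import pytest

from dietswap.core import FoodGroupVector, FoodRecord, NutrientVector
from dietswap.cost import (
    CPISeries,
    PriceTable,
    daily_cost,
    group_cost_summary,
    inflation_adjust,
    replacement_cost,
)
from dietswap.substitution import DoseLevel
from conftest import make_person, make_personday, trivial_design


def _prices(rows):
    return PriceTable(pd.DataFrame(
        rows, columns=["food_code", "category", "price_per_100g", "imputed"]))


def _cpi(rows):
    return CPISeries(pd.DataFrame(rows, columns=["category", "year", "index"]))


class TestInflationAdjust:
    def test_hand_arithmetic(self):
        prices = _prices([("A", "meat", 2.00, False)])
        cpi = _cpi([("meat", 2003, 200.0), ("meat", 2017, 250.0)])
        out = inflation_adjust(prices, cpi, 2003, 2017)
        assert out.price("A") == pytest.approx(2.50)

    def test_categories_adjusted_independently(self):
        prices = _prices([("A", "meat", 1.00, False), ("B", "produce", 1.00, False)])
        cpi = _cpi([("meat", 2003, 100.0), ("meat", 2017, 150.0),
                    ("produce", 2003, 100.0), ("produce", 2017, 120.0)])
        out = inflation_adjust(prices, cpi, 2003, 2017)
        assert out.price("A") == pytest.approx(1.50)
        assert out.price("B") == pytest.approx(1.20)

    def test_missing_category_year_raises(self):
        prices = _prices([("A", "meat", 1.00, False)])
        cpi = _cpi([("meat", 2003, 100.0)])
        with pytest.raises(KeyError):
            inflation_adjust(prices, cpi, 2003, 2017)


def _person_with_foods(foods, meat_oz=0.0, pid="p1"):
    day = make_personday(person_id=pid, meat_oz=meat_oz, energy=2000)
    p = make_person(pid, days=[day])
    p.foods = [FoodRecord(pid, 1, code, False, grams,
                          NutrientVector(), FoodGroupVector(),
                          wweia_category=cat)
               for code, grams, cat in foods]
    return p


class TestDailyCost:
    def test_empty_day_costs_zero(self):
        p = _person_with_foods([])
        assert daily_cost(p, _prices([("A", "meat", 1.0, False)])) == 0.0

    def test_single_item_hand_arithmetic(self):
        p = _person_with_foods([("A", 150.0, "Protein Foods-Meats")])
        assert daily_cost(p, _prices([("A", "meat", 1.00, False)])) \
            == pytest.approx(1.50)

    def test_additive_over_records(self):
        prices = _prices([("A", "meat", 1.00, False), ("B", "grain", 0.40, False)])
        pa = _person_with_foods([("A", 100.0, "Protein Foods-Meats")])
        pb = _person_with_foods([("B", 200.0, "Grains")])
        both = _person_with_foods([("A", 100.0, "Protein Foods-Meats"),
                                   ("B", 200.0, "Grains")])
        assert daily_cost(both, prices) == pytest.approx(
            daily_cost(pa, prices) + daily_cost(pb, prices))

    def test_unpriced_code_raises_with_code_list(self):
        p = _person_with_foods([("MYSTERY", 100.0, "Grains")])
        with pytest.raises(KeyError, match="MYSTERY"):
            daily_cost(p, _prices([("A", "meat", 1.0, False)]))

    def test_imputation_uses_category_median(self):
        prices = _prices([("A", "grain", 0.30, False), ("B", "grain", 0.50, False)])
        out = prices.impute_missing(["C"], {"C": "grain"})
        assert out.price("C") == pytest.approx(0.40)
        assert bool(out.table.set_index("food_code").loc["C", "imputed"])


class TestReplacementCost:
    PRICES = _prices([("A", "meat", 1.0, False)])

    def test_zero_meat_day_expenses_constant(self):
        p = _person_with_foods([("A", 100.0, "Grains")], meat_oz=0.0)
        new, delta = replacement_cost(p, DoseLevel(4.0), self.PRICES, 0.38, 0.26)
        assert delta == 0.0
        assert new == pytest.approx(daily_cost(p, self.PRICES))

    def test_one_ounce_hand_arithmetic(self):
        p = _person_with_foods([("A", 100.0, "Protein Foods-Meats")], meat_oz=3.0)
        _, delta = replacement_cost(p, DoseLevel(1.0), self.PRICES, 0.38, 0.26)
        assert delta == pytest.approx(-0.38 + 0.13)

    def test_cap_rule_in_costing(self):
        p = _person_with_foods([("A", 100.0, "Protein Foods-Meats")], meat_oz=2.5)
        _, delta = replacement_cost(p, DoseLevel(4.0), self.PRICES, 0.38, 0.26)
        assert delta == pytest.approx(2.5 * (-0.38 + 0.13))

    def test_delta_monotone_when_walnuts_cheaper_per_oz_eq(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            meat_price = rng.uniform(0.1, 1.0)
            walnut_price = rng.uniform(0.0, 2 * meat_price * 0.99)
            p = _person_with_foods([("A", 100.0, "Protein Foods-Meats")],
                                   meat_oz=rng.uniform(0, 6))
            deltas = [replacement_cost(p, DoseLevel(d), self.PRICES,
                                       meat_price, walnut_price)[1]
                      for d in (1.0, 2.0, 3.0, 4.0)]
            assert np.all(np.diff(deltas) <= 1e-12)

    def test_delta_ignores_non_meat_records(self):
        base = _person_with_foods([("A", 100.0, "Protein Foods-Meats")], meat_oz=2.0)
        extra = _person_with_foods([("A", 100.0, "Protein Foods-Meats"),
                                    ("A", 500.0, "Grains")], meat_oz=2.0)
        _, d1 = replacement_cost(base, DoseLevel(2.0), self.PRICES, 0.38, 0.26)
        _, d2 = replacement_cost(extra, DoseLevel(2.0), self.PRICES, 0.38, 0.26)
        assert d1 == pytest.approx(d2)


class TestGroupSummary:
    def test_all_zero_prices_give_zero_means(self):
        p = _person_with_foods([("A", 100.0, "Protein Foods-Meats")], meat_oz=0.0)
        table = group_cost_summary([p], trivial_design([p.person_id]),
                                   _prices([("A", "meat", 0.0, False)]),
                                   [DoseLevel(1.0)], 0.0, 0.0)
        assert (table["mean_cost"] == 0.0).all()

    def test_uniform_cohort_matches_hand_result(self):
        persons = [
            _person_with_foods([("A", 200.0, "Protein Foods-Meats")],
                               meat_oz=4.0, pid=f"p{i}")
            for i in range(4)
        ]
        prices = _prices([("A", "meat", 1.00, False)])
        table = group_cost_summary(persons, trivial_design([p.person_id for p in persons]),
                                   prices, [DoseLevel(2.0)], 0.38, 0.26)
        current = table[table["dose_oz"] == 0.0].iloc[0]
        dosed = table[table["dose_oz"] == 2.0].iloc[0]
        assert current["mean_cost"] == pytest.approx(2.00)
        assert dosed["mean_cost"] == pytest.approx(2.00 + 2 * (-0.38 + 0.13))
        assert dosed["pct_change"] == pytest.approx(100 * 2 * (-0.25) / 2.00)

    def test_synthetic_cohort_cost_changes_single_digit_percent(self, included_cohort):
        from dietswap.simulate import SimulationConfig, generate_prices
        included, _, design = included_cohort
        cfg = SimulationConfig(seed=11)
        prices, cpi = generate_prices(cfg)
        codes = sorted({f.food_code for p in included for f in p.foods})
        cat_map = {"Protein Foods-Meats": "meat", "Fruits and Vegetables": "produce",
                   "Grains": "grain", "Milk and Dairy": "dairy",
                   "Mixed Dishes": "mixed", "Nuts and Seeds": "nuts"}
        code_cat = {f.food_code: cat_map[f.wweia_category]
                    for p in included for f in p.foods}
        prices = prices.impute_missing(codes, code_cat)
        table = group_cost_summary(included, design, prices,
                                   [DoseLevel(d) for d in (1.0, 4.0)], 0.38, 0.26)
        dosed = table[table["dose_oz"] > 0]
        assert (dosed["pct_change"] < 0).all()
        assert dosed["pct_change"].min() > -15.0

    def test_high_variance_spending_makes_replacement_not_significant(self):
        # person-to-person spending varies by far more than the sub-dollar
        # replacement delta, so the current and modeled CIs overlap
        from dietswap.simulate import generate_design

        rng = np.random.default_rng(8)
        persons = []
        for i in range(40):
            grams = float(rng.lognormal(np.log(300), 0.9))
            persons.append(_person_with_foods(
                [("A", grams, "Protein Foods-Meats")], meat_oz=4.0, pid=f"p{i}"))
        design = generate_design([p.person_id for p in persons], 8)
        table = group_cost_summary(persons, design,
                                   _prices([("A", "meat", 1.00, False)]),
                                   [DoseLevel(4.0)], 0.38, 0.26)
        dosed = table[table["dose_oz"] == 4.0]
        assert not dosed["significant"].any()
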