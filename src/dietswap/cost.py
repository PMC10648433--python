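"""Food-cost model: price assignment with category-median imputation, CPI
inflation adjustment by food category, day-1 daily cost, replacement cost
under the meat cap rule, and survey-weighted group summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Person
from .cohort import group_members
from .substitution import DoseLevel, meat_oz_equivalents
from .survey import SurveyDesign, brr_standard_error, nonoverlap_significant

__all__ = [
    "PriceTable", "CPISeries", "inflation_adjust", "daily_cost",
    "replacement_cost", "group_cost_summary", "COST_GROUPS",
]


@dataclass
class PriceTable:
    """Per-food-code price per 100 g with category label and imputation flag."""

    table: pd.DataFrame  # columns: food_code, category, price_per_100g, imputed
    meat_price_per_oz: float | None = None
    walnut_price_per_oz: float | None = None

    def __post_init__(self) -> None:
        required = {"food_code", "category", "price_per_100g", "imputed"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"price table missing columns: {sorted(missing)}")
        if (self.table["price_per_100g"] < 0).any():
            raise ValueError("prices must be >= 0")
        self._prices = dict(zip(self.table["food_code"], self.table["price_per_100g"]))

    def price(self, food_code: str) -> float:
        return self._prices[food_code]

    def impute_missing(self, food_codes: Sequence[str],
                       code_category: dict[str, str]) -> "PriceTable":
        """Assign category-median prices to unpriced codes, flagged imputed."""
        known = set(self.table["food_code"])
        medians = self.table.groupby("category")["price_per_100g"].median()
        new_rows = []
        for code in food_codes:
            if code in known:
                continue
            cat = code_category[code]
            if cat not in medians.index:
                raise KeyError(f"no priced items in category {cat!r} to impute from")
            new_rows.append({"food_code": code, "category": cat,
                             "price_per_100g": float(medians[cat]), "imputed": True})
            known.add(code)
        if not new_rows:
            return self
        table = pd.concat([self.table, pd.DataFrame(new_rows)], ignore_index=True)
        return PriceTable(table, self.meat_price_per_oz, self.walnut_price_per_oz)


@dataclass
class CPISeries:
    """Consumer-price-index values per (food category, year)."""

    table: pd.DataFrame  # columns: category, year, index

    def __post_init__(self) -> None:
        if (self.table["index"] <= 0).any():
            raise ValueError("CPI index values must be > 0")
        self._idx = {(r["category"], int(r["year"])): float(r["index"])
                     for _, r in self.table.iterrows()}

    def value(self, category: str, year: int) -> float:
        try:
            return self._idx[(category, year)]
        except KeyError:
            raise KeyError(f"no CPI entry for category {category!r}, year {year}") from None


def inflation_adjust(prices: PriceTable, cpi: CPISeries,
                     base_year: int, target_year: int) -> PriceTable:
    """Scale each price by its category's CPI ratio target/base."""
    t = prices.table.copy()
    ratios = t["category"].map(
        lambda c: cpi.value(c, target_year) / cpi.value(c, base_year)
    )
    t["price_per_100g"] = t["price_per_100g"] * ratios
    return PriceTable(t, prices.meat_price_per_oz, prices.walnut_price_per_oz)


def daily_cost(person: Person, prices: PriceTable, day: int = 1) -> float:
    """Sum over the day's food records of grams/100 * price per 100 g."""
    records = [f for f in person.foods if f.day == day]
    unpriced = sorted({f.food_code for f in records} - set(prices._prices))
    if unpriced:
        raise KeyError(f"unpriced food codes: {unpriced}")
    return float(sum(f.grams / 100.0 * prices.price(f.food_code) for f in records))


def replacement_cost(
    person: Person,
    dose: DoseLevel,
    prices: PriceTable,
    meat_price_per_oz: float,
    walnut_price_per_oz: float,
    day: int = 1,
) -> tuple[float, float]:
    """(new daily cost, delta) after replacing up to the reported meat level.

    r = min(dose, reported meat oz eq); delta = -r*meat price + 0.5r*walnut
    price.  A zero-meat day keeps its expenses unchanged.
    """
    base = daily_cost(person, prices, day=day)
    d = person.day_record(day)
    r = min(dose.meat_target_oz, meat_oz_equivalents(d)) if d is not None else 0.0
    delta = -r * meat_price_per_oz + 0.5 * r * walnut_price_per_oz
    return base + delta, delta


COST_GROUPS = (
    ("any", 4, 18, "4-18"), ("any", 19, 50, "19-50"),
    ("any", 51, 70, "51-70"), ("any", 71, 200, "71+"),
)


def group_cost_summary(
    persons: Sequence[Person],
    design: SurveyDesign,
    prices: PriceTable,
    doses: Sequence[DoseLevel],
    meat_price_per_oz: float,
    walnut_price_per_oz: float,
) -> pd.DataFrame:
    """Weighted mean daily cost per (age group x gender, dose) with BRR CIs,
    percent change vs the current diet, and CI-overlap significance."""
    rows = []
    for gender in ("male", "female"):
        for _, lo, hi, age_label in COST_GROUPS:
            members = [p for p in persons
                       if lo <= int(p.age_years) <= hi and p.gender == gender]
            if not members:
                continue
            sub = design.subset([p.person_id for p in members])
            base_costs = np.array([daily_cost(p, prices) for p in members])
            meat_r = {
                d.meat_target_oz: np.array([
                    min(d.meat_target_oz, meat_oz_equivalents(p.day_record(1)))
                    for p in members
                ]) for d in doses
            }

            def est(costs):
                return lambda w: float(np.sum(w * costs) / np.sum(w))

            current = brr_standard_error(est(base_costs), sub)
            rows.append({
                "group": f"{gender} {age_label}", "dose_oz": 0.0,
                "mean_cost": current.point, "se": current.se,
                "ci_lower": current.lower, "ci_upper": current.upper,
                "pct_change": 0.0, "significant": False,
            })
            for d in doses:
                deltas = -meat_r[d.meat_target_oz] * meat_price_per_oz \
                    + 0.5 * meat_r[d.meat_target_oz] * walnut_price_per_oz
                ci = brr_standard_error(est(base_costs + deltas), sub)
                rows.append({
                    "group": f"{gender} {age_label}", "dose_oz": d.meat_target_oz,
                    "mean_cost": ci.point, "se": ci.se,
                    "ci_lower": ci.lower, "ci_upper": ci.upper,
                    "pct_change": 100.0 * (ci.point - current.point) / current.point
                    if current.point else np.nan,
                    "significant": nonoverlap_significant(current, ci),
                })
    return pd.DataFrame(rows)
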