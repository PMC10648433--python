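"""Domain types, unit conventions, and tabular I/O shared by all pipeline stages.

Units are fixed at ingest and never converted downstream: energy kcal;
protein, saturated fat, MUFA, PUFA, ALA, LA, fiber in g; cholesterol,
calcium, iron, magnesium, potassium, sodium, copper, zinc, vitamin E in mg;
folate (DFE) and vitamin B12 in µg.  Food-pattern amounts are oz equivalents
(protein foods, grains), cup equivalents (fruit, vegetables, dairy) and
teaspoon equivalents (added sugars).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "NUTRIENT_FIELDS",
    "FOOD_GROUP_FIELDS",
    "NutrientVector",
    "FoodGroupVector",
    "FoodRecord",
    "PersonDay",
    "Person",
    "DRIReference",
    "FoodCompositionProfile",
    "SchemaError",
    "scale_and_add",
    "read_cohort",
    "write_cohort",
    "WALNUT_PER_OZ",
    "MEAT_PER_OZ",
]

NUTRIENT_FIELDS = (
    "energy", "protein", "sat_fat", "mufa", "pufa", "ala", "la",
    "cholesterol", "fiber", "calcium", "iron", "magnesium", "potassium",
    "sodium", "copper", "zinc", "folate_dfe", "vitamin_e", "vitamin_b12",
)

FOOD_GROUP_FIELDS = (
    "meat_oz", "cured_meat_oz", "organ_meat_oz", "poultry_oz", "seafood_oz",
    "eggs_oz", "legumes_oz", "soy_oz", "nuts_seeds_oz", "total_protein_oz",
    "seafood_plant_protein_oz",
    "total_fruit_cup", "whole_fruit_cup", "total_veg_cup", "greens_beans_cup",
    "whole_grain_oz", "refined_grain_oz", "dairy_cup", "added_sugars_tsp",
)


class SchemaError(ValueError):
    """Raised when a component set or table schema does not match the contract."""


def _vector_base(fields: tuple[str, ...]):
    """Build a fixed-key float vector dataclass over ``fields``."""

    @dataclass
    class _Vector:
        def to_dict(self) -> dict[str, float]:
            return {k: getattr(self, k) for k in fields}

        def as_array(self) -> np.ndarray:
            return np.array([getattr(self, k) for k in fields], dtype=float)

        @classmethod
        def from_dict(cls, d: dict[str, float]):
            unknown = set(d) - set(fields)
            if unknown:
                raise SchemaError(f"unknown components: {sorted(unknown)}")
            return cls(**d)

        @classmethod
        def from_array(cls, a) -> "_Vector":
            a = np.asarray(a, dtype=float)
            if a.shape != (len(fields),):
                raise SchemaError(f"expected {len(fields)} components, got {a.shape}")
            return cls(**dict(zip(fields, a.tolist())))

        def __add__(self, other):
            if type(other) is not type(self):
                raise SchemaError("mismatched component sets")
            return type(self).from_array(self.as_array() + other.as_array())

    return _Vector


@dataclass
class NutrientVector(_vector_base(NUTRIENT_FIELDS)):
    """Per-day nutrient totals in the package's fixed units.

    All components are finite and non-negative in observed data; vectors
    representing substitution deltas may carry negative components.
    """

    energy: float = 0.0
    protein: float = 0.0
    sat_fat: float = 0.0
    mufa: float = 0.0
    pufa: float = 0.0
    ala: float = 0.0
    la: float = 0.0
    cholesterol: float = 0.0
    fiber: float = 0.0
    calcium: float = 0.0
    iron: float = 0.0
    magnesium: float = 0.0
    potassium: float = 0.0
    sodium: float = 0.0
    copper: float = 0.0
    zinc: float = 0.0
    folate_dfe: float = 0.0
    vitamin_e: float = 0.0
    vitamin_b12: float = 0.0

    _FIELDS = NUTRIENT_FIELDS


@dataclass
class FoodGroupVector(_vector_base(FOOD_GROUP_FIELDS)):
    """USDA food-pattern component amounts (oz/cup/tsp equivalents)."""

    meat_oz: float = 0.0
    cured_meat_oz: float = 0.0
    organ_meat_oz: float = 0.0
    poultry_oz: float = 0.0
    seafood_oz: float = 0.0
    eggs_oz: float = 0.0
    legumes_oz: float = 0.0
    soy_oz: float = 0.0
    nuts_seeds_oz: float = 0.0
    total_protein_oz: float = 0.0
    seafood_plant_protein_oz: float = 0.0
    total_fruit_cup: float = 0.0
    whole_fruit_cup: float = 0.0
    total_veg_cup: float = 0.0
    greens_beans_cup: float = 0.0
    whole_grain_oz: float = 0.0
    refined_grain_oz: float = 0.0
    dairy_cup: float = 0.0
    added_sugars_tsp: float = 0.0

    _FIELDS = FOOD_GROUP_FIELDS


@dataclass
class FoodRecord:
    """One food item on one recall day of one person."""

    person_id: str
    day: int
    food_code: str
    walnut_flag: bool
    grams: float
    nutrients: NutrientVector
    groups: FoodGroupVector
    wweia_category: str = ""

    def __post_init__(self) -> None:
        if self.day not in (1, 2):
            raise ValueError(f"day must be 1 or 2, got {self.day!r}")
        if self.grams < 0:
            raise ValueError("grams must be >= 0")


@dataclass
class PersonDay:
    """One person's one-day aggregated intake (sum of that day's food records)."""

    person_id: str
    day: int
    weekday_indicator: bool  # True = Monday-Thursday
    nutrients: NutrientVector
    groups: FoodGroupVector


@dataclass
class Person:
    """A survey respondent with demographics, flags, recall days and food records."""

    person_id: str
    age_years: float
    gender: Literal["male", "female"]
    race: str
    income_band: str
    education_band: str
    nut_status: str | None = None  # walnut | other_nut | no_nut, set by classification
    days: list[PersonDay] = field(default_factory=list)
    foods: list[FoodRecord] = field(default_factory=list)
    breast_milk: bool = False
    pregnant_or_lactating: bool = False
    reliable_recall: bool = True
    animal_protein_missing: bool = False

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age_years must be >= 0")

    def day_record(self, day: int) -> PersonDay | None:
        for d in self.days:
            if d.day == day:
                return d
        return None

    @property
    def n_days(self) -> int:
        return len(self.days)


class DRIReference:
    """Dietary Reference Intake thresholds per (nutrient, gender, age band).

    Each row carries a threshold value and its kind: EAR (estimated average
    requirement; prevalence of inadequacy uses the fraction below), AI
    (adequate intake; adequacy uses the fraction above) or limit.
    """

    KINDS = ("EAR", "AI", "limit")

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"nutrient", "gender", "age_min", "age_max", "kind", "value"}
        missing = required - set(table.columns)
        if missing:
            raise SchemaError(f"DRI table missing columns: {sorted(missing)}")
        if (table["value"] <= 0).any():
            raise ValueError("DRI thresholds must be > 0")
        bad = set(table["kind"]) - set(self.KINDS)
        if bad:
            raise ValueError(f"unknown threshold kinds: {sorted(bad)}")
        self.table = table.reset_index(drop=True)
        self._cache: dict[tuple[str, str, int], tuple[float, str]] = {}

    def lookup(self, nutrient: str, gender: str, age: float) -> tuple[float, str]:
        years = int(age)  # completed years, matching the band definitions
        key = (nutrient, gender, years)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        t = self.table
        hit = t[
            (t["nutrient"] == nutrient)
            & (t["gender"].isin([gender, "any"]))
            & (t["age_min"] <= years)
            & (years <= t["age_max"])
        ]
        if hit.empty:
            raise KeyError(f"no DRI row for {nutrient}/{gender}/{age}")
        row = hit.iloc[0]
        out = (float(row["value"]), str(row["kind"]))
        self._cache[key] = out
        return out

    @classmethod
    def read_csv(cls, path: str | Path) -> "DRIReference":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# Per-ounce composition used by the substitution engine.  Nutrients a food is
# not a meaningful source of are zero by convention; the HEI adjustment uses a
# separate profile (see dietswap.hei) with its own published MUFA/PUFA/sodium
# values, and the two are deliberately not merged.
WALNUT_PER_OZ = NutrientVector(
    energy=185.0, protein=4.32, sat_fat=1.74, ala=2.57, la=10.8,
    calcium=27.8, iron=0.825, magnesium=44.8, potassium=125.0,
    copper=0.451, zinc=0.876, folate_dfe=27.8, vitamin_e=0.198, fiber=1.9,
)

MEAT_PER_OZ = NutrientVector(
    energy=49.0, protein=7.1, sat_fat=0.76, cholesterol=20.0, ala=0.01,
    calcium=2.0, iron=0.5, magnesium=6.0, potassium=93.0, zinc=1.2,
    vitamin_b12=0.6,
)


@dataclass
class FoodCompositionProfile:
    """Per-oz nutrient composition of the replacement pair (walnut in, meat out)."""

    walnut_per_oz: NutrientVector = field(default_factory=lambda: dataclasses.replace(WALNUT_PER_OZ))
    meat_per_oz: NutrientVector = field(default_factory=lambda: dataclasses.replace(MEAT_PER_OZ))


def scale_and_add(
    base: NutrientVector,
    delta: NutrientVector,
    factor: float,
    clip: bool = False,
) -> NutrientVector:
    """Component-wise ``base + factor * delta``; clip at zero when ``clip``."""
    if not np.isfinite(factor):
        raise ValueError("factor must be finite")
    out = base.as_array() + factor * delta.as_array()
    if clip:
        out = np.clip(out, 0.0, None)
    return NutrientVector.from_array(out)


# ---------------------------------------------------------------------------
# Tabular I/O.  Schemas documented in docs/schemas.md; column names equal the
# type field names.  CSV keeps full float precision via repr round-trip.
# ---------------------------------------------------------------------------

_PERSON_COLS = [
    "person_id", "age_years", "gender", "race", "income_band",
    "education_band", "nut_status", "breast_milk", "pregnant_or_lactating",
    "reliable_recall", "animal_protein_missing",
    "day1_weekday", "day2_weekday",
]


def write_cohort(persons: Iterable[Person], out_dir: str | Path) -> dict[str, Path]:
    """Write persons.csv and food_records.csv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prow, frow = [], []
    for p in persons:
        d1, d2 = p.day_record(1), p.day_record(2)
        prow.append({
            "person_id": p.person_id, "age_years": p.age_years,
            "gender": p.gender, "race": p.race, "income_band": p.income_band,
            "education_band": p.education_band,
            "nut_status": p.nut_status if p.nut_status is not None else "",
            "breast_milk": p.breast_milk,
            "pregnant_or_lactating": p.pregnant_or_lactating,
            "reliable_recall": p.reliable_recall,
            "animal_protein_missing": p.animal_protein_missing,
            "day1_weekday": d1.weekday_indicator if d1 else True,
            "day2_weekday": d2.weekday_indicator if d2 else "",
        })
        for f in p.foods:
            row = {
                "person_id": f.person_id, "day": f.day, "food_code": f.food_code,
                "walnut_flag": f.walnut_flag, "grams": f.grams,
                "wweia_category": f.wweia_category,
            }
            row.update(f.nutrients.to_dict())
            row.update(f.groups.to_dict())
            frow.append(row)
    persons_path = out_dir / "persons.csv"
    foods_path = out_dir / "food_records.csv"
    pd.DataFrame(prow, columns=_PERSON_COLS).to_csv(persons_path, index=False)
    food_cols = ["person_id", "day", "food_code", "walnut_flag", "grams",
                 "wweia_category", *NUTRIENT_FIELDS, *FOOD_GROUP_FIELDS]
    pd.DataFrame(frow, columns=food_cols).to_csv(foods_path, index=False)
    return {"persons": persons_path, "food_records": foods_path}


def read_cohort(in_dir: str | Path) -> list[Person]:
    """Read persons.csv + food_records.csv and rebuild fully linked Persons.

    Person-day aggregates are recomputed as the component-wise sum of that
    person-day's food records, enforcing the aggregation invariant by
    construction.  Referential integrity (every food row's person_id present
    in the persons table) is enforced.
    """
    in_dir = Path(in_dir)
    pt = pd.read_csv(in_dir / "persons.csv", dtype={"person_id": str},
                     float_precision="round_trip")
    ft = pd.read_csv(in_dir / "food_records.csv",
                     dtype={"person_id": str, "food_code": str},
                     float_precision="round_trip")

    bad_day = set(ft["day"].unique()) - {1, 2}
    if bad_day:
        raise ValueError(f"malformed day values in food_records: {sorted(bad_day)}")
    unknown = set(ft["person_id"]) - set(pt["person_id"])
    if unknown:
        raise KeyError(f"food records reference unknown person_ids: {sorted(unknown)[:5]}")

    persons: dict[str, Person] = {}
    for _, r in pt.iterrows():
        persons[r["person_id"]] = Person(
            person_id=r["person_id"], age_years=float(r["age_years"]),
            gender=r["gender"], race=str(r["race"]),
            income_band=str(r["income_band"]), education_band=str(r["education_band"]),
            nut_status=(r["nut_status"] if isinstance(r["nut_status"], str) and r["nut_status"] else None),
            breast_milk=bool(r["breast_milk"]),
            pregnant_or_lactating=bool(r["pregnant_or_lactating"]),
            reliable_recall=bool(r["reliable_recall"]),
            animal_protein_missing=bool(r["animal_protein_missing"]),
        )

    weekday = {
        (r["person_id"], 1): bool(r["day1_weekday"]) for _, r in pt.iterrows()
    }
    weekday.update({
        (r["person_id"], 2): str(r["day2_weekday"]) in ("True", "true", "1", "1.0")
        for _, r in pt.iterrows()
    })

    for _, r in ft.iterrows():
        rec = FoodRecord(
            person_id=r["person_id"], day=int(r["day"]), food_code=r["food_code"],
            walnut_flag=bool(r["walnut_flag"]), grams=float(r["grams"]),
            nutrients=NutrientVector(**{k: float(r[k]) for k in NUTRIENT_FIELDS}),
            groups=FoodGroupVector(**{k: float(r[k]) for k in FOOD_GROUP_FIELDS}),
            wweia_category=str(r["wweia_category"]),
        )
        persons[rec.person_id].foods.append(rec)

    for p in persons.values():
        for day in (1, 2):
            recs = [f for f in p.foods if f.day == day]
            if not recs:
                continue
            nut = NutrientVector.from_array(sum(f.nutrients.as_array() for f in recs))
            grp = FoodGroupVector.from_array(sum(f.groups.as_array() for f in recs))
            p.days.append(PersonDay(
                person_id=p.person_id, day=day,
                weekday_indicator=weekday.get((p.person_id, day), True),
                nutrients=nut, groups=grp,
            ))
    return list(persons.values())
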