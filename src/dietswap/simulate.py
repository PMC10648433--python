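"""Synthetic NHANES-like cohort generator with known ground truth.

The generator emulates the structure of a two-day 24-h recall survey of
no-nut consumers plus the surrounding respondents the exclusion rules must
handle: two non-consecutive recall days with 79% day-2 completion,
demographic strata with realistic proportions, skewed positive nutrient
amounts driven by a Box-Cox random-intercept model (so the usual-intake
estimator is exactly identifiable), protein-food composition calibrated so
meat contributes roughly half of animal-protein oz equivalents, survey base
weights with Fay-type balanced-repeated-replication replicate weights, and
a food-price table with CPI series.

Each logical purpose (demographics, amounts, missingness, weights, foods,
prices, truth) draws from its own stream spawned from the master seed, so
adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import hadamard

from .core import (
    DRIReference,
    FoodGroupVector,
    FoodRecord,
    NutrientVector,
    Person,
    PersonDay,
)
from .cost import CPISeries, PriceTable
from .survey import SurveyDesign
from .usual_intake import age_category, boxcox_inverse

__all__ = [
    "NutrientParams", "SimulationConfig", "TruthRecord",
    "generate_cohort", "generate_prices", "generate_design", "default_dri",
    "GRAMS_PER_OZ",
]

GRAMS_PER_OZ = 28.35

# Age-group population proportions, gender and race mix of a recent
# US survey cycle's no-nut consumers (weighted).
AGE_GROUP_PROPS = {
    (4, 8): 0.0736, (9, 13): 0.0835, (14, 18): 0.0903,
    (19, 50): 0.4449, (51, 70): 0.2279, (71, 85): 0.0798,
}
MALE_PROP = 0.5261
RACE_PROPS = {"hispanic": 0.2203, "nh_white": 0.5196, "nh_black": 0.1554,
              "other": 0.1047}
INCOME_BANDS = {"lt20k": 0.179, "20to75k": 0.495, "75to100k": 0.111,
                "gt100k": 0.215}
EDUCATION_BANDS = {"lt9": 0.208, "9to11": 0.138, "hs": 0.241,
                   "some_college": 0.257, "college": 0.156}

# Per-person-day protein-food oz eq targets and source shares (meats,
# poultry, seafood, eggs, legumes, soy), calibrated to published
# protein-food composition: meat is about half of protein-food intake.
PROTEIN_TARGET_OZ = {("male", True): 4.86, ("female", True): 3.81,
                     ("male", False): 6.97, ("female", False): 5.05}
PROTEIN_SHARES = {
    ("male", True): (0.509, 0.294, 0.045, 0.078, 0.065, 0.010),
    ("female", True): (0.449, 0.317, 0.055, 0.098, 0.069, 0.013),
    ("male", False): (0.494, 0.245, 0.094, 0.086, 0.076, 0.006),
    ("female", False): (0.436, 0.262, 0.115, 0.105, 0.074, 0.008),
}
MEAT_SPLIT = (0.72, 0.26, 0.02)  # meat / cured / organ

# log-scale covariate effects shared by all nutrients (scaled to each
# nutrient's transformed scale).
AGE_EFFECTS = (-0.35, -0.15, -0.05, 0.0, 0.02, -0.05, -0.12)
RACE_EFFECTS = {"hispanic": 0.0, "nh_white": 0.03, "nh_black": -0.04,
                "other": -0.02}
SEQ_DAY2_EFFECT = -0.04
WEEKDAY_EFFECT = 0.03
MALE_EFFECT = 0.12


@dataclass(frozen=True)
class NutrientParams:
    """Usual-intake generating parameters on the Box-Cox transformed scale.

    ``median`` is the reference-person median intake; log-scale effect sizes
    and sds are converted to the transformed scale by the factor median**lam
    (the transform's local slope in log units), keeping coefficients of
    variation comparable across lambdas.
    """

    lam: float
    median: float
    sigma_u_log: float = 0.25
    sigma_e_log: float = 0.35
    gamma_energy_log: float = 0.35  # per 1000 kcal above 2000

    @property
    def scale(self) -> float:
        return float(self.median ** self.lam) if self.lam > 0 else 1.0

    @property
    def mu(self) -> float:
        if self.lam == 0:
            return float(np.log(self.median))
        return float((self.median ** self.lam - 1.0) / self.lam)

    @property
    def sigma_u(self) -> float:
        return self.sigma_u_log * self.scale

    @property
    def sigma_e(self) -> float:
        return self.sigma_e_log * self.scale


DEFAULT_NUTRIENT_PARAMS: dict[str, NutrientParams] = {
    "protein": NutrientParams(0.0, 78.0, 0.20, 0.28),
    "sat_fat": NutrientParams(0.0, 24.0, 0.25, 0.38),
    "mufa": NutrientParams(0.0, 24.0, 0.25, 0.38),
    "pufa": NutrientParams(0.0, 17.0, 0.25, 0.40),
    "ala": NutrientParams(0.0, 1.5, 0.28, 0.45),
    "la": NutrientParams(0.0, 14.0, 0.25, 0.40),
    "cholesterol": NutrientParams(0.0, 270.0, 0.28, 0.45),
    "fiber": NutrientParams(0.3, 15.0, 0.25, 0.38),
    "calcium": NutrientParams(0.0, 950.0, 0.25, 0.35),
    "iron": NutrientParams(0.0, 13.0, 0.25, 0.35),
    "magnesium": NutrientParams(0.3, 270.0, 0.22, 0.30),
    "potassium": NutrientParams(0.0, 2500.0, 0.20, 0.28),
    "sodium": NutrientParams(0.0, 3300.0, 0.22, 0.32),
    "copper": NutrientParams(0.0, 1.1, 0.22, 0.32),
    "zinc": NutrientParams(0.0, 10.0, 0.25, 0.35),
    "folate_dfe": NutrientParams(0.0, 480.0, 0.25, 0.38),
    "vitamin_e": NutrientParams(0.0, 7.5, 0.25, 0.38),
    "vitamin_b12": NutrientParams(0.0, 4.0, 0.30, 0.50),
}

ENERGY_BASE = {  # median day-1 energy (kcal) by (gender, age band index)
    "male": (1600, 2000, 2500, 2500, 2400, 2200, 2000),
    "female": (1500, 1800, 1900, 1900, 1850, 1750, 1650),
}

TRUTH_NUTRIENTS = ("fiber", "magnesium", "potassium", "iron", "vitamin_b12",
                   "zinc", "copper", "ala", "cholesterol")

FOOD_CATEGORIES = ("meat", "produce", "grain", "dairy", "mixed", "nuts")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_persons: int = 1000
    day2_completion_prob: float = 0.79
    nutrient_params: dict[str, NutrientParams] = field(
        default_factory=lambda: dict(DEFAULT_NUTRIENT_PARAMS))
    # fractions of respondents who exist only to exercise the exclusion rules
    frac_under4: float = 0.02
    frac_pregnant: float = 0.015
    frac_unreliable: float = 0.02
    frac_missing_protein: float = 0.01
    frac_extreme_energy: float = 0.005
    frac_walnut: float = 0.04
    frac_other_nut: float = 0.08
    # survey design
    n_replicates: int = 16
    fay: float = 0.3
    weight_sigma: float = 0.25
    # energy (kcal) between/within log-sds
    energy_sigma_u: float = 0.16
    energy_sigma_e: float = 0.20
    # prices
    meat_price_per_oz: float = 0.38
    walnut_price_per_oz: float = 0.26
    price_base_year: int = 2003
    price_target_year: int = 2017
    annual_inflation: float = 0.022
    truth_nutrients: tuple[str, ...] = TRUTH_NUTRIENTS
    truth_draws_per_person: int = 200
    include_foods: bool = True  # food-level records (off for pure amount studies)

    def __post_init__(self) -> None:
        for name in ("day2_completion_prob", "frac_under4", "frac_pregnant",
                     "frac_unreliable", "frac_missing_protein",
                     "frac_extreme_energy", "frac_walnut", "frac_other_nut"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for p in self.nutrient_params.values():
            if p.sigma_u_log < 0 or p.sigma_e_log <= 0:
                raise ValueError("nutrient sds must be positive")
            if not 0 <= p.lam <= 1:
                raise ValueError("Box-Cox lambda must lie in [0, 1] for invertibility")


@dataclass
class TruthRecord:
    """Generating-distribution quantities the estimators are judged against."""

    person_ids: list[str]
    usual_intake: dict[str, np.ndarray]          # nutrient -> per-person T_i
    pop_mean: dict[str, float]
    percentiles: dict[str, np.ndarray]           # nutrient -> 99 percentiles
    frac_below_ear: dict[str, float]
    frac_above_ai: dict[str, float]
    sigma_u2: dict[str, float]
    sigma_e2: dict[str, float]
    lam: dict[str, float]


def default_dri() -> DRIReference:
    """A compact DRI table (EAR/AI/limit) covering the modeled nutrients.

    Values are rounded reference intakes for broad age bands; they serve as
    thresholds for tail-fraction estimation, not as a normative database.
    """
    rows = []

    def add(nutrient, kind, entries):
        for gender, lo, hi, value in entries:
            rows.append({"nutrient": nutrient, "gender": gender,
                         "age_min": lo, "age_max": hi, "kind": kind,
                         "value": value})

    add("magnesium", "EAR", [
        ("any", 4, 8, 110), ("any", 9, 13, 200),
        ("male", 14, 18, 340), ("female", 14, 18, 300),
        ("male", 19, 30, 330), ("female", 19, 30, 255),
        ("male", 31, 200, 350), ("female", 31, 200, 265),
    ])
    add("vitamin_b12", "EAR", [
        ("any", 4, 8, 1.0), ("any", 9, 13, 1.5), ("any", 14, 200, 2.0),
    ])
    add("iron", "EAR", [
        ("any", 4, 8, 4.1), ("any", 9, 13, 5.9),
        ("male", 14, 18, 7.7), ("female", 14, 18, 7.9),
        ("male", 19, 200, 6.0), ("female", 19, 50, 8.1),
        ("female", 51, 200, 5.0),
    ])
    add("zinc", "EAR", [
        ("any", 4, 8, 4.0), ("any", 9, 13, 7.0),
        ("male", 14, 200, 9.4), ("female", 14, 200, 6.8),
    ])
    add("fiber", "AI", [
        ("any", 4, 8, 25), ("male", 9, 13, 31), ("female", 9, 13, 26),
        ("male", 14, 18, 38), ("female", 14, 18, 26),
        ("male", 19, 50, 38), ("female", 19, 50, 25),
        ("male", 51, 200, 30), ("female", 51, 200, 21),
    ])
    add("potassium", "AI", [
        ("any", 4, 8, 2300), ("male", 9, 13, 2500), ("female", 9, 13, 2300),
        ("male", 14, 18, 3000), ("female", 14, 18, 2300),
        ("male", 19, 200, 3400), ("female", 19, 200, 2600),
    ])
    add("ala", "AI", [
        ("any", 4, 8, 0.9), ("any", 9, 13, 1.1),
        ("male", 14, 200, 1.6), ("female", 14, 200, 1.1),
    ])
    add("cholesterol", "limit", [("any", 4, 200, 300)])
    add("copper", "EAR", [
        ("any", 4, 8, 0.34), ("any", 9, 13, 0.54), ("any", 14, 18, 0.685),
        ("any", 19, 200, 0.7),
    ])
    return DRIReference(pd.DataFrame(rows))


def generate_design(
    person_ids: Sequence[str],
    rng: np.random.Generator | int,
    fay: float = 0.3,
    n_replicates: int = 16,
    weight_sigma: float = 0.25,
) -> SurveyDesign:
    """Lognormal pseudo-weights plus grouped half-sample BRR replicates.

    Persons are randomly assigned to ``n_replicates`` variance strata, each
    split into two half-sample groups; a Hadamard matrix supplies the
    balanced selection pattern and Fay's coefficient shrinks the
    perturbation, so the replicate weights satisfy the BRR variance
    formula's contract without mimicking any real survey's PSU structure.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = len(person_ids)
    base_w = np.exp(rng.normal(0.0, weight_sigma, n))
    R = n_replicates
    H = hadamard(R)
    order = rng.permutation(n)
    stratum = np.empty(n, dtype=int)
    half = np.empty(n, dtype=int)
    stratum[order] = np.arange(n) % R
    half[order] = (np.arange(n) // R) % 2
    # replicate r selects half-sample h=0 of stratum s when H[r, s] == +1
    sel = (H[:, stratum] == 1).T == (half == 0)[:, None]   # (n, R)
    rep_w = np.where(sel, (2.0 - fay), fay) * base_w[:, None]
    return SurveyDesign(person_ids=np.array(person_ids), base_weights=base_w,
                        replicate_weights=rep_w, fay=fay)


def _categorical(rng: np.random.Generator, props: dict, n: int) -> np.ndarray:
    keys = list(props)
    p = np.array([props[k] for k in keys], dtype=float)
    p /= p.sum()
    return rng.choice(keys, size=n, p=p)


def _transformed_linear_predictor(
    params: NutrientParams, age_cat: int, gender: str, race: str,
    day: int, weekday: bool, energy: float,
) -> float:
    eff_log = (AGE_EFFECTS[age_cat]
               + (MALE_EFFECT if gender == "male" else 0.0)
               + RACE_EFFECTS[race]
               + (SEQ_DAY2_EFFECT if day == 2 else 0.0)
               + (WEEKDAY_EFFECT if weekday else 0.0)
               + params.gamma_energy_log * (energy - 2000.0) / 1000.0)
    return params.mu + eff_log * params.scale


def _gh(n: int = 21) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(n)
    return x, w / np.sqrt(np.pi)


def _true_usual(params: NutrientParams, lp: np.ndarray, u: np.ndarray) -> np.ndarray:
    """E_e[g^{-1}(lp + u + e)] by 21-point Gauss-Hermite; lp and u broadcast."""
    nodes, wts = _gh()
    e = np.sqrt(2.0) * params.sigma_e * nodes
    t = (lp + u)[..., None] + e
    return boxcox_inverse(t, params.lam) @ wts


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[Person], SurveyDesign, TruthRecord]:
    """Generate the full respondent list, survey design and ground truth.

    The returned person list includes the excludable respondents (under-4s,
    pregnant/lactating women, unreliable recalls, nut consumers, ...); the
    cohort stage filters them.  Ground truth covers all respondents.
    """
    ss = np.random.SeedSequence(config.seed)
    (s_demo, s_amounts, s_missing, s_weights, s_foods, s_truth) = ss.spawn(6)
    rng_demo = np.random.default_rng(s_demo)
    rng_amt = np.random.default_rng(s_amounts)
    rng_miss = np.random.default_rng(s_missing)
    rng_wt = np.random.default_rng(s_weights)
    rng_food = np.random.default_rng(s_foods)
    rng_truth = np.random.default_rng(s_truth)

    n = config.n_persons
    ids = [f"P{i:06d}" for i in range(n)]

    # --- demographics ---------------------------------------------------
    bands = list(AGE_GROUP_PROPS)
    props = np.array(list(AGE_GROUP_PROPS.values()))
    band_idx = rng_demo.choice(len(bands), size=n, p=props / props.sum())
    ages = np.array([rng_demo.uniform(bands[b][0], bands[b][1] + 0.999)
                     for b in band_idx])
    under4 = rng_demo.random(n) < config.frac_under4
    ages = np.where(under4, rng_demo.uniform(0.5, 3.9, size=n), ages)
    genders = np.where(rng_demo.random(n) < MALE_PROP, "male", "female")
    races = _categorical(rng_demo, RACE_PROPS, n)
    incomes = _categorical(rng_demo, INCOME_BANDS, n)
    educations = _categorical(rng_demo, EDUCATION_BANDS, n)
    pregnant = ((genders == "female") & (ages >= 20) & (ages <= 44)
                & (rng_demo.random(n) < config.frac_pregnant / 0.2))
    unreliable = rng_demo.random(n) < config.frac_unreliable
    missing_protein = rng_demo.random(n) < config.frac_missing_protein
    extreme_energy = rng_demo.random(n) < config.frac_extreme_energy
    nut_roll = rng_demo.random(n)
    is_walnut = nut_roll < config.frac_walnut
    is_other_nut = (~is_walnut) & (nut_roll < config.frac_walnut + config.frac_other_nut)

    # --- missingness & weekday ------------------------------------------
    has_day2 = rng_miss.random(n) < config.day2_completion_prob
    weekday1 = rng_miss.random(n) < 4.0 / 7.0
    weekday2 = rng_miss.random(n) < 4.0 / 7.0

    # --- person random effects & per-day residuals -----------------------
    nut_names = list(config.nutrient_params)
    u_energy = rng_amt.normal(0.0, config.energy_sigma_u, n)
    e_energy = rng_amt.normal(0.0, config.energy_sigma_e, (n, 2))
    u_nut = {k: rng_amt.normal(0.0, config.nutrient_params[k].sigma_u, n)
             for k in nut_names}
    e_nut = {k: rng_amt.normal(0.0, config.nutrient_params[k].sigma_e, (n, 2))
             for k in nut_names}

    # --- weights and BRR replicates --------------------------------------
    design = generate_design(ids, rng_wt, fay=config.fay,
                             n_replicates=config.n_replicates,
                             weight_sigma=config.weight_sigma)

    # --- vectorized day-level amounts ------------------------------------
    acats = np.array([age_category(min(max(a, 4.0), 85.0)) for a in ages])
    e_base = np.array([ENERGY_BASE[g][acats[i]] for i, g in enumerate(genders)])
    energy_mat = e_base[:, None] * np.exp(u_energy[:, None] + e_energy)  # (n, 2)
    extreme_vals = rng_amt.choice([300.0, 6200.0], size=n)
    energy_mat[extreme_energy, 0] = extreme_vals[extreme_energy]
    weekday_mat = np.column_stack([weekday1, weekday2]).astype(float)
    race_eff = np.array([RACE_EFFECTS[r] for r in races])
    eff_common = (np.array(AGE_EFFECTS)[acats] + MALE_EFFECT * (genders == "male")
                  + race_eff)[:, None] \
        + SEQ_DAY2_EFFECT * np.array([0.0, 1.0])[None, :] \
        + WEEKDAY_EFFECT * weekday_mat
    amounts: dict[str, np.ndarray] = {}
    for k in nut_names:
        p = config.nutrient_params[k]
        eff_log = eff_common + p.gamma_energy_log * (energy_mat - 2000.0) / 1000.0
        lp = p.mu + eff_log * p.scale
        amounts[k] = np.maximum(
            boxcox_inverse(lp + u_nut[k][:, None] + e_nut[k], p.lam), 1e-3)

    # --- build persons ----------------------------------------------------
    food_code_pools = {
        cat: [f"{cat.upper()}{j:03d}" for j in range(10)] for cat in FOOD_CATEGORIES
    }
    breast_roll = rng_demo.random(n)
    persons: list[Person] = []
    for i in range(n):
        gender = str(genders[i])
        person = Person(
            person_id=ids[i], age_years=float(ages[i]), gender=gender,
            race=str(races[i]), income_band=str(incomes[i]),
            education_band=str(educations[i]),
            breast_milk=bool(under4[i] and breast_roll[i] < 0.3),
            pregnant_or_lactating=bool(pregnant[i]),
            reliable_recall=not bool(unreliable[i]),
            animal_protein_missing=bool(missing_protein[i]),
        )
        days = [1, 2] if has_day2[i] else [1]
        juvenile = ages[i] <= 18
        target = PROTEIN_TARGET_OZ[(gender, juvenile)]
        shares_mean = np.array(PROTEIN_SHARES[(gender, juvenile)])
        person_protein_mult = np.exp(rng_food.normal(0.0, 0.20))
        shares = rng_food.dirichlet(shares_mean * 25.0)

        for day in days:
            weekday = bool(weekday1[i] if day == 1 else weekday2[i])
            energy = float(energy_mat[i, day - 1])
            nvals = {k: float(amounts[k][i, day - 1]) for k in nut_names}
            nvals["energy"] = energy
            nut = NutrientVector(**nvals)

            # protein foods
            day_protein = target * person_protein_mult * np.exp(rng_food.normal(0.0, 0.25))
            src = shares * day_protein
            meat_split = rng_food.dirichlet(np.array(MEAT_SPLIT) * 40.0)
            meats, poultry, seafood, eggs, legumes, soy = src
            nuts_oz = 0.0
            if is_other_nut[i] or is_walnut[i]:
                nuts_oz = float(rng_food.uniform(0.2, 1.5))
            g = FoodGroupVector(
                meat_oz=float(meats * meat_split[0]),
                cured_meat_oz=float(meats * meat_split[1]),
                organ_meat_oz=float(meats * meat_split[2]),
                poultry_oz=float(poultry), seafood_oz=float(seafood),
                eggs_oz=float(eggs), legumes_oz=float(legumes), soy_oz=float(soy),
                nuts_seeds_oz=nuts_oz,
                total_protein_oz=float(src.sum() + 2.0 * nuts_oz),
                seafood_plant_protein_oz=float(seafood + legumes + soy + 2.0 * nuts_oz),
                total_fruit_cup=float(0.45 * energy / 1000 * np.exp(rng_food.normal(0, 0.5))),
                whole_fruit_cup=0.0,  # set below as a fraction of total fruit
                total_veg_cup=float(0.75 * energy / 1000 * np.exp(rng_food.normal(0, 0.4))),
                greens_beans_cup=float(0.12 * energy / 1000 * np.exp(rng_food.normal(0, 0.7))),
                whole_grain_oz=float(0.45 * energy / 1000 * np.exp(rng_food.normal(0, 0.6))),
                refined_grain_oz=float(2.3 * energy / 1000 * np.exp(rng_food.normal(0, 0.3))),
                dairy_cup=float(0.9 * energy / 1000 * np.exp(rng_food.normal(0, 0.5))),
                added_sugars_tsp=float(13.0 * energy / 100.0 / 16.0
                                       * np.exp(rng_food.normal(0, 0.4))),
            )
            g.whole_fruit_cup = float(g.total_fruit_cup * rng_food.uniform(0.3, 0.7))

            day_rec = PersonDay(person_id=ids[i], day=day,
                                weekday_indicator=weekday, nutrients=nut, groups=g)
            person.days.append(day_rec)
            if config.include_foods:
                person.foods.extend(
                    _partition_foods(day_rec, is_walnut[i], food_code_pools, rng_food))
            elif is_walnut[i]:
                # keep nut-status classification possible without food records
                person.nut_status = "walnut"
        persons.append(person)

    truth = _build_truth(config, persons, design, ages, genders, races,
                         u_nut, weekday1, rng_truth)
    return persons, design, truth


def _partition_foods(day: PersonDay, walnut: bool, pools, rng) -> list[FoodRecord]:
    """Split a person-day into food records whose component-wise sum equals it."""
    cats = ["meat", "produce", "grain", "dairy", "mixed"]
    nut_shares = rng.dirichlet(np.ones(len(cats)) * 2.0)
    g = day.groups
    group_arrays = {c: FoodGroupVector() for c in cats}
    group_arrays["meat"] = FoodGroupVector(
        meat_oz=g.meat_oz, cured_meat_oz=g.cured_meat_oz, organ_meat_oz=g.organ_meat_oz)
    group_arrays["produce"] = FoodGroupVector(
        total_fruit_cup=g.total_fruit_cup, whole_fruit_cup=g.whole_fruit_cup,
        total_veg_cup=g.total_veg_cup, greens_beans_cup=g.greens_beans_cup)
    group_arrays["grain"] = FoodGroupVector(
        whole_grain_oz=g.whole_grain_oz, refined_grain_oz=g.refined_grain_oz,
        added_sugars_tsp=g.added_sugars_tsp)
    group_arrays["dairy"] = FoodGroupVector(dairy_cup=g.dairy_cup)
    mixed = FoodGroupVector(
        poultry_oz=g.poultry_oz, seafood_oz=g.seafood_oz, eggs_oz=g.eggs_oz,
        legumes_oz=g.legumes_oz, soy_oz=g.soy_oz,
        total_protein_oz=g.total_protein_oz,
        seafood_plant_protein_oz=g.seafood_plant_protein_oz)
    if not walnut:
        mixed.nuts_seeds_oz = g.nuts_seeds_oz
    group_arrays["mixed"] = mixed

    meat_oz_total = g.meat_oz + g.cured_meat_oz + g.organ_meat_oz
    grams = {
        "meat": meat_oz_total * GRAMS_PER_OZ,
        "produce": float(rng.uniform(150, 500)),
        "grain": float(rng.uniform(100, 400)),
        "dairy": float(rng.uniform(50, 400)),
        "mixed": float(rng.uniform(100, 500)),
    }
    wweia = {"meat": "Protein Foods-Meats", "produce": "Fruits and Vegetables",
             "grain": "Grains", "dairy": "Milk and Dairy", "mixed": "Mixed Dishes"}

    records = []
    for c, share in zip(cats, nut_shares):
        records.append(FoodRecord(
            person_id=day.person_id, day=day.day,
            food_code=str(rng.choice(pools[c])), walnut_flag=False,
            grams=grams[c],
            nutrients=NutrientVector.from_array(day.nutrients.as_array() * share),
            groups=group_arrays[c], wweia_category=wweia[c],
        ))
    if walnut and day.groups.nuts_seeds_oz > 0:
        records.append(FoodRecord(
            person_id=day.person_id, day=day.day,
            food_code=str(rng.choice(pools["nuts"])), walnut_flag=True,
            grams=day.groups.nuts_seeds_oz * 0.5 * GRAMS_PER_OZ,
            nutrients=NutrientVector(),
            groups=FoodGroupVector(nuts_seeds_oz=day.groups.nuts_seeds_oz),
            wweia_category="Nuts and Seeds",
        ))
    return records


def _build_truth(config, persons, design, ages, genders, races, u_nut,
                 weekday1, rng) -> TruthRecord:
    dri = default_dri()
    ids = [p.person_id for p in persons]
    usual, pop_mean, pcts = {}, {}, {}
    below, above = {}, {}
    su2, se2, lams = {}, {}, {}
    w = design.base_weights / design.base_weights.sum()
    n = len(persons)
    K = config.truth_draws_per_person
    for k in config.truth_nutrients:
        p = config.nutrient_params[k]
        lp = np.array([
            _transformed_linear_predictor(
                p, age_category(min(max(ages[i], 4.0), 85.0)), str(genders[i]),
                str(races[i]), 1, bool(weekday1[i]),
                persons[i].day_record(1).nutrients.energy)
            for i in range(n)
        ])
        usual[k] = _true_usual(p, lp, u_nut[k])
        pop_mean[k] = float(np.sum(w * usual[k]))
        # population distribution over persons x fresh u draws
        u_mc = rng.normal(0.0, p.sigma_u, (n, K))
        T = _true_usual(p, lp[:, None], u_mc)
        wr = np.repeat(w, K) / K
        order = np.argsort(T.ravel())
        tv, tw = T.ravel()[order], wr[order]
        cw = np.cumsum(tw)
        pos = (cw - 0.5 * tw) / cw[-1]
        pcts[k] = np.interp(np.arange(1, 100) / 100.0, pos, tv)
        thr = np.empty(n)
        kinds = []
        for i, person in enumerate(persons):
            v, kind = dri.lookup(k, person.gender, max(person.age_years, 4.0))
            thr[i] = v
            kinds.append(kind)
        frac_b = (T < thr[:, None]).mean(axis=1)
        below[k] = float(np.sum(w * frac_b))
        above[k] = float(np.sum(w * (1.0 - frac_b)))
        su2[k] = p.sigma_u ** 2
        se2[k] = p.sigma_e ** 2
        lams[k] = p.lam
    return TruthRecord(person_ids=ids, usual_intake=usual, pop_mean=pop_mean,
                       percentiles=pcts, frac_below_ear=below,
                       frac_above_ai=above, sigma_u2=su2, sigma_e2=se2, lam=lams)


def generate_prices(config: SimulationConfig) -> tuple[PriceTable, CPISeries]:
    """Seeded price table (base-year USD per 100 g) and CPI series by category.

    Meat and nut item prices are set so the per-oz costs equal the
    configured values exactly; other categories get lognormal prices around
    category-typical levels.  About 5% of codes are left unpriced to
    exercise imputation downstream.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(7)[6])
    cat_base = {"meat": None, "produce": 0.55, "grain": 0.45, "dairy": 0.50,
                "mixed": 0.80, "nuts": None}
    rows = []
    for cat in FOOD_CATEGORIES:
        for j in range(10):
            code = f"{cat.upper()}{j:03d}"
            if cat == "meat":
                price = config.meat_price_per_oz / GRAMS_PER_OZ * 100.0
            elif cat == "nuts":
                price = config.walnut_price_per_oz / GRAMS_PER_OZ * 100.0
            else:
                price = float(cat_base[cat] * np.exp(rng.normal(0.0, 0.3)))
            if cat not in ("meat", "nuts") and rng.random() < 0.05:
                continue  # unpriced: must be imputed by the cost stage
            rows.append({"food_code": code, "category": cat,
                         "price_per_100g": price, "imputed": False})
    prices = PriceTable(pd.DataFrame(rows),
                        meat_price_per_oz=config.meat_price_per_oz,
                        walnut_price_per_oz=config.walnut_price_per_oz)

    cpi_rows = []
    for cat in FOOD_CATEGORIES:
        drift = config.annual_inflation + float(rng.normal(0.0, 0.004))
        idx = 100.0
        for year in range(config.price_base_year, config.price_target_year + 1):
            cpi_rows.append({"category": cat, "year": year, "index": idx})
            idx *= (1.0 + drift)
    return prices, CPISeries(pd.DataFrame(cpi_rows))
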