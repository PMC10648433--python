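"""Healthy Eating Index 2015: 13-component piecewise-linear scoring,
the population-ratio method on day-1 intakes, and the walnut-for-meat
substitution adjustment applied at the constituent-amount level.

The population-ratio method computes survey-weighted mean constituent
amounts across persons FIRST and scores the mean amounts, i.e. a ratio of
means, not a mean of per-person ratios.  Confidence intervals come from
balanced repeated replication over the design's replicate weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .core import Person, PersonDay
from .survey import IntervalEstimate, SurveyDesign, brr_standard_error

__all__ = [
    "HEIStandards", "ComponentStandard", "HEIComponentAmounts", "HEIScore",
    "HEIAdjustmentProfile", "score_components", "amounts_from_personday",
    "population_ratio_score", "adjust_amounts_for_substitution",
]

KCAL_PER_TSP_ADDED_SUGAR = 16.0
KCAL_PER_G_FAT = 9.0


@dataclass(frozen=True)
class ComponentStandard:
    """One HEI component: density basis, full/zero-score standards, direction."""

    name: str
    max_points: float
    basis: str                 # per_1000kcal | pct_energy | fa_ratio
    full_standard: float       # density at which max points are awarded
    zero_standard: float       # density at/beyond which 0 points (moderation/ratio)
    adequacy: bool             # True: more is better


# Defaults are the published HEI-2015 scoring standards.
HEI2015_COMPONENTS: tuple[ComponentStandard, ...] = (
    ComponentStandard("total_fruit", 5, "per_1000kcal", 0.8, 0.0, True),
    ComponentStandard("whole_fruit", 5, "per_1000kcal", 0.4, 0.0, True),
    ComponentStandard("total_vegetables", 5, "per_1000kcal", 1.1, 0.0, True),
    ComponentStandard("greens_beans", 5, "per_1000kcal", 0.2, 0.0, True),
    ComponentStandard("whole_grains", 10, "per_1000kcal", 1.5, 0.0, True),
    ComponentStandard("dairy", 10, "per_1000kcal", 1.3, 0.0, True),
    ComponentStandard("total_protein", 5, "per_1000kcal", 2.5, 0.0, True),
    ComponentStandard("seafood_plant_protein", 5, "per_1000kcal", 0.8, 0.0, True),
    ComponentStandard("fatty_acid_ratio", 10, "fa_ratio", 2.5, 1.2, True),
    ComponentStandard("refined_grains", 10, "per_1000kcal", 1.8, 4.3, False),
    ComponentStandard("sodium", 10, "per_1000kcal", 1.1, 2.0, False),  # g/1000 kcal
    ComponentStandard("added_sugars", 10, "pct_energy", 6.4, 26.0, False),
    ComponentStandard("saturated_fats", 10, "pct_energy", 8.0, 16.0, False),
)


@dataclass
class HEIStandards:
    components: tuple[ComponentStandard, ...] = HEI2015_COMPONENTS

    def __post_init__(self) -> None:
        total = sum(c.max_points for c in self.components)
        if total != 100:
            raise ValueError(f"component max points must sum to 100, got {total}")
        n_adequacy = sum(c.adequacy for c in self.components)
        if n_adequacy != 9 or len(self.components) - n_adequacy != 4:
            raise ValueError("expected 9 adequacy and 4 moderation components")


@dataclass
class HEIComponentAmounts:
    """Raw constituent totals every component needs (one day or a weighted mean)."""

    energy: float                       # kcal
    total_fruit_cup: float = 0.0
    whole_fruit_cup: float = 0.0
    total_veg_cup: float = 0.0
    greens_beans_cup: float = 0.0
    whole_grain_oz: float = 0.0
    dairy_cup: float = 0.0
    total_protein_oz: float = 0.0
    seafood_plant_protein_oz: float = 0.0
    mufa_g: float = 0.0
    pufa_g: float = 0.0
    sfa_g: float = 0.0
    sodium_mg: float = 0.0
    refined_grain_oz: float = 0.0
    added_sugars_tsp: float = 0.0

    _ORDER = ("energy", "total_fruit_cup", "whole_fruit_cup", "total_veg_cup",
              "greens_beans_cup", "whole_grain_oz", "dairy_cup",
              "total_protein_oz", "seafood_plant_protein_oz", "mufa_g",
              "pufa_g", "sfa_g", "sodium_mg", "refined_grain_oz",
              "added_sugars_tsp")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self._ORDER], dtype=float)

    @classmethod
    def from_array(cls, a) -> "HEIComponentAmounts":
        return cls(**dict(zip(cls._ORDER, np.asarray(a, dtype=float).tolist())))


@dataclass
class HEIScore:
    components: dict[str, float]
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = float(sum(self.components.values()))


def _density(amounts: HEIComponentAmounts, comp: ComponentStandard) -> float:
    e = amounts.energy
    if e <= 0:
        raise ValueError("energy must be > 0 for density-based scoring")
    raw = {
        "total_fruit": amounts.total_fruit_cup,
        "whole_fruit": amounts.whole_fruit_cup,
        "total_vegetables": amounts.total_veg_cup,
        "greens_beans": amounts.greens_beans_cup,
        "whole_grains": amounts.whole_grain_oz,
        "dairy": amounts.dairy_cup,
        "total_protein": amounts.total_protein_oz,
        "seafood_plant_protein": amounts.seafood_plant_protein_oz,
        "refined_grains": amounts.refined_grain_oz,
    }
    if comp.basis == "per_1000kcal":
        if comp.name == "sodium":
            return (amounts.sodium_mg / 1000.0) / (e / 1000.0)  # g per 1000 kcal
        return raw[comp.name] / (e / 1000.0)
    if comp.basis == "pct_energy":
        if comp.name == "added_sugars":
            return 100.0 * amounts.added_sugars_tsp * KCAL_PER_TSP_ADDED_SUGAR / e
        return 100.0 * amounts.sfa_g * KCAL_PER_G_FAT / e
    # fatty-acid ratio (MUFA + PUFA) / SFA
    if amounts.sfa_g <= 0:
        return np.inf if (amounts.mufa_g + amounts.pufa_g) > 0 else 0.0
    return (amounts.mufa_g + amounts.pufa_g) / amounts.sfa_g


def _score_one(density: float, comp: ComponentStandard) -> float:
    if comp.basis == "fa_ratio" or not comp.adequacy:
        # linear interpolation between the zero-score and full-score standards
        lo, hi = comp.zero_standard, comp.full_standard
        if comp.adequacy:  # ratio: higher is better
            frac = (density - lo) / (hi - lo)
        else:              # moderation: lower is better
            frac = (density - lo) / (hi - lo)
        return float(comp.max_points * np.clip(frac, 0.0, 1.0))
    # simple adequacy: proportional up to the full-score standard
    return float(comp.max_points * min(1.0, density / comp.full_standard))


def score_components(
    amounts: HEIComponentAmounts,
    standards: HEIStandards | None = None,
) -> HEIScore:
    """Score all 13 components from raw amounts; total in [0, 100]."""
    standards = standards or HEIStandards()
    scores = {c.name: _score_one(_density(amounts, c), c) for c in standards.components}
    return HEIScore(components=scores)


def amounts_from_personday(day: PersonDay) -> HEIComponentAmounts:
    g, n = day.groups, day.nutrients
    return HEIComponentAmounts(
        energy=n.energy,
        total_fruit_cup=g.total_fruit_cup, whole_fruit_cup=g.whole_fruit_cup,
        total_veg_cup=g.total_veg_cup, greens_beans_cup=g.greens_beans_cup,
        whole_grain_oz=g.whole_grain_oz, dairy_cup=g.dairy_cup,
        total_protein_oz=g.total_protein_oz,
        seafood_plant_protein_oz=g.seafood_plant_protein_oz,
        mufa_g=n.mufa, pufa_g=n.pufa, sfa_g=n.sat_fat, sodium_mg=n.sodium,
        refined_grain_oz=g.refined_grain_oz, added_sugars_tsp=g.added_sugars_tsp,
    )


# Published per-oz addition/subtraction vectors for adjusting HEI constituent
# amounts under the walnut-for-meat replacement.  These are intentionally kept
# separate from the substitution engine's composition profile: the walnut
# sodium value (0.567 mg/oz) and the meat MUFA/PUFA/sodium values appear only
# in this adjustment.  Note the meat subtraction lists 1 oz eq of seafood &
# plant proteins even though meat is not normally part of that component; the
# literal arithmetic is preserved by default and can be switched off.
@dataclass(frozen=True)
class HEIAdjustmentProfile:
    walnut_mufa_g: float = 2.53
    walnut_pufa_g: float = 13.4
    walnut_sfa_g: float = 1.74
    walnut_energy_kcal: float = 185.0
    walnut_total_protein_ozeq: float = 2.0
    walnut_seafood_plant_ozeq: float = 2.0
    walnut_sodium_mg: float = 0.567
    meat_mufa_g: float = 0.87
    meat_pufa_g: float = 0.12
    meat_sfa_g: float = 0.76
    meat_energy_kcal: float = 49.0
    meat_total_protein_ozeq: float = 1.0
    meat_seafood_plant_ozeq: float = 1.0
    meat_sodium_mg: float = 127.0
    literal_seafood_plant_subtraction: bool = True


def adjust_amounts_for_substitution(
    amounts: HEIComponentAmounts,
    r: float,
    profile: HEIAdjustmentProfile | None = None,
) -> HEIComponentAmounts:
    """amounts + w*walnut - r*meat with w = 0.5 r, clipped at zero."""
    if r < 0:
        raise ValueError("r must be >= 0")
    p = profile or HEIAdjustmentProfile()
    w = 0.5 * r
    meat_sp = p.meat_seafood_plant_ozeq if p.literal_seafood_plant_subtraction else 0.0
    out = replace(
        amounts,
        energy=amounts.energy + w * p.walnut_energy_kcal - r * p.meat_energy_kcal,
        mufa_g=amounts.mufa_g + w * p.walnut_mufa_g - r * p.meat_mufa_g,
        pufa_g=amounts.pufa_g + w * p.walnut_pufa_g - r * p.meat_pufa_g,
        sfa_g=amounts.sfa_g + w * p.walnut_sfa_g - r * p.meat_sfa_g,
        sodium_mg=amounts.sodium_mg + w * p.walnut_sodium_mg - r * p.meat_sodium_mg,
        total_protein_oz=amounts.total_protein_oz
        + w * p.walnut_total_protein_ozeq - r * p.meat_total_protein_ozeq,
        seafood_plant_protein_oz=amounts.seafood_plant_protein_oz
        + w * p.walnut_seafood_plant_ozeq - r * meat_sp,
    )
    return HEIComponentAmounts.from_array(np.clip(out.as_array(), 0.0, None))


def _mean_amounts(
    persons: Sequence[Person],
    weights: np.ndarray,
    doses_r: np.ndarray | None,
    profile: HEIAdjustmentProfile | None,
    day: int,
) -> HEIComponentAmounts:
    rows = []
    for i, p in enumerate(persons):
        d = p.day_record(day)
        a = amounts_from_personday(d)
        if doses_r is not None and doses_r[i] > 0:
            a = adjust_amounts_for_substitution(a, float(doses_r[i]), profile)
        rows.append(a.as_array())
    mat = np.vstack(rows)
    w = weights / weights.sum()
    return HEIComponentAmounts.from_array(w @ mat)


def population_ratio_score(
    persons: Sequence[Person],
    design: SurveyDesign,
    day: int = 1,
    dose_meat_oz: float = 0.0,
    adjustment: HEIAdjustmentProfile | None = None,
    standards: HEIStandards | None = None,
) -> tuple[HEIScore, IntervalEstimate]:
    """Population-ratio HEI for the given dose, with a BRR CI on the total.

    Under a nonzero dose each person's day-1 amounts are adjusted with that
    person's own capped replacement r_i = min(dose, reported meat oz eq).
    """
    from .substitution import meat_oz_equivalents  # local: avoid cycle

    persons = list(persons)
    missing = [p.person_id for p in persons if p.day_record(day) is None]
    if missing:
        raise ValueError(f"persons without day {day}: {missing[:5]}")
    sub = design.subset([p.person_id for p in persons])

    doses_r = None
    if dose_meat_oz > 0:
        doses_r = np.array(
            [min(dose_meat_oz, meat_oz_equivalents(p.day_record(day))) for p in persons]
        )

    def total_under(weights: np.ndarray) -> float:
        mean = _mean_amounts(persons, weights, doses_r, adjustment, day)
        if mean.energy <= 0:
            raise ValueError("zero weighted energy")
        return score_components(mean, standards).total

    interval = brr_standard_error(total_under, sub)
    mean = _mean_amounts(persons, sub.base_weights, doses_r, adjustment, day)
    return score_components(mean, standards), interval
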