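"""Dose-escalation replacement engine: remove meat oz equivalents, add
walnuts at the 0.5-oz-per-1-oz-eq Protein Foods ratio, and apply the
per-ounce nutrient deltas to each recall day independently.

Meat here is the sum of the meat, cured-meat and organ-meat food-pattern
categories; poultry is explicitly excluded.  Replacement is capped at the
reported meat amount, so a day with 2.5 oz of meat under a 4-oz dose has
2.5 oz removed and 1.25 oz of walnuts added.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .core import (
    FoodCompositionProfile,
    NutrientVector,
    Person,
    PersonDay,
    scale_and_add,
)

__all__ = ["DoseLevel", "SubstitutionResult", "meat_oz_equivalents",
           "substitute", "apply_dose_series", "DOSES"]

NEG_TOL = 1e-6


@dataclass(frozen=True)
class DoseLevel:
    """A replacement dose: target meat oz eq removed; walnut oz = half of that."""

    meat_target_oz: float

    def __post_init__(self) -> None:
        if self.meat_target_oz <= 0:
            raise ValueError("meat_target_oz must be > 0")

    @property
    def walnut_oz(self) -> float:
        # 1 oz meat and 0.5 oz nuts are both 1 oz eq of Protein Foods
        return 0.5 * self.meat_target_oz


DOSES = tuple(DoseLevel(d) for d in (1.0, 2.0, 3.0, 4.0))


@dataclass
class SubstitutionResult:
    person_id: str
    day: int
    dose: DoseLevel
    meat_removed_oz: float
    walnut_added_oz: float
    modified: PersonDay
    delta: NutrientVector
    clipped: bool = False


def meat_oz_equivalents(day: PersonDay) -> float:
    """Meat + cured meat + organ meat oz eq; poultry excluded."""
    g = day.groups
    return g.meat_oz + g.cured_meat_oz + g.organ_meat_oz


def substitute(
    day: PersonDay,
    dose: DoseLevel,
    profile: FoodCompositionProfile | None = None,
) -> SubstitutionResult:
    """Replace up to ``dose.meat_target_oz`` of reported meat with walnuts.

    r = min(dose, available meat); w = 0.5 r.  The nutrient delta is
    w * walnut_per_oz - r * meat_per_oz, applied with clipping at zero.
    Food-pattern amounts: the three meat categories are reduced
    proportionally, nuts and seeds gain w oz, and total protein oz eq is
    unchanged (r oz eq out, w oz walnuts = r oz eq in).
    """
    if profile is None:
        profile = FoodCompositionProfile()
    available = meat_oz_equivalents(day)
    r = min(dose.meat_target_oz, available)
    w = 0.5 * r

    delta = scale_and_add(
        scale_and_add(NutrientVector(), profile.walnut_per_oz, w),
        profile.meat_per_oz, -r,
    )
    raw = day.nutrients.as_array() + delta.as_array()
    clipped = bool(np.any(raw < -NEG_TOL))
    new_nutrients = NutrientVector.from_array(np.clip(raw, 0.0, None))

    g = copy.deepcopy(day.groups)
    if r > 0 and available > 0:
        keep = 1.0 - r / available
        g.meat_oz *= keep
        g.cured_meat_oz *= keep
        g.organ_meat_oz *= keep
        g.nuts_seeds_oz += w
        # 0.5 oz nuts = 1 oz eq, so w oz walnuts contribute r oz eq:
        # total protein is conserved, seafood & plant proteins gain r oz eq.
        g.seafood_plant_protein_oz += r

    modified = PersonDay(
        person_id=day.person_id, day=day.day,
        weekday_indicator=day.weekday_indicator,
        nutrients=new_nutrients, groups=g,
    )
    return SubstitutionResult(
        person_id=day.person_id, day=day.day, dose=dose,
        meat_removed_oz=r, walnut_added_oz=w,
        modified=modified, delta=delta, clipped=clipped,
    )


def apply_dose_series(
    person: Person,
    profile: FoodCompositionProfile | None = None,
    doses: tuple[DoseLevel, ...] = DOSES,
) -> dict[float, Person]:
    """Apply each dose independently to every recall day; keys are meat oz targets.

    Dose 0.0 maps to the unmodified person (a deep copy) so downstream
    stages can treat the current diet as just another dose level.
    """
    out: dict[float, Person] = {0.0: copy.deepcopy(person)}
    for dose in doses:
        p = copy.deepcopy(person)
        p.days = [substitute(d, dose, profile).modified for d in person.days]
        out[dose.meat_target_oz] = p
    return out
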