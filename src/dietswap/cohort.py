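"""Sample construction: nut-status classification, ordered exclusion rules,
age-gender reporting groups, and the survey-weighted protein-food
composition summary.

The analysis population is restricted to no-nut consumers aged 4 and over
with reliable recalls, plausible day-1 energy, complete animal-protein
fields, and no pregnancy/lactation (women 20-44).  Exclusion rules fire in
a fixed order and each excluded person carries exactly one (first-match)
reason, so the accounting is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Person
from .survey import SurveyDesign, weighted_mean

__all__ = [
    "classify_nut_status", "apply_exclusions", "assign_groups",
    "protein_food_summary", "ELEMENTARY_GROUPS", "ROLLUP_GROUPS",
    "group_members",
]

# kcal bounds are inclusive: only strictly below 500 or strictly above 5000
# is excluded.
ENERGY_MIN_KCAL = 500.0
ENERGY_MAX_KCAL = 5000.0


def classify_nut_status(person: Person) -> str:
    """walnut if any food maps to a walnut-containing code; else other_nut if
    any day reports nonzero nuts-and-seeds oz eq; else no_nut."""
    if any(f.walnut_flag for f in person.foods):
        return "walnut"
    if any(d.groups.nuts_seeds_oz > 0 for d in person.days):
        return "other_nut"
    return "no_nut"


@dataclass(frozen=True)
class ExclusionRule:
    name: str
    description: str
    order: int


EXCLUSION_RULES = (
    ExclusionRule("age_or_breast_milk", "younger than 4 years or consuming breast milk", 0),
    ExclusionRule("pregnant_lactating", "pregnant or lactating woman aged 20-44", 1),
    ExclusionRule("unreliable_recall", "recall not flagged complete and reliable", 2),
    ExclusionRule("energy_out_of_range", "day-1 energy below 500 or above 5000 kcal", 3),
    ExclusionRule("missing_animal_protein", "missing animal-protein food-pattern fields", 4),
    ExclusionRule("nut_consumer", "walnut or other-nut consumer", 5),
)


def _exclusion_reason(person: Person) -> str | None:
    if person.age_years < 4 or person.breast_milk:
        return "age_or_breast_milk"
    if (person.gender == "female" and person.pregnant_or_lactating
            and 20 <= person.age_years <= 44):
        return "pregnant_lactating"
    if not person.reliable_recall:
        return "unreliable_recall"
    d1 = person.day_record(1)
    if d1 is None:
        return "unreliable_recall"
    if d1.nutrients.energy < ENERGY_MIN_KCAL or d1.nutrients.energy > ENERGY_MAX_KCAL:
        return "energy_out_of_range"
    if person.animal_protein_missing:
        return "missing_animal_protein"
    if person.nut_status is None:
        raise ValueError(f"person {person.person_id} has no nut_status; classify first")
    if person.nut_status != "no_nut":
        return "nut_consumer"
    return None


def apply_exclusions(persons: Iterable[Person]) -> tuple[list[Person], pd.DataFrame]:
    """Split into (included, exclusion log).  Classification is run first for
    any person whose nut_status is unset."""
    included: list[Person] = []
    log_rows = []
    for p in persons:
        if p.nut_status is None:
            p.nut_status = classify_nut_status(p)
        reason = _exclusion_reason(p)
        if reason is None:
            included.append(p)
        else:
            log_rows.append({"person_id": p.person_id, "reason": reason})
    log = pd.DataFrame(log_rows, columns=["person_id", "reason"])
    return included, log


# Elementary reporting groups; 71+ is not split by gender by convention.
ELEMENTARY_GROUPS = (
    ("male", 4, 8, "Male 4-8"), ("male", 9, 13, "Male 9-13"),
    ("male", 14, 18, "Male 14-18"),
    ("female", 4, 8, "Female 4-8"), ("female", 9, 13, "Female 9-13"),
    ("female", 14, 18, "Female 14-18"),
    ("male", 19, 50, "Male 19-50"), ("male", 51, 70, "Male 51-70"),
    ("female", 19, 50, "Female 19-50"), ("female", 51, 70, "Female 51-70"),
    ("any", 71, 200, "Adult 71+"),
)

ROLLUP_GROUPS = {
    "Male 4-18": ("male", 4, 18), "Female 4-18": ("female", 4, 18),
    "Child 4-18": ("any", 4, 18),
    "Adult 19-50": ("any", 19, 50), "Adult 51-70": ("any", 51, 70),
    "Male 19+": ("male", 19, 200), "Female 19+": ("female", 19, 200),
    "Adult 19+": ("any", 19, 200),
}


def assign_groups(persons: Sequence[Person]) -> dict[str, str]:
    """Map person_id -> elementary group label (each person in exactly one)."""
    out = {}
    for p in persons:
        label = None
        years = int(p.age_years)  # completed years
        for gender, lo, hi, name in ELEMENTARY_GROUPS:
            if lo <= years <= hi and gender in (p.gender, "any"):
                label = name
                break
        if label is None:
            raise ValueError(f"age {p.age_years} outside all group bands")
        out[p.person_id] = label
    return out


def group_members(persons: Sequence[Person], label: str) -> list[Person]:
    """Persons belonging to an elementary or roll-up group."""
    if label in ROLLUP_GROUPS:
        gender, lo, hi = ROLLUP_GROUPS[label]
    else:
        match = [g for g in ELEMENTARY_GROUPS if g[3] == label]
        if not match:
            raise KeyError(f"unknown group {label!r}")
        gender, lo, hi, _ = match[0]
    return [p for p in persons
            if lo <= int(p.age_years) <= hi and gender in (p.gender, "any")]


PROTEIN_SOURCES = ("meats", "poultry", "seafood", "eggs", "legumes", "soy")


def _source_oz(p: Person, source: str) -> float:
    """Mean over available days of the source's oz eq."""
    vals = []
    for d in p.days:
        g = d.groups
        if source == "meats":
            vals.append(g.meat_oz + g.cured_meat_oz + g.organ_meat_oz)
        else:
            vals.append(getattr(g, f"{source}_oz"))
    return float(np.mean(vals))


def protein_food_summary(
    persons: Sequence[Person],
    design: SurveyDesign,
    groups: Sequence[str] = ("Male 4-18", "Female 4-18", "Child 4-18",
                             "Male 19+", "Female 19+", "Adult 19+"),
) -> pd.DataFrame:
    """Weighted mean protein-food oz eq and percent shares by group.

    Shares are 100 * source mean / total mean; a zero total yields missing
    shares.  Totals here are the sum of the six sources (animal + legume +
    soy protein foods).
    """
    rows = []
    for label in groups:
        members = group_members(persons, label)
        if not members:
            continue
        sub = design.subset([p.person_id for p in members])
        means = {
            s: weighted_mean([_source_oz(p, s) for p in members], sub.base_weights)
            for s in PROTEIN_SOURCES
        }
        total = float(sum(means.values()))
        row = {"group": label, "total_oz": total}
        for s in PROTEIN_SOURCES:
            row[f"{s}_oz"] = means[s]
            row[f"{s}_share_pct"] = 100.0 * means[s] / total if total > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
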