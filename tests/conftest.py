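"""Shared fixtures: a seeded mid-size synthetic cohort and small builders."""

from __future__ import annotations

import numpy as np
import pytest

from dietswap.cohort import apply_exclusions
from dietswap.core import FoodGroupVector, NutrientVector, Person, PersonDay
from dietswap.simulate import SimulationConfig, generate_cohort
from dietswap.survey import SurveyDesign


@pytest.fixture(scope="session")
def sim_bundle():
    """One mid-size cohort shared across tests (seed-pinned)."""
    config = SimulationConfig(seed=11, n_persons=800)
    persons, design, truth = generate_cohort(config)
    return config, persons, design, truth


@pytest.fixture(scope="session")
def included_cohort(sim_bundle):
    _, persons, design, _ = sim_bundle
    included, log = apply_exclusions(persons)
    return included, log, design


def make_personday(person_id="p1", day=1, meat_oz=0.0, cured_oz=0.0,
                   organ_oz=0.0, poultry_oz=0.0, **nutrients) -> PersonDay:
    groups = FoodGroupVector(
        meat_oz=meat_oz, cured_meat_oz=cured_oz, organ_meat_oz=organ_oz,
        poultry_oz=poultry_oz,
        total_protein_oz=meat_oz + cured_oz + organ_oz + poultry_oz,
    )
    return PersonDay(person_id=person_id, day=day, weekday_indicator=True,
                     nutrients=NutrientVector(**nutrients), groups=groups)


def make_person(person_id="p1", age=30.0, gender="male", days=None,
                **kwargs) -> Person:
    p = Person(person_id=person_id, age_years=age, gender=gender,
               race="nh_white", income_band="20to75k",
               education_band="hs", nut_status="no_nut", **kwargs)
    p.days = days or []
    for d in p.days:
        d.person_id = person_id
    return p


def trivial_design(person_ids, n_replicates=4, fay=0.0) -> SurveyDesign:
    """Equal weights, replicates equal to base: SE 0, point = plain mean."""
    n = len(person_ids)
    return SurveyDesign(
        person_ids=np.array(person_ids),
        base_weights=np.ones(n),
        replicate_weights=np.ones((n, n_replicates)),
        fay=fay,
    )
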