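import numpy as np
import pytest

from rvpedsim import HazardModel, Individual, Pedigree
from rvpedsim.synthetic import make_synthetic_hazards


def make_ped(rows, family_id=1, founder_id=1):
    """Build a toy pedigree from dicts of Individual fields."""
    ped = Pedigree(family_id, founder_id=founder_id)
    for row in rows:
        ped.add(Individual(family_id=family_id, **row))
    ped.validate()
    return ped


def constant_hazards(onset=0.0, death_u=0.0, death_a=None, max_age=100.0, n_bins=1):
    """Hazard model with constant rates on [0, max_age)."""
    if death_a is None:
        death_a = death_u
    part = np.linspace(0.0, max_age, n_bins + 1)
    ones = np.ones(n_bins)
    return HazardModel(
        partition=part,
        onset_pop=onset * ones,
        death_unaffected=death_u * ones,
        death_affected=death_a * ones,
    )


@pytest.fixture(scope="session")
def synthetic_hazards():
    return make_synthetic_hazards()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture()
def parent_child_ped():
    """Founder (1) x married-in (2) -> child (3)."""
    return make_ped(
        [
            dict(individual_id=1, sex="M", affected=True, birth_year=1940, onset_year=1990),
            dict(individual_id=2, sex="F", affected=None),
            dict(individual_id=3, sex="F", father_id=1, mother_id=2, affected=True,
                 birth_year=1965, onset_year=2005),
        ]
    )


@pytest.fixture()
def three_gen_ped():
    """Three generations:

    1 x 2 -> 3, 4 ; 3 x 5 -> 6, 9 ; 4 x 7 -> 8

    so (3,4) are siblings, (1,6) grandparent-grandchild, (4,6) avuncular,
    (6,8) first cousins, (6,9) siblings.
    """
    return make_ped(
        [
            dict(individual_id=1, sex="M", birth_year=1920),
            dict(individual_id=2, sex="F", affected=None),
            dict(individual_id=3, sex="M", father_id=1, mother_id=2, birth_year=1945),
            dict(individual_id=4, sex="F", father_id=1, mother_id=2, birth_year=1948),
            dict(individual_id=5, sex="F", affected=None),
            dict(individual_id=7, sex="M", affected=None),
            dict(individual_id=6, sex="F", father_id=3, mother_id=5, birth_year=1970),
            dict(individual_id=9, sex="M", father_id=3, mother_id=5, birth_year=1973),
            dict(individual_id=8, sex="M", father_id=7, mother_id=4, birth_year=1972),
        ]
    )
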