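import numpy as np
import pytest
from hypothesis import settings

from childmort.graphs import make_lattice_adjacency
from childmort.records import ChildRecord, WomanRecord

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def lattice22():
    return make_lattice_adjacency(2, 2)


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def make_woman(woman_id=1, county="c01", age_years=30, interview_month=2010 * 12,
               children=()):
    """Helper: a woman of given age with (birth_offset_months_before_interview,
    death_age_or_None) children."""
    kids = tuple(
        ChildRecord(birth_month=interview_month - off, death_age_months=dam)
        for off, dam in children)
    return WomanRecord(woman_id, county, interview_month - age_years * 12,
                       interview_month, kids)


@pytest.fixture
def woman_factory():
    return make_woman


def random_women(rng, n=100, county="c01", interview_month=2010 * 12 + 6):
    """A mixed fixture population for tally oracles: random ages, random
    numbers of children, random survival outcomes."""
    women = []
    for i in range(n):
        age = int(rng.integers(15, 50))
        n_kids = int(rng.poisson(max(0.0, (age - 16) * 0.18)))
        kids = []
        for _ in range(n_kids):
            max_off = age * 12 - 15 * 12
            off = int(rng.integers(0, max(1, max_off)))
            dam = None
            if rng.random() < 0.12:
                dam = int(rng.integers(0, 60))
                if dam > off:  # death would fall after interview: censored
                    dam = None
            kids.append((off, dam))
        women.append(make_woman(i, county, age, interview_month, tuple(kids)))
    return women


@pytest.fixture
def mixed_population(rng):
    return random_women(rng)
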