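import numpy as np
import pytest

from stressg import pedigree as pg
from stressg import simulate as sim


@pytest.fixture(scope="session")
def textbook_pedigree():
    """Founders A-D, full sibs X/Y (A x B), half sib Z (A x C)."""
    recs = [pg.PedigreeRecord(i) for i in "ABCD"]
    recs += [
        pg.PedigreeRecord("X", "A", "B"),
        pg.PedigreeRecord("Y", "A", "B"),
        pg.PedigreeRecord("Z", "A", "C"),
    ]
    return pg.validate_and_sort(recs)


@pytest.fixture(scope="session")
def sib_mating_pedigree():
    """Full-sib mating: E is the offspring of full sibs C x D."""
    recs = [
        pg.PedigreeRecord("A"),
        pg.PedigreeRecord("B"),
        pg.PedigreeRecord("C", "A", "B"),
        pg.PedigreeRecord("D", "A", "B"),
        pg.PedigreeRecord("E", "C", "D"),
    ]
    return pg.validate_and_sort(recs)


@pytest.fixture(scope="session")
def default_study():
    """A complete synthetic study at the reference design (~600 fish)."""
    return sim.generate_study(seed=7101)


@pytest.fixture(scope="session")
def default_A(default_study):
    return pg.additive_relationship_matrix(default_study.pedigree)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
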