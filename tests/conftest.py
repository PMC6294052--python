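import numpy as np
import pytest

from foundersim import genetics
from foundersim._state import get_space


@pytest.fixture
def rng():
    return np.random.default_rng(20231109)


def pair(h1, h2):
    return genetics.PairDiplotype(tuple(h1), tuple(h2))


def genotype(*pairs):
    return genetics.Genotype(tuple(pairs))


def neutral_homozygote(allele, n=1):
    """n-pair genotype homozygous for one neutral allele, no selected loci."""
    return genotype(*(pair((allele,), (allele,)) for _ in range(n)))


@pytest.fixture(scope="session")
def space_n2_selected():
    return get_space(2, True)


@pytest.fixture(scope="session")
def space_n2_neutral():
    return get_space(2, False)


@pytest.fixture(scope="session")
def space_n5_neutral():
    return get_space(5, False)
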