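import random

import pytest

from sablast import Sequence, blosum50
from sablast.seq_io import PROTEIN_ALPHABET


@pytest.fixture(scope="session")
def matrix():
    return blosum50()


@pytest.fixture
def demo_query():
    """The eight-residue worked-example query used throughout the docs."""
    return Sequence("demo", "PQGEFGVY")


@pytest.fixture
def rng():
    return random.Random(20120904)


def random_protein(rng, length, alphabet=PROTEIN_ALPHABET):
    return "".join(rng.choice(alphabet) for _ in range(length))
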