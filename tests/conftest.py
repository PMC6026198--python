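import numpy as np
import pytest

from linclust.alphabet import default_alphabet, load_blosum62


@pytest.fixture(scope="session")
def blosum():
    """(JointDistribution, score matrix) of the embedded Blosum62 tables."""
    return load_blosum62()


@pytest.fixture(scope="session")
def scores(blosum):
    return blosum[1]


@pytest.fixture(scope="session")
def alpha13():
    """The default 13-letter reduced alphabet (12 groups + wildcard)."""
    return default_alphabet(13)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_protein(rng, length):
    from linclust.alphabet import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
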