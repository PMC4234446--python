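import numpy as np
import pytest

from cisbind.motif_model import NucleotideMotif, motif_from_sequences
from cisbind.synthetic_data import SynthConfig, generate_database


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sharp_motif():
    """A sharp, non-palindromic 10-column motif."""
    return motif_from_sequences(["GCACGTGGAG"] * 6, id="gbox10")


@pytest.fixture
def soft_motif():
    counts = np.array([[6, 1, 1, 2], [1, 7, 1, 1], [2, 2, 4, 2],
                       [1, 1, 1, 7], [5, 2, 2, 1], [1, 1, 6, 2]],
                      dtype=float)
    return NucleotideMotif(id="soft6", counts=counts, nsites=10)


@pytest.fixture(scope="session")
def small_synth():
    """One seeded synthetic database shared by read-only tests."""
    cfg = SynthConfig(seed=0)
    db, proteome, truth = generate_database(cfg)
    return cfg, db, proteome, truth


def random_motif(rng, width, info=30.0, id="m"):
    cols = []
    for _ in range(width):
        alpha = np.full(4, 0.6)
        alpha[rng.integers(4)] = info
        cols.append(rng.dirichlet(alpha))
    return NucleotideMotif(id=id, counts=np.array(cols), nsites=10)
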