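import numpy as np
import pytest

from tirpoly.simulate import synthetic_library
from tirpoly.te_model import TEConsensus, TELibrary


@pytest.fixture
def rng():
    # deliberately distinct from the sim_library seed: sharing a PCG
    # stream would replay the library's own draws as "random" sequence
    return np.random.default_rng(777)


@pytest.fixture(scope="session")
def sim_library():
    """The simulator's default classified library (two families per
    superfamily, proper TIRs)."""
    return synthetic_library(0)


@pytest.fixture(scope="session")
def tiny_library():
    """A minimal handmade library with known sequences."""
    r = np.random.default_rng(42)
    bases = "ACGT"

    def seq(n):
        return "".join(bases[i] for i in r.integers(0, 4, n))

    fams = [
        TEConsensus("DTT_X1", "DTT", "CTCCCTC" + seq(236) + "GAGGGAG"),
        TEConsensus("DTM_Y1", "DTM", "GAG" + seq(494) + "CTC"),
    ]
    return TELibrary(fams)


def random_seq(r, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in r.choice(4, size=n, p=p))
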