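import numpy as np
import pytest

from cytohet import GenomeSpec, simulate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_genome():
    """A 2-kb low-GC genome shared by alignment-oracle tests."""
    return simulate_genome(GenomeSpec(length=2000, gc=0.28, seed=7))


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
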