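import numpy as np
import pytest

from srnapipe import simulate
from srnapipe.mapping import build_index


@pytest.fixture(scope="session")
def demo():
    """Small simulated two-condition dataset with planted ground truth."""
    genome, sim, lib_plus, lib_minus = simulate.demo_dataset(
        seed=0, total_reads=20_000
    )
    return genome, sim, lib_plus, lib_minus


@pytest.fixture(scope="session")
def demo_genome(demo):
    return demo[0]


@pytest.fixture(scope="session")
def demo_index(demo_genome):
    return build_index(demo_genome.chromosomes)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
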