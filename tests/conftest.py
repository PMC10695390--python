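import numpy as np
import pytest
from hypothesis import settings

from phagei import synthetic

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def sim_spec():
    return synthetic.SimulationSpec(seed=3, n_genes=20)


@pytest.fixture(scope="session")
def sim_genome(sim_spec):
    return synthetic.generate_genome(sim_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
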