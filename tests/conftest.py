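import numpy as np
import pytest

from epicen.config import SimulationConfig
from epicen.genome import build_toy_genome


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def genome(config):
    g = build_toy_genome(config)
    for chrom in g.chrom_names:  # warm the context cache once per session
        g.contexts(chrom)
    return g


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
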