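import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from netspread import (
    GeneratorSpec,
    generate,
    make_small_fixtures,
    summarize,
    threshold_adjacency,
)

DEFAULT_SEED = 42
DEFAULT_THRESHOLD = 0.034


@pytest.fixture(scope="session")
def small_fixtures():
    return make_small_fixtures()


@pytest.fixture(scope="session")
def connectome():
    """Default synthetic connectome (weighted matrix, fixed seed)."""
    return generate(GeneratorSpec(rng_seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def connectome_graph(connectome):
    return threshold_adjacency(connectome, DEFAULT_THRESHOLD)


@pytest.fixture(scope="session")
def connectome_summary(connectome_graph):
    return summarize(connectome_graph)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
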