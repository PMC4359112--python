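import numpy as np
import pytest

from sparcoc import decompose_common_vector, generate_fig1_toy


@pytest.fixture(scope="session")
def toy():
    """The 20x20 rank-one-background + 5x5-block worked example."""
    return generate_fig1_toy(seed=1)


@pytest.fixture(scope="session")
def toy_decomposition(toy):
    """Exact common-vector decomposition of the toy at delta=0."""
    return decompose_common_vector(toy.M, delta=0.0, tol=1e-10, max_iter=20000)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
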