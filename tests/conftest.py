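import numpy as np
import pytest

from lsgc.simulate import benchmark_system, generate_ground_truth_network


@pytest.fixture(scope="session")
def small_system():
    """Off-benchmark miniature realization (D=25, N=400) for fast tests."""
    return benchmark_system(25, N=400, seed=42)


@pytest.fixture(scope="session")
def truth_net_100():
    """One benchmark-scale ground-truth network."""
    return generate_ground_truth_network(100, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
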