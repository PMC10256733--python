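import numpy as np
import pytest

from mrdiet import HarmonizedSet, SimulationTruth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_hset():
    """Five instruments on an exact line Gamma = 0.1 + 2 * gamma."""
    gamma = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    return HarmonizedSet.from_arrays(
        gamma, 0.01, 0.1 + 2.0 * gamma, 0.05
    )


def random_hset(rng, j=10):
    gamma = rng.uniform(0.05, 0.4, j) * rng.choice([-1.0, 1.0], j)
    sigma_gamma = rng.uniform(0.005, 0.02, j)
    Gamma = rng.normal(0.0, 0.3, j)
    sigma_Gamma = rng.uniform(0.02, 0.2, j)
    return HarmonizedSet.from_arrays(gamma, sigma_gamma, Gamma, sigma_Gamma)
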