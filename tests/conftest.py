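import numpy as np
import pytest

from kgcnet import CoupledMapConfig, GCConfig, simulate_coupled_maps


@pytest.fixture(scope="session")
def benchmark_run():
    """One seeded realization of the five-map benchmark system."""
    series, truth = simulate_coupled_maps(CoupledMapConfig(seed=42))
    return series, truth


@pytest.fixture(scope="session")
def kernel_config():
    return GCConfig(m=1, p=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
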