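import numpy as np
import pytest

from rfinet.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size synthetic dataset for fast structural tests."""
    return SimulationConfig(
        n_samples_per_group=10,
        n_mirna=60,
        n_mrna=300,
        n_mirna_modules=2,
        n_mrna_modules=3,
        mirna_module_size_range=(8, 12),
        module_size_range=(30, 40),
        n_de_mirna=3,
        utr_length=300,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
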