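import numpy as np
import pytest

from cgmfda import GenerativeConfig, make_grid
from cgmfda.simulate import simulate_fosr_dataset, simulate_mfpca_dataset


@pytest.fixture(scope="session")
def grid():
    return make_grid(0.0, 360.0, 5.0)


@pytest.fixture(scope="session")
def small_mfpca_data():
    """Modest two-level dataset with known truth, reused across tests."""
    cfg = GenerativeConfig(n_subjects=60, meals_per_subject=4, seed=42)
    dataset, truth = simulate_mfpca_dataset(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def small_fosr_data():
    cfg = GenerativeConfig(n_subjects=80, meals_per_subject=4, seed=43)
    dataset, covariates, truth = simulate_fosr_dataset(cfg)
    return cfg, dataset, covariates, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
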