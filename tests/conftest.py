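import numpy as np
import pytest

from fretpaint.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-molecule simulated 4G-Tract dataset with ground truth."""
    cfg = SimulationConfig(n_gtracts=4, k_on=4e-3, seed=12345)
    dataset, truths = simulate_dataset(cfg, 60)
    return cfg, dataset, truths


@pytest.fixture
def rng():
    return np.random.default_rng(20210310)
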