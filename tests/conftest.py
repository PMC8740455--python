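import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metacorr import SimulationConfig, simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """300-cell dataset with one strongly correlated pair and heavy dropout."""
    return simulate_dataset(
        SimulationConfig(
            n_genes=60, n_cells=300, zero_prob=0.9,
            latent_pairs=[(0, 1, 0.8)], seed=11,
        )
    )


@pytest.fixture(scope="session")
def two_type_dataset():
    """Two separable cell types with marker genes, for classification."""
    return simulate_dataset(
        SimulationConfig(
            n_genes=120, n_cells=800, zero_prob=0.9, n_types=2,
            n_marker_genes=12, marker_shift=1.0, seed=21,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
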