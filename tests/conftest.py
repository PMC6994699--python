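import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitoscreen import simulate as sim

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_config():
    """Small noise-free tile: fast to render, exact truth."""
    return sim.SimulationConfig(image_shape=(512, 512), cells_per_tile=6,
                                noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def small_tile(small_config):
    return sim.simulate_tile(small_config, "control", "baseline")


@pytest.fixture(scope="session")
def default_tile():
    """Full-size noise-free tile at default settings (20 cells)."""
    cfg = sim.SimulationConfig(noise_sd=0.0, seed=1)
    return sim.simulate_tile(cfg, "control", "baseline")


@pytest.fixture(scope="session")
def thin_tree_tile():
    """Width-1 mitochondria with frequent branching: skeleton truth."""
    cfg = sim.SimulationConfig(image_shape=(768, 768), cells_per_tile=6,
                               noise_sd=0.0, mito_width=1,
                               mito_count_per_cell=(8.0, 2.0),
                               branch_probability=0.45, seed=7)
    return sim.simulate_tile(cfg, "control", "baseline")


@pytest.fixture()
def rng():
    # fresh, fixed-seed stream per test: deterministic and independent
    # of test execution order
    return np.random.default_rng(0)
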