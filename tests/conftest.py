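import numpy as np
import pytest

from imcquant import (SimulationConfig, default_panel, simulate_image)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_config():
    """A quick 128x128 configuration for unit tests."""
    return SimulationConfig(image_height=128, image_width=128)


@pytest.fixture(scope="session")
def sim_treated(small_config, panel):
    """One simulated treated image plus its ground truth (shared, read-only)."""
    return simulate_image(small_config, "cisplatin", "m1", "img1", seed=42,
                          panel=panel)


@pytest.fixture(scope="session")
def sim_control(small_config, panel):
    return simulate_image(small_config, "control", "m1", "img1", seed=43,
                          panel=panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
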