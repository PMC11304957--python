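import numpy as np
import pytest
from hypothesis import settings

from cxxxscreen.library_space import enumerate_cxxx
from cxxxscreen.simulate import SimulationConfig, simulate_screen

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_screen():
    """Desk-scale screen on a 200-variant sub-library, all four conditions."""
    config = SimulationConfig(
        library_size=200,
        cfu_count=20_000,
        replicates=3,
        read_depth_per_replicate=20_000,
        seed=42,
    )
    return simulate_screen(config)


@pytest.fixture(scope="session")
def full_universe():
    return list(enumerate_cxxx())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
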