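import numpy as np
import pytest
from hypothesis import settings

from oncoscreen import SimulationConfig

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_config():
    """A fast, small-universe simulation configuration."""
    return SimulationConfig(seed=1, n_genes=200, n_rbp_genes=200,
                            samples_per_group=6, n_events_per_type=60)
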