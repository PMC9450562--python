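import numpy as np
import pytest
from hypothesis import settings

import reverb

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def branching_09():
    """One long reverberating-regime simulation (m=0.9), reused across tests."""
    cfg = reverb.BranchingConfig(m_true=0.9, h=1.0, steps=100_000, seed=12345)
    return reverb.simulate_branching(cfg)


@pytest.fixture(scope="session")
def small_raster():
    rng = np.random.default_rng(7)
    counts = rng.poisson(0.5, size=(12, 400))
    return reverb.SpikeRaster(counts=counts, dt=0.05)
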