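import numpy as np
import pytest

from pepfeat.map_io import FrameSpec
from pepfeat.simulate import SimulationConfig, simulate_map


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated map with truth: 12 features, narrow extent."""
    cfg = SimulationConfig(rt_span=1.5, mz_min=400.0, mz_max=410.0,
                           n_features=12, noise_trace_density=1.0,
                           missing_scan_probability=0.05, rng_seed=42)
    lcms_map, truth = simulate_map(cfg)
    return cfg, lcms_map, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def detect_frame():
    return FrameSpec(15, 211)
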