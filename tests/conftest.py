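import numpy as np
import pytest

from smcluster.config import config_from_dict


@pytest.fixture
def hole_cfg():
    """Noiseless hole scenario at the standard study conditions."""
    return config_from_dict({
        "seed": 11, "scenario": "hole", "a_max_um": 200.0, "C_per_s": 2e-3,
        "n_frames": 60, "frame_interval_s": 2000.0 / 59.0,
    })


@pytest.fixture
def rounding_cfg():
    return config_from_dict({
        "seed": 12, "scenario": "rounding", "eps0": -0.25,
        "gamma_over_eta_m_s": 1e-8, "r0_um": 100.0, "n_frames": 72,
    })


@pytest.fixture
def fusion_cfg():
    return config_from_dict({
        "seed": 13, "scenario": "fusion", "R1_um": 100.0, "R2_um": 100.0,
        "gamma_over_eta_m_s": 2.9e-9, "n_frames": 48,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
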