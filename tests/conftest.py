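import numpy as np
import pytest
from hypothesis import settings

from maxdex import Point2D, SimulationConfig

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small but otherwise default-parameterized simulated cohort."""
    return SimulationConfig(n_patients=10, seed=7)


@pytest.fixture
def noiseless_config():
    """Deterministic measurement model: no landmark noise, no rater effects,
    zero surrogate-glenoid offset — US and MRI must agree exactly."""
    return SimulationConfig(
        n_patients=8,
        seed=3,
        ai_sd=0.065,
        delta_mean=0.0,
        delta_sd=0.0,
        landmark_noise_us=0.0,
        landmark_noise_mri=0.0,
        rater_bias_sd=0.0,
        rater_within_sd=0.0,
    )


def circle_points(cx, cy, r, angles_deg):
    """Exact points on a circle at the given angles (degrees)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return [Point2D(cx + r * np.cos(t), cy + r * np.sin(t)) for t in a]
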