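"""Shared fixtures: analytic beats and small synthetic records."""

import logging

import numpy as np
import pytest

from coascreen.config import PipelineConfig
from coascreen.simulate import CohortConfig, PulseModelParams

logging.disable(logging.INFO)  # keep gate-decision logging out of test output


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def short_cfg():
    """Pipeline config with the session gate lowered to 60 s for short fixtures."""
    return PipelineConfig(min_session_s=60.0)


@pytest.fixture
def steady_params():
    """Pulse model with no heart-rate variability (deterministic periods)."""
    return PulseModelParams(heart_rate_sd=0.0)


@pytest.fixture
def clean_config():
    """60-s noiseless, artifact-free record conditions."""
    return CohortConfig(
        noise_sd=0.0, drift_amplitude=0.0, artifact_rate=0.0,
        duration_per_site=60.0, seed=0,
    )


def triangular_beat(fs: float = 125.0, rise_s: float = 0.2, fall_s: float = 0.6):
    """Piecewise-linear beat: 0->1 over ``rise_s``, 1->0 over ``fall_s``.

    Constant-slope limbs make every slope feature exact: the 20-80%
    chord equals the limb slope, and any 40-ms window inside a limb
    sees the limb slope.
    """
    n_rise = int(round(rise_s * fs))
    n_fall = int(round(fall_s * fs))
    rise = np.linspace(0.0, 1.0, n_rise + 1)
    fall = np.linspace(1.0, 0.0, n_fall + 1)
    samples = np.concatenate([rise, fall[1:]])
    return samples, n_rise  # (beat, peak offset)
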