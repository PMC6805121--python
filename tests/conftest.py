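"""Shared fixtures: a desk-scale configuration and a small cohort.

The small configuration shrinks the face window (100 px at 6 px/deg)
so FDM smoothing and searchlight tests stay fast while preserving every
geometric relation of the full-size window.
"""

import numpy as np
import pytest

from fpsa.config import PipelineConfig
from fpsa.simulate import make_subject_model, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig(
        crop_size=100,
        px_per_deg=6.0,
        screen_size=(320, 240),
        searchlight_px=30,
        searchlight_stride_px=5,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Eight subjects, one baseline + two generalization runs, with
    the generator's default injected anisotropy."""
    return simulate_cohort(
        8, seed=11, config=small_config, n_generalization_runs=2,
    )


@pytest.fixture(scope="session")
def flat_model(small_config):
    """A subject model without any condition modulation."""
    return make_subject_model(
        "S_flat", seed=5, config=small_config,
        specific_gain=0.0, unspecific_gain=0.0,
    )


@pytest.fixture(scope="session")
def angles():
    return np.arange(0, 360, 45)
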