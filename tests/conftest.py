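"""Shared fixtures: phantoms and pipeline products reused across tests.

Heavy artifacts (registration results) are session-scoped so the suite
pays for them once.
"""

import numpy as np
import pytest

from aoangio import (FusionConfig, MotionModel, PhantomSpec,
                     RegistrationConfig, generate_phantom, perfusion_map,
                     register_groupwise, render_frames, render_structural,
                     segment_vessels)


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def structural(default_phantom):
    return render_structural(default_phantom)


@pytest.fixture(scope="session")
def segmentation(structural):
    return segment_vessels(structural, FusionConfig())


@pytest.fixture(scope="session")
def still_flow_frames(default_phantom):
    """Flow on, zero motion, no noise: isolates the flow contrast."""
    return render_frames(default_phantom, 12, MotionModel(0.0, 0.0, seed=5),
                         noise_sd=0.0, flow_on=True, seed=7)


@pytest.fixture(scope="session")
def moving_frames(default_phantom):
    """Default-condition sequence: flow, motion, and sensor noise."""
    return render_frames(default_phantom, 12, MotionModel(seed=5),
                         noise_sd=0.02, flow_on=True, seed=7)


@pytest.fixture(scope="session")
def registration_result(moving_frames):
    return register_groupwise(moving_frames,
                              RegistrationConfig(sampler_seed=11))


@pytest.fixture(scope="session")
def perfusion(registration_result):
    return perfusion_map(registration_result.registered)
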