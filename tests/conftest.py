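import numpy as np
import pytest

from saccvigor.gaze_io import GazeTrace
from saccvigor.synthetic_gaze import AgentProfile, TaskGeometry, make_layout, synth_trial


@pytest.fixture
def geometry():
    return TaskGeometry()


@pytest.fixture
def noiseless_trial(geometry):
    """One noise-free synthetic trial: (trace, layout, ground-truth events)."""
    rng = np.random.default_rng(12345)
    agent = AgentProfile(noise_sd=0.0)
    layout = make_layout(geometry, rng)
    t, x, y, valid, events = synth_trial(layout, agent, (50, "100"), rng, geometry)
    return GazeTrace(t, x, y, valid, geometry.sampling_rate), layout, events


@pytest.fixture
def noisy_trial(geometry):
    rng = np.random.default_rng(54321)
    agent = AgentProfile(noise_sd=0.05)
    layout = make_layout(geometry, rng)
    t, x, y, valid, events = synth_trial(layout, agent, (50, "100"), rng, geometry)
    return GazeTrace(t, x, y, valid, geometry.sampling_rate), layout, events
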