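import numpy as np
import pytest

from sprintox.core import ChannelTrace, SprintTimeline
from sprintox.synthetic import ProtocolConfig, generate_study


@pytest.fixture(scope="session")
def protocol():
    return ProtocolConfig()


@pytest.fixture(scope="session")
def small_study():
    """Three participants, all three occlusion conditions, default presets."""
    return generate_study(n_participants=3, seed=11)


@pytest.fixture
def flat_trace():
    return ChannelTrace(np.zeros(3000), fs=10.0, channel="HHb")


def make_trace(values, fs=10.0, **kw):
    return ChannelTrace(np.asarray(values, dtype=float), fs=fs, **kw)


def make_timeline(n, sprint=10.0, recovery=20.0, first=30.0):
    return SprintTimeline.regular(n, sprint, recovery, first)
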