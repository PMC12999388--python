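import warnings

import numpy as np
import pytest

from emgsyn.io import EMGRecording, PhaseEvents
from emgsyn.synthetic import GroupSpec, make_trial

# pingouin emits pandas/scipy deprecation chatter on import; irrelevant here
warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=DeprecationWarning)


@pytest.fixture(scope="session")
def basic_trial():
    """One deterministic synthetic stroke trial (K_true=3, light noise)."""
    spec = GroupSpec("SG", k_true=3, noise_sd=0.02)
    return make_trial(spec, seed=123)


@pytest.fixture(scope="session")
def noisefree_trial():
    spec = GroupSpec("SG", k_true=3, noise_sd=0.0)
    return make_trial(spec, seed=7)


@pytest.fixture
def sine_recording():
    fs = 2000.0
    t = np.arange(4000) / fs
    data = np.vstack([np.sin(2 * np.pi * 5 * t),
                      np.sin(2 * np.pi * 100 * t)])
    return EMGRecording(["DEL", "BB"], data, fs)


@pytest.fixture
def simple_events():
    return PhaseEvents(0, 100, 200, 300, 499)
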