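import numpy as np
import pytest

from boutonkit.core import StimulusProtocol, Trace
from boutonkit.preprocess import BleachModel
from boutonkit.simulate import NoiseModel, transient_f_over_f0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def double_bleach():
    """The strongly bleaching control model used across the suite."""
    return BleachModel(a1=0.6, tau1_s=5.0, a2=0.4, tau2_s=50.0, c=0.0)


@pytest.fixture
def noiseless():
    return NoiseModel.noiseless()


@pytest.fixture
def train_10x20hz():
    return StimulusProtocol(onset_time_s=1.0, n_stimuli=10, frequency_hz=20.0)


def make_normalized_traces(n, n_responders, seed, noise_sd=0.02,
                           amp_per_stim=0.1, tau_decay_s=0.5,
                           dt=0.098, n_pre=20, n_post=60):
    """F/F0 trace set with known responder labels (onset at t = 0)."""
    rng = np.random.default_rng(seed)
    t = np.arange(-n_pre, n_post) * dt
    stim = StimulusProtocol(onset_time_s=0.0, n_stimuli=10, frequency_hz=20.0)
    labels = np.zeros(n, dtype=bool)
    labels[:n_responders] = True
    rng.shuffle(labels)
    traces = []
    for i in range(n):
        c = (transient_f_over_f0(t, stim, amp_per_stim, tau_decay_s, 2.0)
             if labels[i] else np.zeros_like(t))
        y = 1.0 + c + rng.normal(0.0, noise_sd, t.size)
        traces.append(Trace(t, y, stage="normalized", f0=100.0,
                            roi_id=f"r{i:03d}"))
    return traces, labels
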