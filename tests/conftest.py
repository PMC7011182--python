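import numpy as np
import pytest

from dgephys.core import StimulusProtocol, Trace
from dgephys.simulate import PSCShape, SynapseModel

RATE = 20000.0
DT = 1000.0 / RATE


@pytest.fixture
def rate():
    return RATE


@pytest.fixture
def single_pulse_protocol():
    return StimulusProtocol(onsets_ms=np.array([100.0]), width_ms=0.2)


@pytest.fixture
def train_protocol():
    """5-pulse 20 Hz laser train (50 ms inter-pulse interval)."""
    return StimulusProtocol(
        onsets_ms=50.0 + np.arange(5) * 50.0,
        width_ms=0.2,
        modality="laser",
        train_rate_hz=20.0,
    )


@pytest.fixture
def ipsc_shape():
    return PSCShape(amplitude_pa=50.0, tau_rise_ms=1.0, tau_decay_ms=10.0, polarity=-1)


@pytest.fixture
def reliable_synapse(ipsc_shape):
    return SynapseModel(
        shape=ipsc_shape, failure_prob=0.0, spont_rate_hz=0.0, noise_sd_pa=2.0
    )


def make_trace(samples, rate=RATE, kind="voltage_clamped_current", t0=0.0):
    return Trace(samples=np.asarray(samples, float), sampling_rate=rate, kind=kind, t0=t0)
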