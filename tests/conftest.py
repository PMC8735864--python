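import numpy as np
import pytest

from synint.trace_model import StimulusTrain, SweepSet, Waveform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_pulse_train():
    return StimulusTrain.regular(20.0, 1, start=20.0)


@pytest.fixture
def simple_sweepset():
    """3 sweeps x 1000 samples at dt 0.02 ms with a stimulus at 5 ms."""
    t = 0.02 * np.arange(1000)
    base = np.exp(-((t - 10.0) / 2.0) ** 2)
    sweeps = np.stack([base, base + 1.0, base - 1.0])
    stim = StimulusTrain(onsets=np.array([5.0]), width=2.0, kind="light")
    meta = tuple({"condition": "control", "intensity": 1.0} for _ in range(3))
    return SweepSet(sweeps, dt=0.02, units="mV", stimulus=stim,
                    per_sweep_meta=meta)


def gaussian_bump(sigma: float = 5.0, dt: float = 0.02, center: float = 50.0,
                  span: float = 100.0, amplitude: float = 1.0) -> Waveform:
    t = dt * np.arange(int(span / dt))
    return Waveform(amplitude * np.exp(-((t - center) ** 2) / (2 * sigma ** 2)),
                    dt=dt, units="mV")
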