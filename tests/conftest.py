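import numpy as np
import pytest

from ppg_hrv import pipeline
from ppg_hrv.preprocess import UniformSignal
from ppg_hrv.synthetic import PulseShape, SynthSpec, synth_recording


@pytest.fixture(scope="session")
def clean_recording():
    """120 s clean synthetic recording at the default study conditions."""
    spec = SynthSpec(duration_s=120.0, seed=0)
    raw, truth = synth_recording(spec)
    return spec, raw, truth


@pytest.fixture(scope="session")
def clean_result(clean_recording):
    """Best (channel, polarity) analysis of the clean recording."""
    _, raw, _ = clean_recording
    return pipeline.AnalysisResult(pipeline.analyze_channel(raw, "G")).best


@pytest.fixture(scope="session")
def corrupted_recording():
    """120 s recording whose middle third is replaced by white noise."""
    spec = SynthSpec(duration_s=120.0, seed=3,
                     corruption=[(40.0, 80.0, "white_noise")])
    raw, truth = synth_recording(spec)
    return spec, raw, truth


@pytest.fixture(scope="session")
def corrupted_result(corrupted_recording):
    _, raw, _ = corrupted_recording
    return pipeline.analyze_channel(raw, "G")[0]


def make_pulse_train(period_s: float, duration_s: float, f: float = 100.0,
                     shape: PulseShape | None = None) -> UniformSignal:
    """Noiseless periodic pulse train as an already-valid uniform signal."""
    shape = shape or PulseShape()
    t = np.arange(int(duration_s * f)) / f
    x = np.zeros(t.size)
    beat = 1.0
    while beat < duration_s - 0.5:
        near = np.abs(t - beat) < 1.5
        x[near] += shape(t[near] - beat)
        beat += period_s
    x -= x.mean()
    return UniformSignal(x, f, chunks=[(0, t.size)])


@pytest.fixture(scope="session")
def pulse_train():
    return make_pulse_train(period_s=0.8, duration_s=30.0)
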