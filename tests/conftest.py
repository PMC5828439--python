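import numpy as np
import pytest

from emgipa import EMGRecording


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def noise_recording(rng):
    """A 0.2 s white-noise trace at the study sampling rate."""
    return EMGRecording(
        subject_id="noise",
        samples=rng.normal(0.0, 80.0, size=2500),
        fs=12_500.0,
        label="unknown",
    )


def make_recording(samples, fs=12_500.0, label="unknown", subject_id="t"):
    return EMGRecording(subject_id=subject_id, samples=np.asarray(samples, float), fs=fs, label=label)
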