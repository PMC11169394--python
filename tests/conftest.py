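import numpy as np
import pytest

from epiquant import BaselineEstimate, DetectionConfig, EEGRecord


@pytest.fixture
def config():
    return DetectionConfig()


@pytest.fixture
def config_no_hp():
    """Default criteria without drift-removal filtering (noiseless fixtures)."""
    return DetectionConfig(highpass_cutoff=None)


@pytest.fixture
def baseline50():
    """A fixed 50 μV background amplitude for noiseless constructions."""
    return BaselineEstimate(amplitude=50.0, method="fixed")


def make_record(duration=60.0, fs=1000.0, n_channels=1, subject_id="t"):
    """All-zero record to plant transients on."""
    return EEGRecord(
        samples=np.zeros((n_channels, int(duration * fs))),
        fs=fs,
        channel_ids=tuple(f"EEG{i + 1}" for i in range(n_channels)),
        subject_id=subject_id,
    )


@pytest.fixture
def zero_record():
    return make_record()
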