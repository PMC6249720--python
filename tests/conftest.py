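import numpy as np
import pytest

from ctxseize.io_segmentation import EEGRecord, SeizureInterval
from ctxseize.synthetic_data import SynthConfig, generate_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_record():
    """20 s, 2-channel synthetic record with one 6 s seizure."""
    cfg = SynthConfig(
        fs=128.0, n_channels=2, duration_s=20.0,
        ictal_intervals=[(8.0, 14.0)], seed=7,
    )
    return generate_record(cfg, record_id="rec-small")


@pytest.fixture
def flat_record():
    """Deterministic ramp record useful for exact segmentation checks."""
    fs = 100.0
    signal = np.arange(0, 1000, dtype=float)[np.newaxis, :] / 1000
    return EEGRecord(signal, fs=fs, record_id="ramp",
                     annotations=[SeizureInterval(5.0, 8.0)])
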