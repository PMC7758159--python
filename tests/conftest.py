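import numpy as np
import pytest

from nervequant.io_timeseries import Annotation, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_recording():
    """8-sample two-channel recording at 4 kHz."""
    return Recording(
        channels={
            "nerve": np.array([0.0, 1.5, -2.0, 3.25, -1.0, 0.5, 2.0, -0.75]),
            "bp": np.array([100.0, 101.0, 99.5, 100.5, 100.0, 100.25, 99.75, 100.0]),
        },
        fs=4000.0,
        units={"nerve": "uV", "bp": "mmHg"},
    )


@pytest.fixture
def noise_recording(rng):
    """60 s of Gaussian noise (sd 2 uV) annotated as post-mortem."""
    fs = 4000.0
    sig = rng.normal(0.0, 2.0, int(60 * fs))
    return Recording(
        channels={"nerve": sig},
        fs=fs,
        annotations=[Annotation("postmortem", 0.0, 60.0)],
        units={"nerve": "uV"},
    )
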