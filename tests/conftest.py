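import numpy as np
import pytest

from capnet.segmentation import resample_record
from capnet.simulate import SimConfig, generate_record


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_record():
    """600 s synthetic record at 128 Hz, ~20% A seconds."""
    return generate_record(SimConfig(duration_s=600, a_fraction=0.2, seed=1))


@pytest.fixture(scope="session")
def short_record_32(short_record):
    return resample_record(short_record)
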