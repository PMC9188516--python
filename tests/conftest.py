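import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from thermomri.coefficients import load_coefficient_table
from thermomri.protocol import default_protocol
from thermomri import synth


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def table():
    return load_coefficient_table()


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free 16^3 phantom at the cohort's mean temperature."""
    subject = synth.SubjectSpec("phantom01", "post_mortem", 12.7, seed=7)
    label_vol, gt = synth.generate_phantom(
        shape=(16, 16, 16), subject=subject, cv=0.0, rng=np.random.default_rng(7))
    return subject, label_vol, gt


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
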