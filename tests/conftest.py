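import numpy as np
import pytest

from strideseg import CyclicityConfig, make_trial
from strideseg.synthgait import study_setup


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config25():
    """Default analysis configuration at the smartphone rate."""
    return CyclicityConfig(fsamp=25.0)


@pytest.fixture(scope="session")
def study():
    """Config + fiducial specs matched to the default synthetic trials."""
    return study_setup()


@pytest.fixture(scope="session")
def default_trial():
    """One default study trial, generated once per session."""
    return make_trial(seed=42)
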