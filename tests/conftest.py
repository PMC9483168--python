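import numpy as np
import pytest

from flimdr import AcquisitionConfig, ComponentPair, RunConfig


@pytest.fixture
def acq():
    return AcquisitionConfig(repetition_rate_mhz=80.0, n_time_bins=256)


@pytest.fixture
def components():
    return ComponentPair(tau_free=0.4, tau_bound=3.4)


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
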