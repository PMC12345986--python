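import pytest

from swinegrowth import LogisticParams, default_herd_spec, simulate_slaughter
from swinegrowth.simulate import with_noise_free


@pytest.fixture(scope="session")
def yp_params():
    """Published population parameters of the lean (Yorkshire-type) breed."""
    return LogisticParams(A=160.493, B=16.901, K=0.022)


@pytest.fixture(scope="session")
def qyp_params():
    """Published population parameters of the fat (Qingyu-type) breed."""
    return LogisticParams(A=137.948, B=20.059, K=0.016)


@pytest.fixture(scope="session")
def herd_spec():
    return default_herd_spec(seed=17)


@pytest.fixture(scope="session")
def noise_free_spec(herd_spec):
    return with_noise_free(herd_spec)


@pytest.fixture(scope="session")
def slaughter_tables(herd_spec):
    """(trait_table, truth) from the default slaughter design, one draw."""
    return simulate_slaughter(herd_spec)
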