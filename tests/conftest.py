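import numpy as np
import pytest

from rtkrecruit.params import best_fit_params
from rtkrecruit import synth
from rtkrecruit.cell_model import build_cell_model


@pytest.fixture(scope="session")
def reported_params():
    """Best-fit rate constants as reported (a2' = 52, balanced only to ~4%)."""
    return best_fit_params()


@pytest.fixture(scope="session")
def balanced_params():
    """Best-fit rate constants with a2' recomputed to close the cycle exactly."""
    return best_fit_params(balanced=True)


@pytest.fixture(scope="session")
def hela_fixture():
    return synth.hela_like_fixture()


@pytest.fixture(scope="session")
def hela_model(hela_fixture):
    profile, imap = hela_fixture
    return build_cell_model(profile, imap)


@pytest.fixture(scope="session")
def hela_steady(hela_model):
    return hela_model.steady_state(1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
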