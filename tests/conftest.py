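import numpy as np
import pytest

from crucell import control_params, initial_state, make_pacing, run


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale control parameter set used by most simulator tests."""
    return control_params(n_cru=64)


@pytest.fixture(scope="session")
def short_control_trace(small_params):
    """Two paced beats of the control cell, shared across tests."""
    return run(make_pacing([(2.0, 1.0)]), small_params, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
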