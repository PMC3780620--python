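import numpy as np
import pytest

from numerest import Hyperparameters, generate_session, make_design


@pytest.fixture
def hp_recentered():
    """Fitting-convention hyperparameters (recentered scale)."""
    return Hyperparameters(alpha=0.5, a0=4.0, b0=10.0, eta0=1.0, mu0=0.0,
                           lam=1.0, sigma_y=5.0, n_colors=3)


@pytest.fixture
def exp1_session():
    """One deterministic exp1 session (320 trials, responses missing)."""
    return generate_session(make_design("exp1"), "s00", np.random.default_rng(7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
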