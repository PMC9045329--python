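import numpy as np
import pytest

from methanomod import default_model, solve_steady_state
from methanomod.mca import methanol_grid
from methanomod.monod import fit_monod, growth_curve


@pytest.fixture(scope="session")
def model():
    """The packaged default network (100 mM methanol)."""
    return default_model()


@pytest.fixture(scope="session")
def ss100(model):
    """Converged steady state at 100 mM methanol."""
    ss = solve_steady_state(model, polish=True)
    assert ss.converged
    return ss


@pytest.fixture(scope="session")
def curve(model):
    """Steady-state growth curve, 1 uM to 1 M, 8 points per decade."""
    return growth_curve(model, methanol_grid(1e-6, 1.0, per_decade=8))


@pytest.fixture(scope="session")
def monod_fit(curve):
    return fit_monod(curve)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def profile_extremes(model):
    """Full control/response profile at a low and a high methanol point."""
    from methanomod.mca import control_profile
    return control_profile(model, grid=[1e-4, 2e-2])


@pytest.fixture(scope="session")
def profile_transition(model):
    """Control profile through the MTA/MCR handoff region."""
    from methanomod.mca import control_profile
    return control_profile(model, grid=[4e-4, 6e-4, 9e-4])
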