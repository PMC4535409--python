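import numpy as np
import pytest
from hypothesis import HealthCheck, settings as hyp_settings

from pihna import PihnaParameters, SolverSettings, TumourState

hyp_settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def coarse_settings() -> SolverSettings:
    """Cheap solver settings for unit tests (1 mm grid, 60 mm domain)."""
    return SolverSettings(dr=1.0, r_max=60.0)


@pytest.fixture(scope="session")
def coarse_grid(coarse_settings):
    return coarse_settings.make_grid()


@pytest.fixture(scope="session")
def aggressive_params() -> PihnaParameters:
    return PihnaParameters(D=305.0, rho=83.0)


@pytest.fixture(scope="session")
def moderate_params() -> PihnaParameters:
    """Mid-grid kinetics that develop a clear hypoxic band quickly."""
    return PihnaParameters(D=14.3, rho=26.0)


def make_state(grid, K=2.39e5, c=None, h=None, n=None, v=None, a=None, t=0.0):
    """Hand-built state with zero defaults (helper, not a fixture)."""
    z = np.zeros_like(grid.r)

    def arr(x):
        if x is None:
            return z.copy()
        if np.isscalar(x):
            return np.full_like(grid.r, float(x))
        return np.asarray(x, dtype=float)

    return TumourState(t=t, c=arr(c), h=arr(h), n=arr(n), v=arr(v), a=arr(a))


@pytest.fixture(scope="session")
def grown_hypoxic(moderate_params, coarse_settings, coarse_grid):
    """A tumour grown to 1.5 cm T2 radius carrying a real hypoxic burden."""
    from pihna import run_until_t2_radius

    state, t1 = run_until_t2_radius(moderate_params, coarse_grid,
                                    coarse_settings, target_radius=1.5)
    assert state.h.max() > 0
    return state, t1
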