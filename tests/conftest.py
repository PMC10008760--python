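import numpy as np
import pytest

from pumba import make_default_schedule, make_synthetic_aif


@pytest.fixture(scope="session")
def aif():
    return make_synthetic_aif()


@pytest.fixture(scope="session")
def schedule():
    return make_default_schedule()


def numerical_convolution(irf_func, times, conc, t_eval, dt=0.005):
    """Brute-force trapezoidal convolution oracle on a fine uniform grid,
    independent of the analytic per-segment formulas under test."""
    grid = np.arange(0.0, float(np.max(t_eval)) + dt, dt)
    cp = np.interp(grid, times, conc)
    irf = irf_func(grid)
    full = np.convolve(irf, cp)[: len(grid)] * dt
    # trapezoid endpoint correction; cp[0] is zero by construction
    full -= 0.5 * dt * (irf[0] * cp + irf * cp[0])
    return np.interp(t_eval, grid, full)


def curve_rel_err(analytic, oracle):
    """Relative error normalised by the oracle curve's peak."""
    return np.max(np.abs(analytic - oracle)) / np.max(np.abs(oracle))
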