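import numpy as np
import pytest

from pulseswitch.types import KineticParams, LuminescenceTrace, SwitchProfile


@pytest.fixture
def default_params() -> KineticParams:
    return KineticParams(delta_m=0.6, delta_p=0.35, alpha=5.0, kappa=1.0,
                         sigma=10.0)


@pytest.fixture
def three_switch_profile() -> SwitchProfile:
    """One all-or-nothing up-switch followed by two graded down-switches."""
    return SwitchProfile((14.0, 20.0, 26.0), (3.0, 48.0, 12.0, 2.4), (0.0, 48.0))


@pytest.fixture
def grid_48h() -> np.ndarray:
    return np.arange(0.0, 48.01, 0.25)


@pytest.fixture
def deterministic_mean_trace():
    """Factory: trace from the macroscopic mean path plus Gaussian noise.

    Model-matched data without intrinsic molecular noise: handy when a test
    needs the latent path to be exactly the LNA mean.
    """
    return _deterministic_mean_trace


def _deterministic_mean_trace(profile, params, grid, sigma, seed, cell_id="det"):
    from scipy.integrate import odeint

    dm, dp, al = params.delta_m, params.delta_p, params.alpha

    def rhs(y, t):
        return [profile.rate_at(t) - dm * y[0], al * y[0] - dp * y[1]]

    y0 = [profile.rates[0] / dm, al * profile.rates[0] / (dm * dp)]
    path = odeint(rhs, y0, grid, hmax=0.05)
    rng = np.random.default_rng(seed)
    values = params.kappa * path[:, 1] + rng.normal(0.0, sigma, len(grid))
    return LuminescenceTrace(cell_id, grid, values)
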