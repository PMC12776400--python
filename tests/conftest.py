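import numpy as np
import pytest

from wellmix import (
    WellGeometry,
    build_grid,
    calibrate,
    run_scenarios,
)


@pytest.fixture(scope="session")
def geometry():
    return WellGeometry()


@pytest.fixture(scope="session")
def grid(geometry):
    return build_grid(geometry)


@pytest.fixture(scope="session")
def constants():
    """Two-anchor calibrated constants, shared across the session."""
    return calibrate()


@pytest.fixture(scope="session")
def scenario_trajectories(constants):
    """The four named 12-cycle scenario runs on the default grid."""
    return run_scenarios(constants)


def euler_evolve(K: np.ndarray, c: np.ndarray, tau: float, n_steps: int) -> np.ndarray:
    """Independent forward-Euler integration of dc/dtau = K c."""
    h = tau / n_steps
    c = c.astype(float).copy()
    for _ in range(n_steps):
        c = c + h * (K @ c)
    return c
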