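"""Shared fixtures: grids, detector arrays and cached model matrices."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ringpam as rp
from ringpam.reconstruct import build_model_matrices

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CS = 1.5  # mm/µs


@pytest.fixture(scope="session")
def grid() -> rp.TimeGrid:
    """Default sampling: 100 MHz, window 4–33 µs (covers depths 12–40 mm)."""
    return rp.TimeGrid(4.0, 0.01, 2900)


@pytest.fixture(scope="session")
def z_grid() -> np.ndarray:
    return np.arange(12.0, 40.0 + 1e-9, 0.05)


@pytest.fixture(scope="session")
def meas_array() -> rp.DetectorArray:
    """Fabricated array subset used in measurements (flat + 3 outer rings)."""
    return rp.measurement_array()


@pytest.fixture(scope="session")
def meas_matrices(meas_array, z_grid, grid):
    return build_model_matrices(meas_array, z_grid, grid, CS)


@pytest.fixture(scope="session")
def microsphere_rf_25(meas_array, grid):
    """Noise-free single-position acquisition of a microsphere at 25 mm."""
    return rp.simulate_bscan(meas_array, rp.microsphere(25.0), [0.0], CS, grid)
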