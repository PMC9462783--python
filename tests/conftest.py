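"""Shared fixtures: a small optical system and synthetic acquisitions.

All fixtures are deterministic; session scope keeps the forward
simulations (the expensive part) shared across test modules.
"""

import numpy as np
import pytest

import stripesim as ss

SMALL = 128
MEDIUM = 256


@pytest.fixture(scope="session")
def system_small():
    return ss.OpticalSystem(na=1.4, wavelength_nm=520.0, pixel_nm=45.0, shape=(SMALL, SMALL))


@pytest.fixture(scope="session")
def system_medium():
    return ss.OpticalSystem(na=1.4, wavelength_nm=520.0, pixel_nm=45.0, shape=(MEDIUM, MEDIUM))


@pytest.fixture(scope="session")
def otf_small(system_small):
    return ss.analytic_otf(system_small)


@pytest.fixture(scope="session")
def otf_medium(system_medium):
    return ss.analytic_otf(system_medium)


@pytest.fixture(scope="session")
def model_small(system_small):
    return ss.default_illumination(system_small)


@pytest.fixture(scope="session")
def model_medium(system_medium):
    return ss.default_illumination(system_medium)


@pytest.fixture(scope="session")
def filament_truth_medium():
    return ss.make_ground_truth("filaments", (MEDIUM, MEDIUM), seed=2)


@pytest.fixture(scope="session")
def noiseless_stack_medium(filament_truth_medium, system_medium, model_medium):
    return ss.simulate_stack(
        filament_truth_medium, system_medium, model_medium, noise=None, seed=2
    )


@pytest.fixture(scope="session")
def bead_truth_small():
    return ss.make_ground_truth("beads", (SMALL, SMALL), seed=1, n=12, min_sep=20)


@pytest.fixture(scope="session")
def bead_stack_small(bead_truth_small, system_small, model_small):
    return ss.simulate_stack(bead_truth_small, system_small, model_small, noise=None, seed=1)


def true_estimate(model) -> ss.IlluminationEstimate:
    """Wrap a simulator illumination model as an exact parameter estimate."""
    return ss.IlluminationEstimate(
        k_theta=model.k_theta,
        phases_rad=model.phases_rad,
        peak_positions=np.zeros((9, 2), dtype=int),
        m=model.m,
    )


def canonical_k_and_phases(k_est, phases_est, k_true):
    """Resolve the +/- band sign ambiguity before comparing to ground truth."""
    k = np.array(k_est, dtype=float)
    ph = np.array(phases_est, dtype=float)
    if np.dot(k, k_true) < 0:
        k, ph = -k, -ph
    return k, ph


def wrapped_angle_diff_deg(a_deg, b_deg, period=360.0):
    d = (np.asarray(a_deg) - np.asarray(b_deg) + period / 2) % period - period / 2
    return np.abs(d)
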