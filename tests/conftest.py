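"""Shared fixtures: small synthetic PSFs and spline models.

Session-scoped because spline construction and the phase-model bank are
the expensive parts of the suite; all tests treat them as read-only.
"""

import numpy as np
import pytest

from fourpi_smlm.config import OpticalConfig
from fourpi_smlm.phase_dynamics import build_phase_models, decompose_psf
from fourpi_smlm.psf_spline import compute_spline_coefficients
from fourpi_smlm.simulator import make_symmetric_4pi_psf


@pytest.fixture(scope="session")
def cfg():
    return OpticalConfig()


@pytest.fixture(scope="session")
def small_stack(cfg):
    """Noiseless scalar 4Pi PSF over ±500 nm (101 planes, 10 nm)."""
    return make_symmetric_4pi_psf(cfg, n_xy=17, n_z=101, dz=10.0)


@pytest.fixture(scope="session")
def small_psf(small_stack):
    return compute_spline_coefficients(small_stack)


@pytest.fixture(scope="session")
def small_dec(small_stack):
    return decompose_psf(small_stack)


@pytest.fixture(scope="session")
def wide_stack(cfg):
    """PSF over ±1100 nm for off-focus fitting and artifact statistics."""
    return make_symmetric_4pi_psf(cfg, n_xy=17, n_z=221, dz=10.0)


@pytest.fixture(scope="session")
def wide_psf(wide_stack):
    return compute_spline_coefficients(wide_stack)


@pytest.fixture(scope="session")
def phase_models(small_psf):
    """Bank of 12 phase-shifted models of the small PSF."""
    return build_phase_models(small_psf, 12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
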