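"""Shared fixtures: filters and stacks are expensive, so they are built once
per session.  All synthetic inputs are generated here at run time."""

from __future__ import annotations

import numpy as np
import pytest

from nlmscope import gmr, imaging, rcwa
from nlmscope.transfer import TransferFunction


@pytest.fixture(scope="session")
def published_params():
    return gmr.published_resonance()  # lambda0 630, Q 60, p 390, t_min 0.17


@pytest.fixture(scope="session")
def cmt_tf_band(published_params):
    """CMT filter over 620-640 nm and +-89 deg (covers NA up to ~1)."""
    angles = np.linspace(-89.0, 89.0, 6001)
    wavelengths = np.linspace(620.0, 640.0, 81)
    return gmr.sample_transfer_function(published_params, None, wavelengths, angles)


@pytest.fixture(scope="session")
def cfg_band():
    """The published illumination: 6-nm-FWHM source, NA 0.45."""
    return imaging.ImagingConfig(
        center_wavelength_nm=630.0, spectral_fwhm_nm=6.0, n_spectral_samples=7, na=0.45
    )


@pytest.fixture(scope="session")
def cfg_mono():
    return imaging.ImagingConfig(
        center_wavelength_nm=630.0, spectral_fwhm_nm=0.0, n_spectral_samples=1, na=0.45
    )


@pytest.fixture(scope="session")
def calibrated_stack():
    """Device stack with the nitride index calibrated to put the dip at 630 nm."""
    return rcwa.calibrate_stack(630.0)


@pytest.fixture(scope="session")
def dip_wavelength(calibrated_stack):
    lam, _ = rcwa.find_dip_center(calibrated_stack)
    return lam


def _half_angle_grid():
    return np.concatenate([np.arange(0.0, 5.0, 0.02), np.arange(5.0, 28.6, 0.25)])


@pytest.fixture(scope="session")
def rcwa_tf_band(calibrated_stack):
    """RCWA transfer function over 620-640 nm x +-28.5 deg (mirrored halves).

    This is the expensive fixture (~15k solves); n_orders 14 is converged to
    1e-5 for this stack (checked in the convergence test).
    """
    half = _half_angle_grid()
    wavelengths = np.arange(620.0, 640.0 + 1e-9, 0.5)
    tf_half, _ = rcwa.scan_map(calibrated_stack, wavelengths, half, n_orders=14)
    t_full = np.concatenate([tf_half.t[:, :0:-1], tf_half.t], axis=1)
    angles = np.concatenate([-half[:0:-1], half])
    return TransferFunction(wavelengths, angles, t_full, meta={"model": "rcwa"})


@pytest.fixture(scope="session")
def pillar_calibration(cmt_tf_band, cfg_band):
    """Closed-loop calibration on uniform-step pillar layouts through the
    on-resonance coupled-mode filter with the 6-nm source."""
    from nlmscope import phantoms, retrieval  # local import keeps fixtures lazy

    def closure(phi):
        obj, labels = phantoms.make_pillar_phantom(phases_rad=[phi] * 10)
        return imaging.form_image(obj, cmt_tf_band, cfg_band), labels, None

    steps = np.linspace(0.02 * np.pi, 0.5 * np.pi, 10)
    return retrieval.build_calibration(steps, closure)


@pytest.fixture(scope="session")
def flat_tf_band(rcwa_tf_band):
    """Ideal bright-field reference on the same grids."""
    return TransferFunction(
        rcwa_tf_band.wavelengths_nm,
        rcwa_tf_band.angles_deg,
        np.ones_like(rcwa_tf_band.t),
    )
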