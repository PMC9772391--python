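"""Fourier-optics image formation through an angular filter.

A complex specimen transmission p(x,y) is propagated through the filter and an
NA-limited pupil directly in the Fourier domain (the 4f relay is abstracted:
no focal length enters the computation).  For each spectral sample the object
spectrum is multiplied by the filter response H(fx) along one image axis only
— the guided-mode-resonance filter is anisotropic, acting on the spatial
frequency fx = sin(theta)/lambda conjugate to the direction across the grating
grooves — and by an isotropic circular pupil of numerical aperture NA.  The
camera records the incoherent (weighted) sum of the squared magnitudes over
the spectral samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .gmr import ResonanceParams, sample_transfer_function
from .transfer import TransferFunction

__all__ = [
    "PhaseObject",
    "ImagingConfig",
    "IntensityImage",
    "form_image",
    "detuned_image_pair",
    "zernike_reference_image",
    "ripple_period",
]


# ------------------------------------------------------------------- objects
@dataclass
class PhaseObject:
    """2D specimen: phase map (radians), optional amplitude, pixel pitch (um).

    The complex transmission is ``amplitude * exp(i*phase)``; pure phase
    objects (amplitude 1 everywhere) neither absorb nor scatter amplitude.
    """

    phase: np.ndarray
    pitch_um: float
    amplitude: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2:
            raise ValueError("phase must be a 2D map")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase must be finite")
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")
        if self.amplitude is not None:
            self.amplitude = np.asarray(self.amplitude, dtype=float)
            if self.amplitude.shape != self.phase.shape:
                raise ValueError("amplitude and phase shapes differ")
            if np.any(self.amplitude < 0):
                raise ValueError("amplitude must be nonnegative")

    @property
    def transmission(self) -> np.ndarray:
        p = np.exp(1j * self.phase)
        return p if self.amplitude is None else self.amplitude * p


@dataclass
class ImagingConfig:
    """Illumination, pupil and sampling choices for image formation.

    center_wavelength_nm : illumination wavelength (nm).
    spectral_fwhm_nm : source bandwidth, FWHM of a Gaussian profile
        (0 = monochromatic; the published source has 6 nm).
    n_spectral_samples : quadrature points across +-1.5 FWHM.
    na : numerical aperture of the collection pupil (0 < na <= 1).
    filter_axis : image axis (0 or 1) along which the 1D filter acts.
    pad_factor : zero-padding multiple suppressing FFT wrap-around.
    apodization : 'cosine' tapers the object's deviation from background
        across the pad margin; 'none' disables it (periodic objects).
    """

    center_wavelength_nm: float = 630.0
    spectral_fwhm_nm: float = 0.0
    n_spectral_samples: int = 7
    na: float = 0.45
    filter_axis: int = 1
    pad_factor: int = 2
    apodization: str = "cosine"

    def __post_init__(self) -> None:
        if not (0.0 < self.na <= 1.0):
            raise ValueError("na must be in (0, 1]")
        if self.spectral_fwhm_nm < 0:
            raise ValueError("spectral_fwhm_nm must be >= 0")
        if self.n_spectral_samples < 1:
            raise ValueError("n_spectral_samples must be >= 1")
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")
        if self.apodization not in ("cosine", "none"):
            raise ValueError("apodization must be 'cosine' or 'none'")
        if self.filter_axis not in (0, 1):
            raise ValueError("filter_axis must be 0 or 1")

    def spectral_samples(self) -> list[tuple[float, float]]:
        """(wavelength, weight) quadrature of the Gaussian source profile."""
        if self.spectral_fwhm_nm == 0.0 or self.n_spectral_samples == 1:
            return [(self.center_wavelength_nm, 1.0)]
        half = 1.5 * self.spectral_fwhm_nm
        lam = np.linspace(-half, half, self.n_spectral_samples)
        w = np.exp(-4.0 * np.log(2.0) * (lam / self.spectral_fwhm_nm) ** 2)
        w /= w.sum()
        return list(zip((self.center_wavelength_nm + lam).tolist(), w.tolist()))


@dataclass
class IntensityImage:
    """Simulated camera image: nonnegative intensity with physical pitch."""

    intensity: np.ndarray
    pitch_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2D")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if np.any(self.intensity < -1e-12):
            raise ValueError("intensity must be nonnegative")
        np.clip(self.intensity, 0.0, None, out=self.intensity)

    def with_poisson_noise(self, photons_per_unit: float, seed: int) -> "IntensityImage":
        """Shot-noise realization: Poisson with mean photons_per_unit*I, rescaled."""
        rng = np.random.default_rng(seed)
        counts = rng.poisson(self.intensity * photons_per_unit)
        return IntensityImage(
            counts / photons_per_unit, self.pitch_um, {**self.meta, "poisson_seed": seed}
        )


# ------------------------------------------------------------------ pipeline
def _apodization_window(n_pad: int, n_orig: int, kind: str) -> np.ndarray:
    """1D window: flat over the original field, cosine decay across half the
    pad margin, zero outside.  Applied to the deviation from background."""
    w = np.zeros(n_pad)
    lo = (n_pad - n_orig) // 2
    w[lo : lo + n_orig] = 1.0
    if kind == "cosine":
        ramp = max((n_pad - n_orig) // 4, 1)
        edge = 0.5 * (1.0 + np.cos(np.linspace(0.0, np.pi, ramp)))
        if lo >= ramp:
            w[lo - ramp : lo] = edge[::-1]
            w[lo + n_orig : lo + n_orig + ramp] = edge
    return w


def _embed(obj: PhaseObject, cfg: ImagingConfig) -> tuple[np.ndarray, tuple]:
    """Pad the complex transmission into a background of 1, apodizing the
    deviation so FFT periodicity does not create wrap-around artifacts."""
    p = obj.transmission
    ny, nx = p.shape
    npy, npx = cfg.pad_factor * ny, cfg.pad_factor * nx
    dev = np.zeros((npy, npx), dtype=complex)
    oy, ox = (npy - ny) // 2, (npx - nx) // 2
    dev[oy : oy + ny, ox : ox + nx] = p - 1.0
    if cfg.apodization != "none" and cfg.pad_factor > 1:
        wy = _apodization_window(npy, ny, cfg.apodization)
        wx = _apodization_window(npx, nx, cfg.apodization)
        dev *= np.outer(wy, wx)
    return 1.0 + dev, (oy, ox, ny, nx)


def _filtered_intensity(
    field_ft: np.ndarray,
    H_line: np.ndarray,
    pupil: np.ndarray,
    filter_axis: int,
) -> np.ndarray:
    shape = [1, 1]
    shape[filter_axis] = H_line.size
    out = field_ft * H_line.reshape(shape) * pupil
    img = np.fft.ifft2(out)
    return np.abs(img) ** 2


def form_image(obj: PhaseObject, tf: TransferFunction, cfg: ImagingConfig) -> IntensityImage:
    """Image the object through the angular filter and the NA-limited pupil.

    For each spectral sample: FFT the padded complex transmission, multiply by
    the filter response interpolated at fx = sin(theta)/lambda along
    ``cfg.filter_axis``, by the circular pupil indicator
    fx^2 + fy^2 <= (na/lambda)^2, inverse FFT, square.  Samples add
    incoherently with Gaussian weights.  A flat filter (H = 1) reduces to
    ideal bright field.
    """
    samples = cfg.spectral_samples()
    lam_min_um = min(s[0] for s in samples) * 1e-3
    nyquist = lam_min_um / (4.0 * cfg.na)
    if obj.pitch_um > nyquist * (1 + 1e-12):
        raise ValueError(
            f"object pitch {obj.pitch_um} um too coarse: need <= lambda/(4*NA) "
            f"= {nyquist:.4f} um to sample the coherent cutoff"
        )

    padded, (oy, ox, ny, nx) = _embed(obj, cfg)
    field_ft = np.fft.fft2(padded)
    f_axis0 = np.fft.fftfreq(padded.shape[0], d=obj.pitch_um)
    f_axis1 = np.fft.fftfreq(padded.shape[1], d=obj.pitch_um)
    f2 = f_axis0[:, None] ** 2 + f_axis1[None, :] ** 2
    fx_filter = f_axis1 if cfg.filter_axis == 1 else f_axis0

    total = np.zeros((ny, nx))
    for lam_nm, weight in samples:
        lam_um = lam_nm * 1e-3
        f_cut = cfg.na / lam_um
        cover = np.sin(np.deg2rad(np.abs(tf.angles_deg).max())) / lam_um
        if cover < f_cut * (1 - 1e-3):
            raise ValueError(
                f"filter band covers |fx| <= {cover:.4f} cycles/um at {lam_nm} nm "
                f"but the NA {cfg.na} pupil requires |fx| <= {f_cut:.4f} cycles/um"
            )
        H_line = tf.sample_on_fx(lam_nm, fx_filter, fill=0.0)
        pupil = (f2 <= f_cut**2).astype(float)
        inten = _filtered_intensity(field_ft, H_line, pupil, cfg.filter_axis)
        total += weight * inten[oy : oy + ny, ox : ox + nx]

    return IntensityImage(
        total,
        obj.pitch_um,
        meta={
            "wavelengths_nm": [s[0] for s in samples],
            "na": cfg.na,
            "filter": tf.meta.get("model", "custom"),
        },
    )


def _as_tf(source, wavelengths_nm, max_angle_deg=89.0, n_angles=6001) -> TransferFunction:
    if isinstance(source, TransferFunction):
        return source
    if isinstance(source, ResonanceParams):
        angles = np.linspace(-max_angle_deg, max_angle_deg, n_angles)
        wavelengths = np.unique(np.asarray(wavelengths_nm, dtype=float))
        return sample_transfer_function(source, None, wavelengths, angles)
    raise TypeError("filter source must be a TransferFunction or ResonanceParams")


def detuned_image_pair(
    obj: PhaseObject,
    source,
    cfg: ImagingConfig,
    detuning_nm: float = 3.0,
    center_wavelength_nm: float | None = None,
):
    """Images below and above resonance (lambda0 -+ detuning).

    For a weak phase step the sign of (feature - background) flips between the
    two: tuning across the resonance reverses the relative phase of the
    paraxial background, switching positive to negative phase contrast.

    ``source`` is a TransferFunction covering both wavelengths or a CMT
    :class:`ResonanceParams` (sampled on demand).
    """
    if center_wavelength_nm is None:
        center_wavelength_nm = (
            source.lambda0_nm
            if isinstance(source, ResonanceParams)
            else cfg.center_wavelength_nm
        )
    lams = [center_wavelength_nm - detuning_nm, center_wavelength_nm + detuning_nm]
    tf = _as_tf(source, lams)
    images = []
    for lam in lams:
        cfg_k = ImagingConfig(
            center_wavelength_nm=lam,
            spectral_fwhm_nm=cfg.spectral_fwhm_nm,
            n_spectral_samples=cfg.n_spectral_samples,
            na=cfg.na,
            filter_axis=cfg.filter_axis,
            pad_factor=cfg.pad_factor,
            apodization=cfg.apodization,
        )
        images.append(form_image(obj, tf, cfg_k))
    return images[0], images[1]


def zernike_reference_image(
    obj: PhaseObject,
    annulus: dict,
    cfg: ImagingConfig,
) -> IntensityImage:
    """Idealized Zernike phase-contrast reference: an isotropic annular
    Fourier filter (radii in cycles/um) that attenuates and phase-shifts the
    background ring.  Wide annuli reproduce the classic halo and shade-off
    artifacts of non-ideal spatial filtering.

    annulus keys: inner, outer (cycles/um), attenuation (amplitude factor,
    default 1), phase_shift (radians, default pi/2).
    """
    inner = float(annulus["inner"])
    outer = float(annulus["outer"])
    att = float(annulus.get("attenuation", 1.0))
    shift = float(annulus.get("phase_shift", np.pi / 2))
    if inner >= outer:
        raise ValueError("annulus inner radius must be < outer radius")
    lam_um = cfg.center_wavelength_nm * 1e-3
    if outer > cfg.na / lam_um * (1 + 1e-9):
        raise ValueError("annulus extends beyond the pupil")

    padded, (oy, ox, ny, nx) = _embed(obj, cfg)
    field_ft = np.fft.fft2(padded)
    f0 = np.fft.fftfreq(padded.shape[0], d=obj.pitch_um)
    f1 = np.fft.fftfreq(padded.shape[1], d=obj.pitch_um)
    fr = np.sqrt(f0[:, None] ** 2 + f1[None, :] ** 2)
    ring = (fr >= inner) & (fr <= outer)
    H = np.where(ring, att * np.exp(1j * shift), 1.0)
    pupil = (fr <= cfg.na / lam_um).astype(float)
    img = np.fft.ifft2(field_ft * H * pupil)
    inten = np.abs(img) ** 2
    return IntensityImage(
        inten[oy : oy + ny, ox : ox + nx],
        obj.pitch_um,
        meta={"filter": "zernike_annulus", **annulus},
    )


# ------------------------------------------------------------------ analysis
def ripple_period(
    profile: np.ndarray,
    pitch_um: float,
    min_prominence_frac: float = 0.02,
) -> float:
    """Mean peak-to-peak spacing (um) of the ripple train in a 1D intensity
    profile (already windowed to the ripple region).

    Peaks are located with a prominence threshold relative to the profile's
    dynamic range; at least two peaks are required.
    """
    y = np.asarray(profile, dtype=float)
    prom = min_prominence_frac * (y.max() - y.min())
    peaks, _ = find_peaks(y, prominence=prom)
    if peaks.size < 2:
        raise ValueError("fewer than two ripple maxima found in the window")
    return float(np.mean(np.diff(peaks)) * pitch_um)
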