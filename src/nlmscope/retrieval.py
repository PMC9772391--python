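"""Weak-phase-object theory, contrast metrics, calibration and quantitative
phase retrieval.

A weak phase object p = exp(i*phi) ~ 1 + i*phi scatters a small field in
quadrature with the strong background.  The resonant angular filter
attenuates the background to a residual b (itself in quadrature) while the
diffracted sidebands pass with t1 ~ 1, so the camera intensity becomes a
monotone function of phi.  That monotone relation is measured once on
features of known phase (the calibration curve) and inverted pixel-by-pixel
to turn a single filtered image into a quantitative phase map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import binary_erosion

from .imaging import IntensityImage

__all__ = [
    "weak_phase_expand",
    "michelson_contrast",
    "weak_object_intensity",
    "CalibrationCurve",
    "CalibrationFamily",
    "build_calibration",
    "build_calibration_family",
    "region_signals",
    "PhaseEstimate",
    "retrieve_phase_map",
]


# --------------------------------------------------------------- weak theory
def weak_phase_expand(phi):
    """First-order field 1 + i*phi and the truncation bound max(phi^2)/2.

    The bound |exp(i*phi) - (1 + i*phi)| <= phi^2/2 follows from the Taylor
    remainder; a bound approaching 1 signals that the object is far outside
    the weak regime.
    """
    phi = np.asarray(phi, dtype=float)
    bound = float(np.max(phi**2) / 2.0) if phi.size else 0.0
    return 1.0 + 1j * phi, bound


def michelson_contrast(intensity) -> float:
    """Michelson contrast C = (Imax - Imin)/(Imax + Imin) of an image region."""
    inten = np.asarray(intensity, dtype=float)
    if inten.size == 0:
        raise ValueError("empty region")
    imax, imin = float(inten.max()), float(inten.min())
    if imax + imin == 0.0:
        raise ValueError("all-zero region: contrast undefined")
    return (imax - imin) / (imax + imin)


def weak_object_intensity(phi_step: float, b: complex, t1: complex = 1.0) -> float:
    """First-order feature/background intensity ratio for a uniform phase step.

    The background transmits with amplitude b = H(0); the object's sideband
    field i*phi*t1 adds to it, so the ratio is |b + i*t1*phi|^2 / |b|^2.
    Maximum first-order contrast occurs when the background and the (i-phase)
    sidebands end up collinear, which the resonance's pi/2 shift arranges.
    """
    b = complex(b)
    if b == 0:
        raise ValueError("b = 0: dark-field regime, contrast diverges")
    _, bound = weak_phase_expand(phi_step)
    ratio = abs(b + 1j * complex(t1) * phi_step) ** 2 / abs(b) ** 2
    return float(ratio)


# -------------------------------------------------------------- calibration
@dataclass
class CalibrationCurve:
    """Monotone mapping between known phase steps and measured image signal.

    Interpolation is monotone piecewise-cubic (PCHIP) in both directions;
    extrapolation is forbidden, so retrieved phases always lie inside
    ``valid_range``.
    """

    phase_steps: np.ndarray
    signals: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        phi = np.asarray(self.phase_steps, dtype=float)
        sig = np.asarray(self.signals, dtype=float)
        if phi.ndim != 1 or phi.size != sig.size:
            raise ValueError("phase_steps and signals must be 1D of equal length")
        if phi.size < 3:
            raise ValueError("need at least 3 calibration steps")
        order = np.argsort(phi)
        phi, sig = phi[order], sig[order]
        if np.any(np.diff(phi) <= 0):
            raise ValueError("duplicate phase steps: degenerate calibration knots")
        dsig = np.diff(sig)
        if np.all(dsig > 0):
            self._sign = 1.0
        elif np.all(dsig < 0):
            self._sign = -1.0
        else:
            k = int(np.argmin(dsig * np.sign(dsig.sum() or 1)))
            raise ValueError(
                "calibration signal is not strictly monotone in phase "
                f"(offending interval [{phi[k]:.4f}, {phi[k + 1]:.4f}] rad)"
            )
        self.phase_steps, self.signals = phi, sig
        self._fwd = PchipInterpolator(phi, sig, extrapolate=False)
        self._inv = PchipInterpolator(
            sig[:: int(self._sign)], phi[:: int(self._sign)], extrapolate=False
        )

    @property
    def valid_range(self) -> tuple[float, float]:
        return float(self.phase_steps[0]), float(self.phase_steps[-1])

    def signal_of(self, phase):
        return self._fwd(phase)

    def phase_of(self, signal):
        """Inverse mapping; NaN outside the calibrated signal range."""
        return self._inv(signal)

    # ---------------------------------------------------------------- io
    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"phase_rad": self.phase_steps, "signal": self.signals}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CalibrationCurve":
        df = pd.read_csv(path)
        return cls(df["phase_rad"].to_numpy(), df["signal"].to_numpy(), **kwargs)


@dataclass
class CalibrationFamily:
    """Size-resolved calibration: one monotone curve per reference feature
    diameter.

    The interior signal of a uniform feature behind a spatial-frequency notch
    depends not only on its phase but also on its size — features comparable
    to the inverse notch width lose part of their own low-frequency content
    (shade-off).  A family of curves built on uniform-step disks of several
    diameters removes that geometric bias: each measured region is inverted
    with the curve pair bracketing its equivalent diameter, interpolating
    linearly in diameter.
    """

    diameters_um: np.ndarray
    curves: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.diameters_um = np.asarray(self.diameters_um, dtype=float)
        if self.diameters_um.size != len(self.curves):
            raise ValueError("one curve per diameter required")
        if np.any(np.diff(self.diameters_um) <= 0):
            raise ValueError("diameters must be strictly increasing")

    @property
    def valid_range(self) -> tuple[float, float]:
        lo = max(c.valid_range[0] for c in self.curves)
        hi = min(c.valid_range[1] for c in self.curves)
        return lo, hi

    def curve_for(self, diameter_um: float):
        """Bracketing curves and interpolation weight for a diameter
        (clamped to the covered range)."""
        d = float(np.clip(diameter_um, self.diameters_um[0], self.diameters_um[-1]))
        j = int(np.searchsorted(self.diameters_um, d))
        j = min(max(j, 1), self.diameters_um.size - 1)
        d0, d1 = self.diameters_um[j - 1], self.diameters_um[j]
        w = (d - d0) / (d1 - d0)
        return self.curves[j - 1], self.curves[j], w

    def phase_of(self, signal, diameter_um: float):
        lo, hi, w = self.curve_for(diameter_um)
        return (1.0 - w) * lo.phase_of(signal) + w * hi.phase_of(signal)


def region_signals(
    img: IntensityImage,
    labels: np.ndarray,
    background_mask: np.ndarray | None = None,
    erode_px: int = 2,
    aggregate: str = "mean",
) -> dict[int, float]:
    """Background-normalized signal per labeled region.

    Region interiors are eroded by ``erode_px`` pixels before averaging so
    edge ripples do not bias the statistics; ``aggregate`` selects mean or
    median.  The background level is the aggregate over ``background_mask``
    (default: the eroded zero-label region).
    """
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    agg = np.mean if aggregate == "mean" else np.median
    inten = img.intensity
    if background_mask is None:
        background_mask = labels == 0
    background_mask = binary_erosion(background_mask, iterations=max(erode_px, 1))
    bg = float(agg(inten[background_mask]))
    if bg == 0.0:
        raise ValueError("background level is zero: cannot normalize")
    out: dict[int, float] = {}
    for k in np.unique(labels):
        if k == 0:
            continue
        mask = labels == k
        if erode_px > 0:
            mask = binary_erosion(mask, iterations=erode_px)
        if not mask.any():
            raise ValueError(f"region {k} vanished after erosion")
        out[int(k)] = float(agg(inten[mask])) / bg
    return out


def build_calibration(
    step_phases,
    image_for_step,
    estimator: str = "normalized",
    erode_px: int = 2,
    aggregate: str = "mean",
    meta: dict | None = None,
) -> CalibrationCurve:
    """Build a calibration curve from simulated (or measured) step images.

    Parameters
    ----------
    step_phases : known phases (radians) of the calibration features;
        at least 3, spanning the target working range.
    image_for_step : closure ``phi -> (IntensityImage, labels, background_mask)``
        running the full imaging pipeline at fixed configuration on a
        uniform-step phantom of phase ``phi`` (``background_mask`` may be
        None to use the zero-label region).
    estimator : 'normalized' (background-normalized feature intensity,
        robust for large uniform regions) or 'michelson' (contrast of the
        full image, extremum-sensitive).

    Raises if the resulting signal is not strictly monotone in phase.
    """
    phis = np.asarray(sorted(float(p) for p in step_phases))
    if phis.size < 3:
        raise ValueError("need at least 3 calibration steps")
    signals = []
    for phi in phis:
        img, labels, bg_mask = image_for_step(phi)
        if estimator == "normalized":
            sig = region_signals(img, labels, bg_mask, erode_px, aggregate)
            signals.append(float(np.mean(list(sig.values()))))
        elif estimator == "michelson":
            signals.append(michelson_contrast(img.intensity))
        else:
            raise ValueError("estimator must be 'normalized' or 'michelson'")
    return CalibrationCurve(
        phis,
        np.asarray(signals),
        meta={"estimator": estimator, "erode_px": erode_px,
              "aggregate": aggregate, **(meta or {})},
    )


def build_calibration_family(
    step_phases,
    diameters_um,
    image_for_step,
    erode_px: int = 2,
    aggregate: str = "mean",
    meta: dict | None = None,
) -> CalibrationFamily:
    """Build a size-resolved calibration from uniform-step disk images.

    ``image_for_step(phi, diameter_um)`` must run the imaging pipeline at
    fixed configuration on a single uniform disk feature, returning
    ``(IntensityImage, labels, background_mask)``.
    """
    diams = np.asarray(sorted(float(d) for d in diameters_um))
    if diams.size < 2:
        raise ValueError("need at least 2 reference diameters")
    curves = []
    label_diams = []
    phi0 = float(min(step_phases))
    for d in diams:
        # index the family by the label-equivalent diameter, the same size
        # metric used for measured regions at retrieval time
        img0, labels0, _ = image_for_step(phi0, d)
        label_diams.append(2.0 * img0.pitch_um * np.sqrt((labels0 > 0).sum() / np.pi))
        curves.append(
            build_calibration(
                step_phases,
                lambda phi, d=d: image_for_step(phi, d),
                estimator="normalized",
                erode_px=erode_px,
                aggregate=aggregate,
                meta={"diameter_um": float(d)},
            )
        )
    return CalibrationFamily(np.asarray(label_diams), curves, meta=meta or {})


# ---------------------------------------------------------------- retrieval
@dataclass
class PhaseEstimate:
    """Retrieved phase map with per-region statistics.

    ``phase_map`` is NaN where the signal falls outside the calibrated range;
    ``region_means`` maps label -> mean retrieved phase; ``region_errors``
    maps label -> |retrieved - truth| when ground truth was supplied.
    """

    phase_map: np.ndarray
    valid_mask: np.ndarray
    frac_out_of_range: float
    region_means: dict[int, float] = field(default_factory=dict)
    region_errors: dict[int, float] = field(default_factory=dict)

    @property
    def max_region_error(self) -> float:
        if not self.region_errors:
            raise ValueError("no ground truth supplied")
        return max(self.region_errors.values())


def _auto_background_level(intensity: np.ndarray, bins: int = 256) -> float:
    """Modal intensity: centre of the most populated histogram bin."""
    hist, edges = np.histogram(intensity.ravel(), bins=bins)
    k = int(np.argmax(hist))
    return 0.5 * (edges[k] + edges[k + 1])


def retrieve_phase_map(
    img: IntensityImage,
    cal: CalibrationCurve,
    background_region: np.ndarray | str = "auto",
    labels: np.ndarray | None = None,
    truth: np.ndarray | None = None,
    erode_px: int = 2,
    aggregate: str = "mean",
) -> PhaseEstimate:
    """Invert a filtered image into a quantitative phase map.

    The image is normalized by the background level — the modal intensity
    when ``background_region`` is 'auto', otherwise the aggregate over the
    given mask — and the per-pixel signal is mapped through the inverse
    calibration.  Pixels outside the calibrated signal range are masked NaN
    (a warning is issued when they exceed 20%).  When ``labels`` (and
    optionally a ground-truth phase map) are given, per-region means and
    absolute errors are attached.
    """
    inten = img.intensity
    agg = np.mean if aggregate == "mean" else np.median
    if isinstance(background_region, str):
        if background_region != "auto":
            raise ValueError("background_region must be a mask or 'auto'")
        bg = _auto_background_level(inten)
    else:
        mask = np.asarray(background_region, dtype=bool)
        mask = binary_erosion(mask, iterations=max(erode_px, 1))
        bg = float(agg(inten[mask]))
    if bg == 0.0:
        raise ValueError("background level is zero")

    signal = inten / bg
    is_family = isinstance(cal, CalibrationFamily)
    if is_family:
        mid = cal.curves[len(cal.curves) // 2]
        pixel_inverse = mid.phase_of  # per-pixel map: reference-size curve
    else:
        pixel_inverse = cal.phase_of
    with np.errstate(invalid="ignore"):
        phase_map = np.asarray(pixel_inverse(signal), dtype=float)
    valid = np.isfinite(phase_map)
    frac_out = 1.0 - valid.mean()
    if frac_out > 0.20:
        warnings.warn(
            f"{frac_out:.0%} of pixels fall outside the calibrated range",
            stacklevel=2,
        )

    est = PhaseEstimate(phase_map, valid, float(frac_out))
    if labels is not None:
        for k in np.unique(labels):
            if k == 0:
                continue
            raw_mask = labels == k
            mask = raw_mask
            if erode_px > 0:
                mask = binary_erosion(mask, iterations=erode_px)
            if not mask.any():
                continue
            # invert the region-mean signal: the same estimator order used to
            # build the calibration, so ripple-induced nonlinearity cancels
            s_k = agg(signal[mask])
            if is_family:
                d_k = 2.0 * img.pitch_um * np.sqrt(raw_mask.sum() / np.pi)
                phi_k = float(cal.phase_of(s_k, d_k))
            else:
                phi_k = float(cal.phase_of(s_k))
            if not np.isfinite(phi_k):
                continue
            est.region_means[int(k)] = phi_k
            if truth is not None:
                t = float(agg(np.asarray(truth)[mask]))
                est.region_errors[int(k)] = abs(phi_k - t)
    return est
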