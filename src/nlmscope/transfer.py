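"""Sampled complex angular transfer functions t(lambda, theta).

The :class:`TransferFunction` is the container every downstream stage consumes:
it holds the complex amplitude transmission of an angular filter sampled on a
(wavelength, angle) grid.  The spatial-frequency coordinate used by the imaging
module is a derived view of the angle axis through the exact mapping
``fx = sin(theta) / lambda`` (cycles per micrometre when lambda is in um).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TransferFunction"]


def _check_monotone(x: np.ndarray, name: str) -> None:
    if x.ndim != 1 or x.size == 0:
        raise ValueError(f"{name} must be a non-empty 1D grid")
    d = np.diff(x)
    if x.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError(f"{name} must be strictly monotone")


@dataclass
class TransferFunction:
    """Complex transmission of an angular filter on a (wavelength, angle) grid.

    Parameters
    ----------
    wavelengths_nm : 1D array of wavelengths in nm (strictly monotone).
    angles_deg : 1D array of signed incidence angles in degrees.
    t : complex array of shape ``(len(wavelengths_nm), len(angles_deg))``.
    polarization : polarization tag; the devices in scope are TM.
    axis : image axis (0 or 1) along which the one-dimensional filter acts.
    tmax : passivity bound used by :meth:`validate`; 1 for physical filters,
        slightly larger for phenomenological models with a residual floor.
    """

    wavelengths_nm: np.ndarray
    angles_deg: np.ndarray
    t: np.ndarray
    polarization: str = "TM"
    axis: int = 1
    tmax: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.atleast_1d(np.asarray(self.wavelengths_nm, dtype=float))
        self.angles_deg = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))
        self.t = np.atleast_2d(np.asarray(self.t, dtype=complex))
        if self.t.shape != (self.wavelengths_nm.size, self.angles_deg.size):
            raise ValueError(
                f"t has shape {self.t.shape}, expected "
                f"({self.wavelengths_nm.size}, {self.angles_deg.size})"
            )
        _check_monotone(self.wavelengths_nm, "wavelengths_nm")
        _check_monotone(self.angles_deg, "angles_deg")
        if self.axis not in (0, 1):
            raise ValueError("axis must be 0 or 1")

    # ------------------------------------------------------------------ checks
    def validate(self, rtol: float = 1e-9) -> None:
        """Raise if |t| exceeds the passivity bound anywhere."""
        mag = np.abs(self.t)
        if not np.all(np.isfinite(self.t)):
            raise ValueError("transfer function contains non-finite values")
        if mag.max() > self.tmax * (1.0 + rtol):
            raise ValueError(
                f"|t| reaches {mag.max():.6f}, above the bound {self.tmax:.6f}"
            )

    # -------------------------------------------------------------- evaluation
    def at_wavelength(self, lambda_nm: float) -> np.ndarray:
        """Complex 1D angular response at ``lambda_nm`` (linear interpolation)."""
        wl = self.wavelengths_nm
        if self.t.shape[0] == 1:
            if not np.isclose(lambda_nm, wl[0], atol=1e-9):
                raise ValueError(
                    f"transfer function sampled only at {wl[0]} nm, "
                    f"cannot evaluate at {lambda_nm} nm"
                )
            return self.t[0].copy()
        if not (wl.min() - 1e-9 <= lambda_nm <= wl.max() + 1e-9):
            raise ValueError(
                f"wavelength {lambda_nm} nm outside coverage "
                f"[{wl.min()}, {wl.max()}] nm"
            )
        idx = np.searchsorted(wl, lambda_nm)
        idx = np.clip(idx, 1, wl.size - 1)
        w = (lambda_nm - wl[idx - 1]) / (wl[idx] - wl[idx - 1])
        return (1.0 - w) * self.t[idx - 1] + w * self.t[idx]

    def fx_per_um(self, lambda_nm: float) -> np.ndarray:
        """Spatial-frequency view of the angle axis: fx = sin(theta)/lambda."""
        return np.sin(np.deg2rad(self.angles_deg)) / (lambda_nm * 1e-3)

    def sample_on_fx(
        self,
        lambda_nm: float,
        fx: np.ndarray,
        fill: complex | None = None,
    ) -> np.ndarray:
        """Interpolate t(lambda, .) linearly in fx onto an arbitrary fx grid.

        Out-of-coverage frequencies raise unless ``fill`` is given.
        """
        t_ang = self.at_wavelength(lambda_nm)
        fx_tf = self.fx_per_um(lambda_nm)
        if fx_tf[0] > fx_tf[-1]:
            fx_tf, t_ang = fx_tf[::-1], t_ang[::-1]
        fx = np.asarray(fx, dtype=float)
        lo, hi = fx_tf[0], fx_tf[-1]
        out_of_band = (fx < lo) | (fx > hi)
        if np.any(out_of_band) and fill is None:
            raise ValueError(
                f"filter band [{lo:.4f}, {hi:.4f}] cycles/um does not cover the "
                f"requested range [{fx.min():.4f}, {fx.max():.4f}] cycles/um"
            )
        out = np.interp(fx, fx_tf, t_ang.real) + 1j * np.interp(fx, fx_tf, t_ang.imag)
        if np.any(out_of_band):
            out = np.where(out_of_band, fill, out)
        return out

    # ---------------------------------------------------------------------- io
    def to_csv(self, path: str | Path) -> None:
        """Long-format CSV with columns wavelength_nm, theta_deg, re_t, im_t."""
        wl, th = np.meshgrid(self.wavelengths_nm, self.angles_deg, indexing="ij")
        pd.DataFrame(
            {
                "wavelength_nm": wl.ravel(),
                "theta_deg": th.ravel(),
                "re_t": self.t.real.ravel(),
                "im_t": self.t.imag.ravel(),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "TransferFunction":
        df = pd.read_csv(path)
        wl = np.unique(df["wavelength_nm"].to_numpy())
        th = np.unique(df["theta_deg"].to_numpy())
        t = np.full((wl.size, th.size), np.nan, dtype=complex)
        iw = np.searchsorted(wl, df["wavelength_nm"].to_numpy())
        it = np.searchsorted(th, df["theta_deg"].to_numpy())
        t[iw, it] = df["re_t"].to_numpy() + 1j * df["im_t"].to_numpy()
        if np.any(np.isnan(t)):
            raise ValueError(f"{path}: grid is not complete rectangular")
        return cls(wl, th, t, **kwargs)

    def to_binary(self, path: str | Path) -> None:
        """Raw float64 (re, im) array plus a JSON sidecar describing the grids."""
        path = Path(path)
        stacked = np.stack([self.t.real, self.t.imag]).astype(np.float64)
        stacked.tofile(path)
        sidecar = {
            "shape": list(stacked.shape),
            "dtype": "float64",
            "layout": "(re/im, wavelength, angle), C order",
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "angles_deg": self.angles_deg.tolist(),
            "polarization": self.polarization,
            "axis": self.axis,
            "tmax": self.tmax,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_binary(cls, path: str | Path) -> "TransferFunction":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        raw = np.fromfile(path, dtype=np.float64).reshape(sidecar["shape"])
        return cls(
            np.asarray(sidecar["wavelengths_nm"]),
            np.asarray(sidecar["angles_deg"]),
            raw[0] + 1j * raw[1],
            polarization=sidecar.get("polarization", "TM"),
            axis=sidecar.get("axis", 1),
            tmax=sidecar.get("tmax", 1.0),
        )
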