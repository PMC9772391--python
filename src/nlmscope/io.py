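"""File I/O for phase maps, intensity images and previews.

Phase and intensity maps travel as 32-bit float TIFF with the physical pixel
pitch stored in the resolution tags (and the full metadata dict as JSON in
the image description); label maps as integer TIFF; previews as 8-bit PNG.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "write_float_tiff",
    "read_float_tiff",
    "write_label_tiff",
    "read_label_tiff",
    "write_png_preview",
]


def write_float_tiff(path, array: np.ndarray, pitch_um: float, meta: dict | None = None) -> None:
    """Float32 TIFF with pitch (um/px) in the resolution tags + JSON metadata."""
    desc = json.dumps({"pitch_um": pitch_um, **(meta or {})}, default=str)
    ppcm = 1e4 / pitch_um  # pixels per centimetre
    tifffile.imwrite(
        path,
        np.asarray(array, dtype=np.float32),
        description=desc,
        resolution=(ppcm, ppcm),
        resolutionunit="CENTIMETER",
    )


def read_float_tiff(path) -> tuple[np.ndarray, float, dict]:
    """Returns (array, pitch_um, metadata)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray().astype(float)
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (ValueError, TypeError):
                meta = {}
        pitch = float(meta.get("pitch_um", 0.0))
        if pitch <= 0:
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                pitch = 1e4 * den / num
        if pitch <= 0:
            raise ValueError(f"{path}: no pixel pitch recorded")
    return arr, pitch, meta


def write_label_tiff(path, labels: np.ndarray, pitch_um: float) -> None:
    desc = json.dumps({"pitch_um": pitch_um, "kind": "labels"})
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32), description=desc)


def read_label_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(int)


def write_png_preview(path, array: np.ndarray, percentile_clip: float = 0.1) -> None:
    """8-bit grayscale preview, robustly stretched between percentiles."""
    a = np.asarray(array, dtype=float)
    lo, hi = np.percentile(a, [percentile_clip, 100.0 - percentile_clip])
    if hi <= lo:
        hi = lo + 1.0
    scaled = np.clip((a - lo) / (hi - lo), 0.0, 1.0)
    iio.imwrite(path, (scaled * 255).astype(np.uint8))
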