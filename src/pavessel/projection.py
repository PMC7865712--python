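"""Image/volume I/O and maximum-amplitude projection (MAP).

A photoacoustic amplitude volume is a non-negative 3D array indexed
(z, row, col); the analysis substrate is its maximum-amplitude projection,
the per-pixel maximum over depth.  Images follow the usual raster
convention: row-major, 0-based, origin at the top-left.

Two normalization modes are supported.  Per-image min-max normalization maps
each MAP to [0, 1] independently; for longitudinal runs a shared intensity
scale (typically the control image's range) can be applied to every
timepoint instead, so that genuine intensity changes between timepoints
survive normalization — with per-image scaling the mean PA signal of every
frame would be pinned to the same range and drug-induced signal increases
would be erased.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "ROISpec",
    "project_map",
    "intensity_scale",
    "normalize",
    "read_image",
    "write_image",
    "read_volume",
    "write_volume",
    "extract_roi",
]


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest: ``row0:row0+height, col0:col0+width``."""

    name: str
    row0: int
    col0: int
    height: int
    width: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ROISpec":
        return cls(**json.loads(text))


def intensity_scale(volume_or_image: np.ndarray) -> tuple[float, float]:
    """(min, max) of an array, the scale used for shared normalization."""
    arr = np.asarray(volume_or_image, dtype=float)
    return float(arr.min()), float(arr.max())


def normalize(image: np.ndarray, scale: tuple[float, float] | None = None) -> np.ndarray:
    """Min-max normalize to [0, 1]; constant input maps to all zeros.

    With ``scale=(lo, hi)`` a fixed scale is applied (values clipped to
    [0, 1]) instead of the image's own range.
    """
    arr = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if scale is None:
        lo, hi = float(arr.min()), float(arr.max())
    else:
        lo, hi = scale
    if hi <= lo:
        return np.zeros_like(arr)
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


def project_map(volume: np.ndarray, scale: tuple[float, float] | None = None) -> np.ndarray:
    """Maximum-amplitude projection of a (z, m, n) volume, normalized to [0, 1].

    ``scale`` switches to shared-scale normalization (see module docstring).
    """
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 3 or vol.size == 0:
        raise ValueError(f"expected a non-empty (z, m, n) volume, got shape {vol.shape}")
    if not np.all(np.isfinite(vol)):
        raise ValueError("volume contains non-finite values")
    if np.any(vol < 0):
        raise ValueError("photoacoustic amplitudes must be non-negative")
    return normalize(vol.max(axis=0), scale=scale)


def _check_grayscale(arr: np.ndarray, path) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError(f"{path}: multi-channel color images are not supported")
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D grayscale image, got shape {arr.shape}")
    return arr


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale TIFF or PNG as float64 in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = _check_grayscale(np.asarray(arr), path)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return np.asarray(arr, dtype=np.float64)


def write_image(image: np.ndarray, path: str | Path, bit_depth: int = 16) -> None:
    """Write a [0, 1] float image as 8- or 16-bit grayscale TIFF/PNG.

    Quantization bounds the write→read round-trip error by 1/(2^bits − 1).
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("expected a 2D image")
    if bit_depth == 16:
        quant = np.rint(np.clip(arr, 0, 1) * 65535).astype(np.uint16)
    elif bit_depth == 8:
        quant = np.rint(np.clip(arr, 0, 1) * 255).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, quant)
    else:
        iio.imwrite(path, quant)


def read_volume(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as a (z, m, n) volume (z = page index)."""
    vol = tifffile.imread(Path(path))
    if vol.ndim == 2:
        vol = vol[None, :, :]
    if vol.ndim != 3:
        raise ValueError(f"{path}: expected a multi-page grayscale TIFF")
    return np.asarray(vol, dtype=np.float64)


def write_volume(volume: np.ndarray, path: str | Path) -> None:
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("expected a (z, m, n) volume")
    tifffile.imwrite(Path(path), vol.astype(np.float32))


def extract_roi(image: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Crop a rectangular ROI; downstream metrics use the crop's own m×n."""
    m, n = image.shape
    if roi.height < 1 or roi.width < 1:
        raise ValueError(f"ROI {roi.name!r} has non-positive size")
    if roi.row0 < 0 or roi.col0 < 0 or roi.row0 + roi.height > m or roi.col0 + roi.width > n:
        raise ValueError(
            f"ROI {roi.name!r} [{roi.row0}:{roi.row0 + roi.height}, "
            f"{roi.col0}:{roi.col0 + roi.width}] outside image of shape {image.shape}"
        )
    return image[roi.row0:roi.row0 + roi.height, roi.col0:roi.col0 + roi.width].copy()
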