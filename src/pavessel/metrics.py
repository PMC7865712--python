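"""The five quantitative vascular parameters.

Given a MAP image I, its binary vessel map B and skeleton map S (all m×n,
T = m·n pixels):

* **PA signal** — mean of I over all pixels, proportional to the absorbed
  optical energy (hemoglobin absorption dominates at 532 nm).
* **diameter** — the Euclidean distance transform E of B gives, at each
  skeleton pixel, the distance to the nearest background pixel (a vessel
  radius); the image-level diameter is the skeleton average.  Both the raw
  EDT average (``edt_mean_px``) and the full-width estimate
  ``diameter_px = 2·mean(E|S)`` are reported.
* **density** — white pixels of B over T: the areal fraction covered by
  vessels.  Sensitive to both vessel caliber and vessel length.
* **length fraction** — white pixels of S over T: total centerline length
  per area.  Insensitive to vessel dilation or constriction, since thinning
  maps a dilated vessel to (nearly) the same centerline.
* **fractal dimension** — box-counting dimension of B: cover the mask with
  grids of box size r, count occupied boxes N(r), and fit
  log N(r) = −D·log r + c by least squares; D is the fractal dimension
  (2 for space-filling masks, 1 for a line, log 8/log 3 ≈ 1.893 for the
  Sierpinski carpet).

Empty-input conventions: an empty skeleton has diameter 0; an empty mask has
fractal dimension 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import distance_transform_edt

__all__ = [
    "BoxCountCurve",
    "VesselMetrics",
    "box_sizes",
    "box_counts",
    "fractal_dimension",
    "mean_diameter",
    "density",
    "length_fraction",
    "pa_signal",
    "pa_signal_vessel",
    "compute_all",
]


@dataclass(frozen=True)
class BoxCountCurve:
    """Box-counting curve: occupied-box counts over a ladder of box sizes."""

    sizes: tuple[int, ...]
    counts: tuple[int, ...]
    fit_slope: float
    fit_r2: float


@dataclass(frozen=True)
class VesselMetrics:
    """The five vascular parameters of one image (or ROI)."""

    pa_signal: float
    diameter_px: float
    edt_mean_px: float
    density: float
    length_fraction: float
    fractal_dimension: float
    fd_fit_r2: float

    def to_dict(self) -> dict:
        return asdict(self)

    PARAMETERS = ("pa_signal", "diameter_px", "density", "length_fraction", "fractal_dimension")


def _is_power_of(x: int, base: int) -> bool:
    if x < 1:
        return False
    while x % base == 0:
        x //= base
    return x == 1


def box_sizes(shape: tuple[int, int]) -> list[int]:
    """Ladder of box sizes for the box-counting estimate.

    Square images whose side is a power of 3 get the exact self-similar
    ladder 1, 3, 9, …, side.  Otherwise the ladder is dyadic from 2 px,
    capped at min(m, n)//8: large boxes are excluded because the ceiling in
    the count of partially covered boxes biases the log-log slope, and the
    1-px box is excluded because counts there saturate to the pixel area of
    the mask rather than follow the covering law.
    """
    m, n = shape
    s = min(m, n)
    if m == n and s >= 3 and _is_power_of(s, 3):
        sizes = []
        r = 1
        while r <= s:
            sizes.append(r)
            r *= 3
        return sizes
    cap = max(8, s // 8)
    sizes = []
    r = 2
    while r <= min(cap, s):
        sizes.append(r)
        r *= 2
    while len(sizes) < 3 and (sizes[-1] * 2 if sizes else 2) <= s // 2:
        sizes.append(sizes[-1] * 2 if sizes else 2)
    return sizes


def box_counts(mask: np.ndarray, sizes: list[int] | None = None) -> tuple[list[int], list[int]]:
    """Number of origin-anchored r×r grid boxes containing vessel pixels."""
    mask = np.asarray(mask, dtype=bool)
    if sizes is None:
        sizes = box_sizes(mask.shape)
    m, n = mask.shape
    counts = []
    for r in sizes:
        pm = (-m) % r
        pn = (-n) % r
        padded = np.pad(mask, ((0, pm), (0, pn)))
        blocks = padded.reshape(padded.shape[0] // r, r, padded.shape[1] // r, r)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    return list(sizes), counts


def fractal_dimension(mask: np.ndarray) -> tuple[float, BoxCountCurve]:
    """Box-counting fractal dimension of a binary mask.

    Returns the dimension (0 for an empty mask) and the underlying
    box-counting curve with the least-squares fit quality.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0, BoxCountCurve((), (), 0.0, 0.0)
    sizes, counts = box_counts(mask)
    log_r = np.log(np.asarray(sizes, dtype=float))
    log_n = np.log(np.asarray(counts, dtype=float))
    if len(sizes) < 2 or np.ptp(log_r) == 0:
        return 0.0, BoxCountCurve(tuple(sizes), tuple(counts), 0.0, 0.0)
    slope, intercept = np.polyfit(log_r, log_n, 1)
    pred = slope * log_r + intercept
    ss_res = float(np.sum((log_n - pred) ** 2))
    ss_tot = float(np.sum((log_n - log_n.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fd = float(-slope)
    return fd, BoxCountCurve(tuple(sizes), tuple(counts), float(slope), r2)


def mean_diameter(mask: np.ndarray, skeleton: np.ndarray) -> tuple[float, float]:
    """Skeleton-averaged vessel width from the EDT of the mask.

    Returns ``(diameter_px, edt_mean_px)`` where ``edt_mean_px`` is the mean
    distance-to-background over skeleton pixels and ``diameter_px`` is its
    full-width counterpart 2·edt_mean_px.  (0, 0) for an empty skeleton.
    """
    mask = np.asarray(mask, dtype=bool)
    skeleton = np.asarray(skeleton, dtype=bool)
    if mask.shape != skeleton.shape:
        raise ValueError("mask and skeleton shapes differ")
    if np.any(skeleton & ~mask):
        raise ValueError("skeleton contains pixels outside the mask")
    if not skeleton.any():
        return 0.0, 0.0
    edt = distance_transform_edt(mask)
    edt_mean = float(edt[skeleton].mean())
    return 2.0 * edt_mean, edt_mean


def density(mask: np.ndarray) -> float:
    """Vessel area fraction: white pixels of the binary map over m·n."""
    return float(np.asarray(mask, dtype=bool).mean())


def length_fraction(skeleton: np.ndarray) -> float:
    """Centerline fraction: white pixels of the skeleton map over m·n."""
    return float(np.asarray(skeleton, dtype=bool).mean())


def pa_signal(image: np.ndarray) -> float:
    """Mean MAP intensity over all pixels (normalized units)."""
    arr = np.asarray(image, dtype=np.float64)
    return float(arr.mean())


def pa_signal_vessel(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean MAP intensity restricted to vessel pixels; 0 for an empty mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    return float(np.asarray(image, dtype=np.float64)[mask].mean())


def compute_all(image: np.ndarray, mask: np.ndarray, skeleton: np.ndarray) -> VesselMetrics:
    """All five parameters of one image with consistent B and S maps."""
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    skeleton = np.asarray(skeleton, dtype=bool)
    if not (image.shape == mask.shape == skeleton.shape):
        raise ValueError(
            f"shape mismatch: image {image.shape}, mask {mask.shape}, "
            f"skeleton {skeleton.shape}"
        )
    diam, edt_mean = mean_diameter(mask, skeleton)
    fd, curve = fractal_dimension(mask)
    return VesselMetrics(
        pa_signal=pa_signal(image),
        diameter_px=diam,
        edt_mean_px=edt_mean,
        density=density(mask),
        length_fraction=length_fraction(skeleton),
        fractal_dimension=fd,
        fd_fit_r2=curve.fit_r2,
    )
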