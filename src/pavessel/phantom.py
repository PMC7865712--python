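"""Synthetic vascular phantoms with exact ground truth.

This module renders branching vascular trees as 2D grayscale images that
mimic maximum-amplitude-projection (MAP) images of superficial vasculature
acquired with optical-resolution photoacoustic microscopy: bright vessels on
a dark background, Gaussian cross-sectional intensity profiles, a Gaussian
point-spread blur emulating the ~12 µm lateral resolution of such systems,
and additive Gaussian noise.  Vessel widths span large trunks (tens of
pixels) down to capillaries (1–4 px) through geometric width decay over
branching levels.

Each phantom carries an exact, pre-blur ground truth (:class:`PhantomTruth`)
— binary mask, one-pixel centerline skeleton, and per-vessel centerlines and
widths — so that every downstream quantity (diameter, density, length
fraction, fractal dimension) can be checked against construction.

A vasoactive drug response is modelled by :class:`DrugEffectSpec`: vessel
dilation, peak-intensity increase, recruitment of new terminal capillaries,
and disc-shaped hyperintense bleeding spots, all scaled per timepoint by an
effect curve so that a 10-timepoint longitudinal series (control followed by
post-injection observations) can be simulated with a known response shape.

All randomness is a pure function of the phantom parameters and their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import line as draw_line

__all__ = [
    "PhantomSpec",
    "DrugEffectSpec",
    "Vessel",
    "PhantomTruth",
    "generate_tree_phantom",
    "apply_drug_effect",
    "generate_series",
    "make_analytic_shape",
    "carfilzomib_like_effect",
    "bortezomib_like_effect",
    "null_effect",
    "DEFAULT_TIMEPOINT_LABELS",
    "DEFAULT_TIMEPOINT_MINUTES",
]

# Observation schedule of a 10-h follow-up series: one pre-injection control
# then 10 min, 30 min, and 1,2,3,4,6,8,10 h post-injection.
DEFAULT_TIMEPOINT_LABELS = (
    "control", "10min", "30min", "1h", "2h", "3h", "4h", "6h", "8h", "10h",
)
DEFAULT_TIMEPOINT_MINUTES = (0.0, 10.0, 30.0, 60.0, 120.0, 180.0, 240.0, 360.0, 480.0, 600.0)

# Stream labels for child seeds of the master seed (np.random.SeedSequence
# spawn keys); a fixed noise-seed stride keeps per-timepoint noise draws
# independent but reproducible.
_GEOMETRY_STREAM = 0
_RECRUIT_STREAM = 1
_BLEED_STREAM = 2
_NOISE_STREAM = 3
NOISE_SEED_STRIDE = 7919


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic vascular tree phantom.

    Defaults describe the desk-scale stand-in for a mouse-ear MAP image:
    a 256×256 frame with three tortuous trunks (~12 px wide) branching three
    levels down to ~2.6 px capillaries, vessel peak intensity 0.8 over a 0.05
    background, 1 px PSF blur and additive Gaussian noise of σ = 0.02
    (vessel-to-noise ratio ≈ 40).
    """

    image_size: tuple[int, int] = (256, 256)
    n_trunks: int = 3
    trunk_width_px: float = 12.0
    branch_levels: int = 3
    width_decay: float = 0.6
    tortuosity: float = 3.0
    vessel_peak_intensity: float = 0.8
    background_level: float = 0.05
    noise_sigma: float = 0.02
    psf_sigma_px: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        m, n = self.image_size
        if m < 1 or n < 1:
            raise ValueError(f"image_size must be positive, got {self.image_size}")
        if self.trunk_width_px < 1:
            raise ValueError("trunk_width_px must be >= 1")
        if self.n_trunks < 1:
            raise ValueError("n_trunks must be >= 1")
        if self.branch_levels < 0:
            raise ValueError("branch_levels must be >= 0")
        if not (0 < self.width_decay <= 1):
            raise ValueError("width_decay must be in (0, 1]")
        if self.tortuosity < 0:
            raise ValueError("tortuosity must be >= 0")
        if not (0 < self.vessel_peak_intensity <= 1):
            raise ValueError("vessel_peak_intensity must be in (0, 1]")
        if not (0 <= self.background_level < 1):
            raise ValueError("background_level must be in [0, 1)")
        if self.vessel_peak_intensity <= self.background_level:
            raise ValueError("vessel_peak_intensity must exceed background_level")
        if self.noise_sigma < 0 or self.psf_sigma_px < 0:
            raise ValueError("noise_sigma and psf_sigma_px must be >= 0")
        # Trunks are laid out across the rows; they must fit without merging
        # into a single slab.
        if min(m, n) < 4 * self.trunk_width_px or m < 2 * self.trunk_width_px * self.n_trunks:
            raise ValueError(
                f"image {self.image_size} too small to place {self.n_trunks} "
                f"trunks of width {self.trunk_width_px} px"
            )


@dataclass(frozen=True)
class DrugEffectSpec:
    """Vascular drug response, scaled per timepoint by ``effect_curve``.

    At effect magnitude e (a value of ``effect_curve``), every vessel width
    is multiplied by ``1 + (dilation_factor - 1) e``, the vessel peak
    intensity by ``1 + (intensity_factor - 1) e``, ``round(recruit_fraction
    × e × n_terminal)`` new terminal capillaries are added, and
    ``round(bleed_spots × e)`` hyperintense discs are rendered next to
    vessels (in the image only, never in the vessel truth mask).  e = 0
    reproduces the baseline phantom exactly.
    """

    dilation_factor: float = 1.2
    intensity_factor: float = 1.5
    recruit_fraction: float = 0.3
    bleed_spots: int = 5
    effect_curve: tuple[float, ...] = (0.0,) + (1.0,) * 9

    def validate(self) -> None:
        if self.dilation_factor <= 0 or self.intensity_factor <= 0:
            raise ValueError("dilation_factor and intensity_factor must be > 0")
        if self.recruit_fraction < 0:
            raise ValueError("recruit_fraction must be >= 0")
        if self.bleed_spots < 0:
            raise ValueError("bleed_spots must be >= 0")
        if any(not (0.0 <= e <= 1.0) for e in self.effect_curve):
            raise ValueError("effect_curve values must lie in [0, 1]")


def carfilzomib_like_effect() -> DrugEffectSpec:
    """Strong acute response: rapid onset, peak at the 30-min timepoint
    (index 2), then slow decay back toward baseline by 10 h."""
    return DrugEffectSpec(
        dilation_factor=1.2,
        intensity_factor=1.5,
        recruit_fraction=0.3,
        bleed_spots=5,
        effect_curve=(0.0, 0.8, 1.0, 0.75, 0.55, 0.4, 0.3, 0.2, 0.12, 0.06),
    )


def bortezomib_like_effect() -> DrugEffectSpec:
    """Weak response: mild dilation/intensity change, no bleeding spots."""
    return DrugEffectSpec(
        dilation_factor=1.05,
        intensity_factor=1.1,
        recruit_fraction=0.05,
        bleed_spots=0,
        effect_curve=(0.0, 0.3, 0.5, 0.4, 0.3, 0.5, 0.3, 0.4, 0.3, 0.2),
    )


def null_effect(n_timepoints: int = 10) -> DrugEffectSpec:
    """Vehicle (saline-like) control: zero effect at every timepoint."""
    return DrugEffectSpec(
        dilation_factor=1.0,
        intensity_factor=1.0,
        recruit_fraction=0.0,
        bleed_spots=0,
        effect_curve=(0.0,) * n_timepoints,
    )


@dataclass
class Vessel:
    """One vessel segment of the tree: a piecewise-linear centerline with a
    constant width.  ``level`` 0 is a trunk; terminal vessels have no
    children."""

    vessel_id: int
    polyline: np.ndarray  # (k, 2) float array of (row, col) vertices
    width_px: float
    level: int
    parent_id: int | None = None


@dataclass
class PhantomTruth:
    """Generator-side ground truth for one phantom image."""

    mask: np.ndarray       # bool (m, n), True on vessel
    skeleton: np.ndarray   # bool (m, n), True on centerline
    per_vessel: list[Vessel] = field(default_factory=list)
    area_fraction: float = 0.0
    skeleton_fraction: float = 0.0

    @property
    def n_terminal(self) -> int:
        return _terminal_count(self.per_vessel)


def _terminal_count(vessels: list["Vessel"]) -> int:
    parents = {v.parent_id for v in vessels if v.parent_id is not None}
    return sum(1 for v in vessels if v.vessel_id not in parents)


# ---------------------------------------------------------------------------
# Geometry


def _smooth_perturbation(rng: np.random.Generator, t: np.ndarray, amplitude: float) -> np.ndarray:
    """Low-frequency perpendicular wiggle of a centerline, max |value| ≈ amplitude.

    t runs in [0, 1] along the vessel; the perturbation vanishes at t=0 so a
    branch stays attached to its parent.
    """
    if amplitude <= 0:
        return np.zeros_like(t)
    out = np.zeros_like(t)
    for k in (1, 2, 3):
        phase = rng.uniform(0, 2 * np.pi)
        out += rng.uniform(0.3, 1.0) / k * np.sin(np.pi * k * t + phase)
    out -= out[0]
    peak = np.max(np.abs(out))
    if peak > 0:
        out *= amplitude / peak
    return out


def _trunk_polyline(rng: np.random.Generator, spec: PhantomSpec, index: int) -> np.ndarray:
    """Trunks run across the full column range at roughly evenly spaced rows."""
    m, n = spec.image_size
    base_row = m * (index + 1) / (spec.n_trunks + 1)
    jitter = rng.uniform(-m / (4 * (spec.n_trunks + 1)), m / (4 * (spec.n_trunks + 1)))
    row = float(np.clip(base_row + jitter, spec.trunk_width_px, m - 1 - spec.trunk_width_px))
    cols = np.arange(0.0, n, 2.0)
    if cols[-1] < n - 1:
        cols = np.append(cols, n - 1.0)
    t = cols / cols[-1]
    rows = row + _smooth_perturbation(rng, t, spec.tortuosity)
    rows = np.clip(rows, 0.0, m - 1.0)
    return np.column_stack([rows, cols])


def _polyline_length(poly: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))


def _point_along(poly: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Point at arc-length fraction ``frac`` and the local unit tangent."""
    seg = np.diff(poly, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    target = frac * cum[-1]
    i = int(np.searchsorted(cum, target, side="right") - 1)
    i = min(max(i, 0), len(seg) - 1)
    local = (target - cum[i]) / seglen[i] if seglen[i] > 0 else 0.0
    point = poly[i] + local * seg[i]
    tangent = seg[i] / seglen[i] if seglen[i] > 0 else np.array([0.0, 1.0])
    return point, tangent


# Minimum boundary-to-boundary gap (px) kept between a branch and any vessel
# other than its parent, so that distinct vessels stay resolvable (and stay
# distinct under a 1-px dilation of the mask).
_CLEARANCE_PX = 4.0


def _truncate_at_collisions(
    pts: np.ndarray,
    width: float,
    parent: Vessel,
    others: list[Vessel],
) -> np.ndarray:
    """Cut a candidate centerline where it would crowd other vessels.

    Against non-parent vessels the clearance applies from the first point;
    against the parent it applies only after the branch has separated from
    it (it necessarily starts on the parent's centerline).
    """
    keep = len(pts)
    sep_thresh = (width + parent.width_px) / 2.0 + _CLEARANCE_PX / 2.0
    separated = False
    pverts = parent.polyline
    overts = [(o.polyline, (width + o.width_px) / 2.0 + _CLEARANCE_PX) for o in others]
    for i, p in enumerate(pts):
        dpar = np.min(np.hypot(pverts[:, 0] - p[0], pverts[:, 1] - p[1]))
        if separated and dpar < sep_thresh:
            keep = i
            break
        if dpar >= sep_thresh:
            separated = True
        hit = False
        for verts, thresh in overts:
            if np.min(np.hypot(verts[:, 0] - p[0], verts[:, 1] - p[1])) < thresh:
                hit = True
                break
        if hit:
            keep = i
            break
    return pts[:keep]


def _branch_polyline(
    rng: np.random.Generator,
    spec: PhantomSpec,
    parent: Vessel,
    length: float,
    tortuosity: float,
    width: float,
    others: list[Vessel] | None = None,
    side: float | None = None,
) -> np.ndarray | None:
    m, n = spec.image_size
    start, tangent = _point_along(parent.polyline, rng.uniform(0.2, 0.85))
    angle = math.atan2(tangent[0], tangent[1])
    if side is None:
        side = 1.0 if rng.random() < 0.5 else -1.0
    angle += side * math.radians(rng.uniform(45.0, 70.0))
    direction = np.array([math.sin(angle), math.cos(angle)])
    n_pts = max(int(length / 2.0) + 1, 4)
    s = np.linspace(0.0, length, n_pts)
    pts = start[None, :] + s[:, None] * direction[None, :]
    normal = np.array([-direction[1], direction[0]])
    wiggle = _smooth_perturbation(rng, s / max(length, 1e-9), tortuosity)
    pts = pts + wiggle[:, None] * normal[None, :]
    inside = (pts[:, 0] >= 0) & (pts[:, 0] <= m - 1) & (pts[:, 1] >= 0) & (pts[:, 1] <= n - 1)
    if not inside[0]:
        return None
    cut = np.argmin(inside) if not inside.all() else len(pts)
    pts = pts[:cut]
    if others is not None:
        pts = _truncate_at_collisions(pts, width, parent, others)
    # very short stubs are dropped: segments barely longer than their
    # parent's radius are not resolvable as distinct vessels
    if len(pts) < 10:
        return None
    return pts


def _build_tree(spec: PhantomSpec, rng: np.random.Generator) -> list[Vessel]:
    vessels: list[Vessel] = []
    next_id = 0
    for i in range(spec.n_trunks):
        vessels.append(Vessel(next_id, _trunk_polyline(rng, spec, i), spec.trunk_width_px, 0))
        next_id += 1
    current = [v for v in vessels]
    for level in range(1, spec.branch_levels + 1):
        width = spec.trunk_width_px * spec.width_decay ** level
        children: list[Vessel] = []
        for parent in current:
            plen = _polyline_length(parent.polyline)
            for side in (1.0, -1.0):  # one child per side: no narrow sibling wedges
                length = plen * rng.uniform(0.35, 0.55)
                others = [v for v in vessels if v.vessel_id != parent.vessel_id]
                poly = _branch_polyline(rng, spec, parent, length,
                                        spec.tortuosity * 0.7 ** level, width, others,
                                        side=side)
                if poly is None:
                    continue
                child = Vessel(next_id, poly, width, level, parent.vessel_id)
                next_id += 1
                children.append(child)
        vessels.extend(children)
        current = children
    return vessels


def _recruited_capillaries(
    spec: PhantomSpec,
    vessels: list[Vessel],
    n_new: int,
    width_scale: float,
    rng: np.random.Generator,
) -> list[Vessel]:
    """New terminal capillaries sprouting from random existing vessels."""
    new: list[Vessel] = []
    if n_new <= 0:
        return new
    cap_width = max(spec.trunk_width_px * spec.width_decay ** max(spec.branch_levels, 1), 1.5)
    next_id = max(v.vessel_id for v in vessels) + 1
    attempts = 0
    while len(new) < n_new and attempts < 20 * n_new:
        attempts += 1
        parent = vessels[rng.integers(0, len(vessels))]
        length = rng.uniform(22.0, 45.0)
        width = cap_width * width_scale
        others = [v for v in vessels + new if v.vessel_id != parent.vessel_id]
        poly = _branch_polyline(rng, spec, parent, length, spec.tortuosity * 0.5,
                                width, others)
        if poly is None:
            continue
        new.append(Vessel(next_id, poly, width, spec.branch_levels + 1, parent.vessel_id))
        next_id += 1
    return new


# ---------------------------------------------------------------------------
# Rasterization


def _rasterize(
    spec: PhantomSpec,
    vessels: list[Vessel],
    peak_intensity: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render mask, skeleton, and pre-noise intensity from the vessel list.

    A pixel belongs to the mask iff its center lies within width/2 (Euclidean)
    of the vessel centerline; intensity follows a Gaussian cross profile
    peak·exp(-d²/(2(width/4)²)), composed across vessels by maximum.
    """
    m, n = spec.image_size
    mask = np.zeros((m, n), dtype=bool)
    skel = np.zeros((m, n), dtype=bool)
    intensity = np.zeros((m, n), dtype=np.float64)

    for v in vessels:
        w = v.width_px
        sigma = w / 4.0
        margin = w / 2.0 + max(3.0 * sigma, 2.0)
        dist = None
        r0 = max(int(np.floor(v.polyline[:, 0].min() - margin)), 0)
        r1 = min(int(np.ceil(v.polyline[:, 0].max() + margin)) + 1, m)
        c0 = max(int(np.floor(v.polyline[:, 1].min() - margin)), 0)
        c1 = min(int(np.ceil(v.polyline[:, 1].max() + margin)) + 1, n)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1, dtype=float),
                             np.arange(c0, c1, dtype=float), indexing="ij")
        dist = np.full(rr.shape, np.inf)
        p = v.polyline
        for a, b in zip(p[:-1], p[1:]):
            ab = b - a
            denom = ab @ ab
            dr = rr - a[0]
            dc = cc - a[1]
            if denom > 0:
                t = np.clip((dr * ab[0] + dc * ab[1]) / denom, 0.0, 1.0)
            else:
                t = 0.0
            qr = dr - t * ab[0]
            qc = dc - t * ab[1]
            np.minimum(dist, np.hypot(qr, qc), out=dist)
        sub = (slice(r0, r1), slice(c0, c1))
        mask[sub] |= dist <= w / 2.0
        np.maximum(
            intensity[sub],
            peak_intensity * np.exp(-(dist ** 2) / (2.0 * sigma ** 2)),
            out=intensity[sub],
        )
        # centerline raster: 8-connected line between successive vertices
        verts = np.rint(p).astype(int)
        verts[:, 0] = np.clip(verts[:, 0], 0, m - 1)
        verts[:, 1] = np.clip(verts[:, 1], 0, n - 1)
        for (ra, ca), (rb, cb) in zip(verts[:-1], verts[1:]):
            lr, lc = draw_line(ra, ca, rb, cb)
            skel[lr, lc] = True

    skel &= mask
    return mask, skel, intensity


def _render_image(
    spec: PhantomSpec,
    intensity: np.ndarray,
    bleed_discs: list[tuple[float, float, float, float]],
    noise_seed: int,
) -> np.ndarray:
    m, n = spec.image_size
    image = np.maximum(spec.background_level, intensity)
    for (rr, cc, radius, peak) in bleed_discs:
        r0 = max(int(rr - radius) - 1, 0)
        r1 = min(int(rr + radius) + 2, m)
        c0 = max(int(cc - radius) - 1, 0)
        c1 = min(int(cc + radius) + 2, n)
        gr, gc = np.meshgrid(np.arange(r0, r1, dtype=float),
                             np.arange(c0, c1, dtype=float), indexing="ij")
        d = np.hypot(gr - rr, gc - cc)
        sub = (slice(r0, r1), slice(c0, c1))
        np.maximum(image[sub], np.where(d <= radius, peak, 0.0), out=image[sub])
    if spec.psf_sigma_px > 0:
        image = gaussian_filter(image, spec.psf_sigma_px, mode="reflect")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence(noise_seed, spawn_key=(_NOISE_STREAM,)))
        image = image + rng.normal(0.0, spec.noise_sigma, size=(m, n))
    return np.clip(image, 0.0, 1.0)


def _make_truth(spec: PhantomSpec, vessels: list[Vessel],
                mask: np.ndarray, skel: np.ndarray) -> PhantomTruth:
    return PhantomTruth(
        mask=mask,
        skeleton=skel,
        per_vessel=vessels,
        area_fraction=float(mask.mean()),
        skeleton_fraction=float(skel.mean()),
    )


# ---------------------------------------------------------------------------
# Public operations


def generate_tree_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Render a baseline vascular phantom and its exact ground truth.

    Returns
    -------
    image : (m, n) float64 array in [0, 1]
    truth : PhantomTruth with pre-blur mask/skeleton and per-vessel widths
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(_GEOMETRY_STREAM,)))
    vessels = _build_tree(spec, rng)
    mask, skel, intensity = _rasterize(spec, vessels, spec.vessel_peak_intensity)
    image = _render_image(spec, intensity, [], spec.seed)
    return image, _make_truth(spec, vessels, mask, skel)


def apply_drug_effect(
    baseline: PhantomSpec,
    effect: DrugEffectSpec,
    timepoint_index: int,
    noise_seed: int | None = None,
) -> tuple[np.ndarray, PhantomTruth]:
    """Render the phantom under the drug effect at one timepoint.

    The underlying vascular tree is the one of ``baseline`` (same seed, same
    geometry); only widths, intensity, recruited capillaries and bleeding
    spots change, each scaled by ``effect.effect_curve[timepoint_index]``.
    Effect magnitude 0 reproduces ``generate_tree_phantom(baseline)`` exactly.
    """
    baseline.validate()
    effect.validate()
    if not (0 <= timepoint_index < len(effect.effect_curve)):
        raise IndexError(
            f"timepoint_index {timepoint_index} outside effect_curve of "
            f"length {len(effect.effect_curve)}"
        )
    e = effect.effect_curve[timepoint_index]
    if noise_seed is None:
        noise_seed = baseline.seed

    rng = np.random.default_rng(
        np.random.SeedSequence(baseline.seed, spawn_key=(_GEOMETRY_STREAM,)))
    vessels = _build_tree(baseline, rng)

    width_scale = 1.0 + (effect.dilation_factor - 1.0) * e
    peak = baseline.vessel_peak_intensity * (1.0 + (effect.intensity_factor - 1.0) * e)

    dilated = [replace(v, width_px=v.width_px * width_scale) for v in vessels]

    n_recruit = int(round(effect.recruit_fraction * e * _terminal_count(vessels)))
    if n_recruit > 0:
        rec_rng = np.random.default_rng(
            np.random.SeedSequence(baseline.seed, spawn_key=(_RECRUIT_STREAM,)))
        dilated.extend(_recruited_capillaries(baseline, dilated, n_recruit, width_scale, rec_rng))

    mask, skel, intensity = _rasterize(baseline, dilated, peak)

    n_bleeds = int(round(effect.bleed_spots * e))
    discs: list[tuple[float, float, float, float]] = []
    if n_bleeds > 0:
        bleed_rng = np.random.default_rng(
            np.random.SeedSequence(baseline.seed, spawn_key=(_BLEED_STREAM,)))
        for _ in range(n_bleeds):
            host = dilated[int(bleed_rng.integers(0, len(dilated)))]
            point, tangent = _point_along(host.polyline, float(bleed_rng.uniform(0.1, 0.9)))
            normal = np.array([-tangent[1], tangent[0]])
            radius = float(bleed_rng.uniform(3.0, 8.0))
            offset = host.width_px / 2.0 + radius * 0.5
            side = 1.0 if bleed_rng.random() < 0.5 else -1.0
            center = point + side * offset * normal
            discs.append((float(center[0]), float(center[1]), radius, peak * 0.9))

    image = _render_image(baseline, intensity, discs, noise_seed)
    return image, _make_truth(baseline, dilated, mask, skel)


def generate_series(
    baseline: PhantomSpec,
    effect: DrugEffectSpec,
    n_timepoints: int,
    labels: tuple[str, ...] | None = None,
) -> list[tuple[str, np.ndarray, PhantomTruth]]:
    """Simulate a longitudinal series over one vascular bed.

    The first element is the unmodified baseline phantom (the pre-injection
    control); subsequent timepoints apply the drug effect at the magnitude of
    ``effect.effect_curve``.  Each timepoint draws independent noise from a
    sub-seed of the master seed, so a zero-effect series yields statistically
    identical but not bit-identical images.
    """
    if n_timepoints < 2:
        raise ValueError("a series needs a control plus at least one timepoint")
    if len(effect.effect_curve) < n_timepoints:
        raise ValueError(
            f"effect_curve of length {len(effect.effect_curve)} shorter than "
            f"{n_timepoints} timepoints"
        )
    if labels is None:
        if n_timepoints == len(DEFAULT_TIMEPOINT_LABELS):
            labels = DEFAULT_TIMEPOINT_LABELS
        else:
            labels = ("control",) + tuple(f"t{i}" for i in range(1, n_timepoints))
    if len(labels) != n_timepoints:
        raise ValueError("labels length must match n_timepoints")

    out = []
    for t in range(n_timepoints):
        noise_seed = baseline.seed + NOISE_SEED_STRIDE * t
        if t == 0:
            image, truth = generate_tree_phantom(baseline)
        else:
            image, truth = apply_drug_effect(baseline, effect, t, noise_seed=noise_seed)
        out.append((labels[t], image, truth))
    return out


# ---------------------------------------------------------------------------
# Analytic shapes (calibration fixtures for the morphometry operators)


def _sierpinski(depth: int) -> np.ndarray:
    if depth == 0:
        return np.ones((1, 1), dtype=bool)
    tile = _sierpinski(depth - 1)
    s = tile.shape[0]
    out = np.zeros((3 * s, 3 * s), dtype=bool)
    for bi in range(3):
        for bj in range(3):
            if bi == 1 and bj == 1:
                continue
            out[bi * s:(bi + 1) * s, bj * s:(bj + 1) * s] = tile
    return out


def make_analytic_shape(name: str, **size_params) -> np.ndarray:
    """Exact binary masks with known morphometry.

    ``filled_square(side)`` — solid side×side square (fractal dimension 2).
    ``straight_line(length, size=(length, length))`` — 1-px horizontal line
    (fractal dimension 1).
    ``sierpinski_carpet(depth)`` or ``(side=3**k)`` — fractal dimension
    log 8 / log 3.
    ``bar(width, length, size)`` — centered horizontal bar of the given
    width, the reference object for diameter recovery.
    """
    if name == "filled_square":
        side = int(size_params["side"])
        if side < 1:
            raise ValueError("side must be >= 1")
        return np.ones((side, side), dtype=bool)

    if name == "straight_line":
        length = int(size_params["length"])
        size = size_params.get("size", (length, length))
        m, n = size
        if length < 1 or length > n:
            raise ValueError("line length must be in [1, n]")
        out = np.zeros((m, n), dtype=bool)
        out[m // 2, :length] = True
        return out

    if name == "sierpinski_carpet":
        if "depth" in size_params:
            depth = int(size_params["depth"])
        else:
            side = int(size_params["side"])
            depth = round(math.log(side, 3))
            if 3 ** depth != side:
                raise ValueError(f"carpet side {side} is not a power of 3")
        if depth < 0:
            raise ValueError("depth must be >= 0")
        return _sierpinski(depth)

    if name == "bar":
        width = int(size_params["width"])
        length = int(size_params["length"])
        m, n = size_params.get("size", (width * 7, length))
        if width > m or length > n:
            raise ValueError("bar does not fit in the image")
        out = np.zeros((m, n), dtype=bool)
        r0 = (m - width) // 2
        c0 = (n - length) // 2
        out[r0:r0 + width, c0:c0 + length] = True
        return out

    raise ValueError(f"unknown analytic shape {name!r}")
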