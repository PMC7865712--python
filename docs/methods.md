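# Methods

This note documents the models, algorithms and numerical choices behind
`pavessel`, and what the synthetic validation does and does not establish.

## The analysis substrate

The unit of analysis is a 2D maximum-amplitude-projection (MAP) image: the
per-pixel maximum over depth of a non-negative photoacoustic amplitude
volume.  Arrays are row-major, 0-based, origin top-left; intensities live in
[0, 1] as float64 internally and are quantized only on file write (16-bit
TIFF for images, 8-bit PNG for masks), bounding write→read error by 1/65535.

Normalization matters longitudinally.  Per-image min–max normalization pins
every frame to [0, 1] and therefore erases between-timepoint intensity
changes — exactly the signal a PA-intensity readout is after.  Longitudinal
runs therefore default to a shared scale: the control frame's (min, max) is
applied to every timepoint (`normalization: shared`).  Per-image mode
remains available for purely morphological questions, and `none` keeps
stored intensities untouched (the simulator writes all timepoints on one
absolute scale).

## Segmentation

1. **Vesselness.**  Frangi's 2D eigenvalue measure for bright ridges,
   maximum over scales σ ∈ {1, 2, 4, 8} px (capillaries are 1–4 px across at
   a ~12 µm-resolution, so the ladder spans capillary to trunk calibers).
   β = 0.5; γ defaults to half the maximum Hessian norm per image.  All
   windowed operations use reflective padding.  Images smaller than the
   largest filter kernel are rejected rather than silently filtered.
2. **Binarization.**  A local-mean adaptive threshold (window 101 px, offset
   +0.02) applied to the *intensity* image proposes candidate components;
   a component survives only if it contains a pixel with vesselness above
   0.05 (of the [0, 1]-normalized response).  The split of labor is
   deliberate: the eigenvalue response localizes vessels extremely reliably
   but concentrates near centerlines and does not span the full lumen, so
   thresholding the response alone under-covers wide vessels (Dice ≈ 0.64
   on tree phantoms); thresholding the intensity alone admits background
   speckle.  Seeded gating combines both (Dice ≈ 0.95, empty masks on
   noise-only frames).  Components below 40 px are removed; enclosed holes
   below 40 px are filled — only small ones, because a vascular network's
   loops legitimately enclose background, and filling those inflates
   density by ~50%.
3. **Boundary regularization.**  The mask boundary is smoothed (Gaussian on
   the binary map, σ = 0.7 px, re-thresholded at 0.5).  The Euclidean
   distance transform is a minimum, so a single noise-driven background
   pixel at a vessel wall biases the local width estimate down by up to
   2 px on wide vessels; regularization caps the width error at ≈1.7 px
   across widths 5–15 px. Setting `mask_smooth_sigma: 0` disables it.
4. **Skeletonization.**  Topology-preserving thinning (Zhang's method,
   8-connected), then pruning of terminal branches that end at a junction
   and are ≤ 10 px long — thinning artifacts from boundary irregularities
   are about as long as the local vessel radius, while real side branches
   extend well beyond it.  Short free-standing paths (both ends open) are
   never pruned: those are small vessels.  The skeleton is intersected with
   the mask, so S ⊆ B holds by construction.

Thinning of a flat-ended bar insets each end by roughly a third of the bar
width; a 9×100 bar yields a 94-px centerline.  Skeleton-length comparisons
in the tests allow for this end effect.

All parameters round-trip through YAML configs and are exposed as CLI flags.
None of them is canonical — they are engineering defaults chosen on the
phantoms, not instrument-validated values.

## The five parameters

* **PA signal** — mean intensity over *all* pixels.  A vessel-masked variant
  (`pa_signal_vessel`) is provided separately; the headline quantity
  deliberately uses the whole frame so it is independent of segmentation.
* **Diameter** — the distance transform E of the mask gives, on the
  skeleton, the distance to the nearest background pixel (a radius).  The
  reported `diameter_px` is 2·mean(E over S); the raw mean is kept as
  `edt_mean_px` so both the full-width and the radius-like convention are
  available.  Empty skeleton → 0.
* **Density** and **length fraction** — white-pixel fractions of B and S.
  Since S ⊆ B, length fraction ≤ density always.  Dilating vessels raises
  density and diameter but leaves the length fraction within ~1% (the
  centerline does not lengthen) — the property that makes the pair
  diagnostic: density moves with *both* caliber and length.
* **Fractal dimension** — grid box counting with origin-anchored boxes, FD
  = −OLS slope of log N(r) vs log r, with the fit R² reported as a quality
  flag.  The ladder is dyadic, r = 2, 4, …, capped at min(m, n)/8.  Two
  exclusions are deliberate: 1-px boxes (their count is the mask's pixel
  area, which forces a slope of −2 over the first octave for any shape) and
  boxes larger than an eighth of the image (the ceiling in partially
  covered boxes flattens the tail; with large boxes included, a 100-px line
  reads ≈0.91 instead of ≈0.97).  Square images whose side is a power of 3
  instead use the exact self-similar ladder 1, 3, 9, …, side, on which the
  depth-4 Sierpinski carpet reproduces N(3ᵏ) = 8⁴⁻ᵏ exactly and FD =
  log 8/log 3 to four decimals.  Grid-offset averaging is not performed
  (origin anchoring matches the plain box-counting definition); dyadic
  grids on base-3 fractals show the well-known log-periodic bias, which is
  why calibration uses each shape's natural scaling factor.  Empty mask →
  FD 0 by convention.

Degenerate-input conventions (empty mask/skeleton → zeros) are explicit
because real pipelines do hit empty ROIs.

## Longitudinal analysis

The baseline is the single pre-injection record per (group, ROI) series —
not a window average — and every parameter is reported as
100·(x(t) − x₀)/x₀.  A zero control value raises an error carrying the
(ROI, parameter) context rather than propagating infinities.  Group
summaries are unweighted means over post-control timepoints, reported per
parameter and pooled over all five, with between-group ratios.  No
hypothesis testing is performed; with one series per arm there is no
replication to test over, and the analysis stays descriptive.

## The phantom generator

The generator emulates the statistical structure of a superficial
vascular MAP image, not its physics:

* **Geometry.**  `n_trunks` tortuous trunks span the frame at separated
  rows; each vessel spawns one child per side per level (branching angle
  45–70°, length 0.35–0.55 of the parent), widths decaying geometrically
  (`width_decay`, default 0.6 from 12 px trunks to 2.6 px level-3
  capillaries).  Branches keep a 4-px boundary-to-boundary clearance from
  all vessels except their parent and are truncated where they would
  crowd another vessel — distinct vessels remain resolvable, and remain
  distinct under a 1-px dilation of the mask.  Stubs shorter than ~18 px
  are dropped.
* **Rendering.**  Ground truth first: the mask is the set of pixel centers
  within width/2 (Euclidean) of the centerline polyline, the skeleton its
  8-connected raster.  Intensity is peak·exp(−d²/(2(width/4)²)) composed
  across vessels by maximum over a constant background, then Gaussian PSF
  blur (1 px, standing in for the ~12 µm lateral resolution) and additive
  Gaussian noise (σ = 0.02 against a 0.75 vessel-to-background contrast).
  Truth is stored pre-blur, so width recovery is measured against exact
  geometry.
* **Drug response.**  At effect magnitude e ∈ [0, 1] (per-timepoint curve):
  widths ×(1 + (dilation−1)e), peak intensity ×(1 + (intensity−1)e),
  round(recruit·e·n_terminal) new terminal capillaries, round(bleeds·e)
  hyperintense discs (radius 3–8 px) beside vessels — in the image but
  never in the vessel truth mask, mimicking extravascular blood.  e = 0
  reproduces the baseline bit-for-bit.  The packaged presets encode an
  acute response peaking at the 30-min timepoint and decaying over 10 h
  (carfilzomib-like), a weak irregular response (bortezomib-like), and a
  zero-effect vehicle control.
* **Seeding.**  One master seed; geometry, recruitment, bleeding and noise
  draw from separate child streams, and each series timepoint uses a
  fixed-stride noise sub-seed.  Every output is a pure function of
  (spec, effect, seed).

What the generator does **not** emulate: speckle or any acoustic wave
physics, depth-dependent sensitivity, vessel crossings in projection (the
clearance rule forbids them), flow or hematocrit variation, motion
artifacts, and the heavy-tailed background texture of tissue.  Passing the
synthetic suite therefore shows that the pipeline recovers known geometry
and known longitudinal effects under idealized imaging statistics; it does
not certify accuracy on instrument data, where threshold and scale defaults
would need re-tuning.

## Problem sizes and runtime

Validation uses 256×256 phantoms (three trunks, three branch levels),
160×256 bars for width recovery, 5 seeds for drug-response recovery, 20
replicate seeds for the null-series stability band, and 10 phantoms for the
dilation-invariance check — sizes at which the full suite runs in a couple
of minutes on one CPU while leaving every effect measurable.
`scripts/acceptance.py` re-derives all headline numbers at these sizes.

## Known limitations

* The diameter estimate inherits thinning artifacts at junctions; on
  heavily branched beds it is biased by a fraction of a pixel.
* The box-counting slope on finite vessel masks mixes the solid-vessel
  regime (locally 2D below the trunk width) with the network regime, so
  its absolute value is ladder-dependent; within a longitudinal series the
  ladder is fixed and percent changes are comparable.
* Bleeding spots are not removed from the mask by design (their status in
  the underlying evaluation protocol is unspecified); ROIs containing
  bleeds therefore report them as vessel area.
* Adaptive-threshold parameters interact with image size (the 101-px
  window must fit); small ROIs should be cropped after segmentation, as
  the pipeline does.
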