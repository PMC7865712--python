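# pavessel

Quantitative vascular evaluation of photoacoustic microscopy images.

Optical-resolution photoacoustic microscopy (OR-PAM) images superficial
vasculature label-free: hemoglobin absorbs the 532 nm excitation strongly, so
the per-pixel maximum of the 3D photoacoustic amplitude volume over depth —
the maximum-amplitude-projection (MAP) image — shows bright vessels on a dark
background at ~12 µm lateral resolution.  `pavessel` turns such MAP images
into five quantitative vascular parameters and tracks their evolution over a
longitudinal experiment (e.g. monitoring the peripheral vasculature of a
mouse ear for 10 h after injecting a vasoactive drug such as the proteasome
inhibitor carfilzomib, against bortezomib and saline controls).

It is written for researchers who have MAP images (or amplitude volumes) and
want reproducible morphometry: segmentation, per-image parameters, and
percent-change-from-control curves per treatment group and region of
interest.

## Method

Stage 1 — segmentation.  A multi-scale Hessian (Frangi-type) vesselness
filter scores bright tubular structures at scales σ ∈ {1, 2, 4, 8} px; an
adaptive local-mean threshold of the intensity image proposes vessel
candidates, which are kept where they contain a strong vesselness response;
small objects are removed, small holes filled, and the binary map B(i,j) is
thinned to a one-pixel-wide skeleton map S(i,j) with short spurs pruned.

Stage 2 — parameter extraction.  With I(i,j) the MAP image, E(i,j) the
Euclidean distance transform of B, and T = m·n the pixel count:

* PA signal  = Σᵢⱼ I(i,j) / T — mean absorbed-energy proxy;
* diameter   = 2 · mean of E(i,j) over skeleton pixels — skeleton-averaged
  vessel width (the raw EDT average is also reported as `edt_mean_px`);
* density    = Σᵢⱼ B(i,j) / T — areal fraction covered by vessels;
* length fraction = Σᵢⱼ S(i,j) / T — centerline length per area, insensitive
  to vessel dilation or constriction;
* fractal dimension = −slope of log N(r) vs log r, where N(r) counts the
  r×r grid boxes containing vessel pixels (box counting; ≈2 for
  space-filling beds, 1 for a single vessel, log 8/log 3 for the Sierpinski
  carpet).

Stage 3 — longitudinal analysis.  Each parameter is expressed as the percent
difference from its pre-injection control value, 100·(x(t) − x₀)/x₀, which
puts the five heterogeneous parameters on one axis; group summaries are
means over post-injection timepoints with between-group ratios.

Because the method must be validated without access to instrument data, the
package ships a synthetic phantom generator: branching vascular trees with
known masks, centerlines and per-vessel widths, Gaussian vessel
cross-profiles, PSF blur, additive noise, and a parameterized drug response
(dilation, intensity increase, capillary recruitment, bleeding spots)
evolving over a 10-timepoint series.

## Worked example

Simulate a strong acute drug response peaking 30 min after injection,
quantify every timepoint, and inspect the percent change at the peak:

```python
from pavessel import (PhantomSpec, SeriesRecord, build_change_table,
                      carfilzomib_like_effect, compute_all, generate_series,
                      segment, summarize_group)

minutes = dict(zip(("control","10min","30min","1h","2h","3h","4h","6h","8h","10h"),
                   (0,10,30,60,120,180,240,360,480,600)))
records = []
for label, image, truth in generate_series(PhantomSpec(seed=42),
                                           carfilzomib_like_effect(), 10):
    mask, skeleton = segment(image)
    records.append(SeriesRecord("carfilzomib_like", label, minutes[label],
                                "full", compute_all(image, mask, skeleton)))

table = build_change_table(records)
print(table[table.timepoint_label == "30min"][["parameter", "percent_change"]]
      .to_string(index=False))
```

prints

```
        parameter  percent_change
          density       20.908643
      diameter_px       17.275099
fractal_dimension        3.088541
  length_fraction        6.439100
        pa_signal       56.375317
```

— at the simulated peak, vessel area is up ~21% (dilation ×1.2 plus newly
recruited capillaries), measured width ~17%, centerline length ~6% (new
capillaries only, since dilation does not lengthen centerlines), network
complexity ~3%, and mean PA signal ~56% (intensity ×1.5 on ~23% of the
frame).  `summarize_group(table, "density")` reports the per-group mean
percent change over the post-injection timepoints (9.28% here).

The same pipeline runs from the shell:

```sh
pavessel end-to-end --out runs/demo --seed 42 --group carfilzomib_like
```

which writes the simulated series, per-image masks/skeletons, `metrics.csv`,
and a percent-change report (CSV + one line plot per parameter) into a
self-describing run directory; re-running from its `config.yaml` snapshot
reproduces the data files bit-for-bit.

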