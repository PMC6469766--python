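# mitoprox

Quantify how a fluorescently labelled protein relates spatially to the
mitochondrial network in two-channel confocal images — directly colocalized,
wrapped around the organelles in rings, pressed against them as puncta, or
unrelated.  Built for imaging experiments of the "does drug X drive protein Y
to mitochondria?" kind, where each treatment group contributes a few dozen
images and the readout is a per-image statistic summarized as group
mean ± SEM.

Two statistics are computed on the segmented (binary) channels $A$ and $B$:

* **Percent overlap** — the Jaccard coefficient
  $|A \wedge B| / |A \vee B|$, times 100.  Strict pixel coincidence: 100%
  for identical masks, 0% for disjoint ones.  Blind to adjacency.
* **Proximity index** — the masks are averaged pixel-wise (1 both, 0.5 one,
  0 neither) and swept by a $2^k \times 2^k$ window ($2 \le k \le 10$,
  default 64 px).  Each window weights its pixels by the ratio factor
  $\min(n_A/n_B, n_B/n_A)$ and scores the mean of its non-zero weighted
  pixels; the image index is the sum of window scores divided by the number
  of non-zero windows.  It lies in [0, 1], is 1 exactly for identical masks,
  0 when a channel is absent — and, unlike the overlap, it credits
  structures that co-occur within a window without touching.

Upstream of the metrics the package provides TIFF/OME-TIFF I/O, the
median → white-top-hat → threshold (Otsu/fixed/quantile) segmentation chain,
a window-size sweep for choosing the analysis granularity, a batch pipeline
with tidy CSV output and JSON-lines run logs, and a synthetic-scene generator
with exact ground-truth masks.  See `docs/methods.md` for the full model
description and design rationale.

## Worked example

```python
from mitoprox import (SceneConfig, generate_scene, segment_pair,
                      percent_overlap, proximity_index, ProximityConfig)

# a synthetic cell: tubular mitochondria, protein forming rings around them
scene = generate_scene(SceneConfig(seed=7, protein_mode="mito_ring"))
mito, prot = segment_pair(scene.image, "mito", "protein")

ov = percent_overlap(mito, prot)
prox = proximity_index(mito, prot, ProximityConfig(k=6))
print(f"thresholds: mito={mito.threshold:.1f}, protein={prot.threshold:.1f}")
print(f"percent overlap: {ov.overlap_percent:.2f}%  (common={ov.common}, union={ov.union})")
print(f"proximity index (64 px window): {prox.proximity_index:.4f} "
      f"over {prox.n_nonzero_windows} non-zero windows")
```

prints

```
thresholds: mito=68.3, protein=66.7
percent overlap: 22.20%  (common=1442, union=6496)
proximity index (64 px window): 0.2821 over 11 non-zero windows
```

The realized Otsu thresholds are carried on the masks (and into the run log)
so the row can be reproduced from the raw image.  The 22% overlap here is
segmentation blur — on the noiseless ground-truth masks the ring overlaps the
mitochondria by exactly 0.00%, yet the proximity index still sees it: at an
8-px window (k=3) the ring scores 0.252 against 0.048 for a
membrane-localized control, which is the separation the window-size sweep is
designed to maximize.

## Command line

```
mitoprox simulate --seed 3 --n 10 --out out/      # synthetic benchmark + sweep
mitoprox analyze  --config run.yaml               # batch over a manifest CSV
mitoprox sweep    --config run.yaml --kmin 2 --kmax 8
```

`analyze` expects a YAML config pointing at a manifest CSV with columns
`image, group, channel_a, channel_b[, roi]`; it writes `results.csv` (one row
per image: pixel counts, overlap, proximity index, realized thresholds),
`summaries.csv` (group mean ± SEM) and `run.log.jsonl`.

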