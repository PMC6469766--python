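# Methods

## The measurement problem

Given a two-channel fluorescence image of a cell — one channel labelling the
mitochondrial network, the other a protein of interest — how much of the
protein sits *on* the mitochondria, and how much sits *near* them?  Pixel-wise
coincidence statistics answer the first question but are blind to the second:
a protein that forms rings around mitochondria, or puncta pressed against
them, scores near zero on any AND/OR measure even though its distribution is
tightly coupled to the organelle.  The package computes two complementary
statistics on segmented (binary) channels.

## Percent overlap

With foreground masks $A$ and $B$,

$$\mathrm{overlap} = \frac{|A \wedge B|}{|A \vee B|},$$

the number of pixels foreground in both channels divided by the number
foreground in either — the Jaccard coefficient of the two masks, reported
both as a fraction and as a percentage.  It is 1 for identical masks and 0
for disjoint ones.  When both masks are empty the ratio is 0/0; the package
defines the result as 0 and emits a warning, since the input is biologically
meaningless.

## Proximity index

The proximity index relaxes strict coincidence to *windowed co-occurrence*:

1. Average the two masks pixel-wise: 1 where both channels are present, 0.5
   where exactly one is, 0 where neither is.
2. Sweep the averaged image from top-left to bottom-right with a
   $2^k \times 2^k$ window, $2 \le k \le 10$.  The default sweep is a
   non-overlapping tiling (stride = window size): each pixel then belongs to
   exactly one window and the "number of windows" in step 5 is unambiguous.
   A smaller stride is available for sensitivity analysis.
3. Per window, compute the **ratio factor** $\min(n_A/n_B,\; n_B/n_A)$ from
   the two foreground pixel counts inside the window; it is 1 when the two
   channels occupy equal areas there and 0 when either is absent.
4. Multiply every pixel in the window by the ratio factor; the window's
   index is the mean of the non-zero weighted pixels (0 if there are none).
5. The image-level index is the sum of the window indices divided by the
   number of windows with a non-zero index, or 0 if every window is empty.

The index lies in [0, 1], is symmetric in the two channels, equals 1 exactly
when the masks coincide, and equals 0 when either channel is absent.  Two
structures that interdigitate inside a window — rings, adjacent puncta —
score highly even with zero pixel overlap, which is precisely the regime
percent overlap cannot see.

The production implementation tiles via integral images (per-window counts in
O(1)); the algebraic identity `window index = ratio × (n_A + n_B) / (2 n_OR)`
follows from steps 1–4 because the non-zero averaged pixels are exactly the
union pixels.  The test suite verifies it against an explicit per-window
Python loop written straight from the stepwise definition (200 random mask
pairs, agreement to 1e−12).

**Edges.** Images whose sides are not multiples of the window keep truncated
right/bottom windows by default ("partial"), so the whole image is scanned.
"pad" (zero-pad to a full tiling) is provided for completeness but is
numerically identical to "partial": padded zeros can enter neither the
counts nor the non-zero-pixel average.  "drop" discards partial windows.

## Window-size selection

The overlap is window-free, but the proximity index depends on the window
size: small windows demand co-occurrence at fine granularity, large windows
forgive larger separations.  `window_size_sweep` computes the mean index per
treatment group at every k in a range and reports, per k, the **separation**
— the largest absolute difference between any two group means — selecting
the k that maximizes it, with ties broken toward the smaller (finer) window.
The default analysis window is 64 px (k = 6).  "Widest distinction" is not a
uniquely defined criterion; the max pairwise group-mean difference was chosen
as the simplest scale-free formalization.

## Segmentation

Each channel passes through a median filter (square window, default radius 1,
i.e. 3×3) to suppress shot noise, then a white top-hat with a disk
structuring element (default radius 15 px) to remove slowly varying
background while keeping structures thinner than the element — appropriate
for tubular organelles imaged at roughly 100 nm/px.  Filter order is fixed
(noise removal before background subtraction); either filter can be disabled.
A single global threshold then binarizes the filtered channel, foreground
strictly above the threshold.  The default method is Otsu's
(between-class-variance maximization), with `fixed` and `quantile`
(upper-tail fraction) overrides; manual per-image threshold picking is not
reproducible, so every run logs the realized threshold instead.  A constant
channel has a degenerate histogram under Otsu: the package warns and returns
an all-zero mask.  An optional ROI mask zeroes pixels outside the region
before thresholding and clips the final masks to the region.

Intensities are kept on their native scale end to end (no normalization), so
fixed thresholds refer to camera units, and the top-hat makes fixed-threshold
masks invariant to constant intensity offsets.

## Synthetic scenes

No raw imaging data accompanies the statistics, so the package ships a
generator whose scenes have exactly known foreground masks.  A scene is a
filled-ellipse "cell" covering ~60% of a 256×256 frame (any size ≥ 64 px
works) containing:

* **mitochondria** — either a tubular network (persistent random walks,
  ~3 px wide, 12 tubules of 60 steps by default) or fragmented perinuclear
  clusters (40 disks of radius 2–4 px packed around a nucleus-offset
  centre), the morphologies of healthy vs. depolarized cells;
* **protein** — one of five modes: plasma-membrane annulus (4 px thick),
  uniform cytosolic puncta (radius-2 disks), *mito_colocalized* (a fraction
  `coloc_fraction` of a fixed pixel budget — 4% of the cell area — sampled
  from the mitochondrial mask, remainder as cytosolic puncta),
  *mito_ring* (a 3-px dilation band around the mitochondria, excluding
  them), or *mito_adjacent_puncta* (puncta confined to a 6-px band off the
  mitochondria).

The colocalized subsets are drawn through a seed-fixed permutation and the
puncta through a truncated deterministic sequence, so the foreground sets are
*nested* in `coloc_fraction`: the overlap is then exactly monotone in the
fraction, not merely on average.  `displacement` shifts the finished protein
pattern toroidally (area-conserving), providing a controlled way to move the
protein off the mitochondria.

Rendering: signal amplitude 200 on a 16-bit scale, Gaussian PSF (σ = 1 px
default), linear background gradient (amplitude 30, offset 10), Poisson shot
noise plus Gaussian read noise (σ = `noise_scale`, default 5; 0 disables
both), quantized to integers.  These values give a noiseless-scene Otsu
segmentation Jaccard of 0.74–0.89 against truth for resolvable structures.

What the generator does **not** emulate: 3-D structure and out-of-focus
light, chromatic shift, photobleaching, cell-to-cell morphology
heterogeneity, and spatially correlated backgrounds.  Passing tests
demonstrate the correctness and discriminative behaviour of the statistics
under controlled geometry, not segmentation robustness on real micrographs.
One deliberate idealization matters for interpretation: the
`mito_colocalized` truth mask is a scattered single-pixel sample of the
mitochondrial mask, which is below segmentation resolution once blurred —
segmentation-fidelity checks therefore use the spatially coherent modes
(membrane, ring) and the mitochondrial channels.

## Statistical aggregation and the monotonicity check

The pipeline reports per-image rows plus group mean ± SEM
(SEM = sample SD/√n; defined 0 for n = 1); hypothesis testing is deliberately
out of scope and left to downstream tools.  The proximity index of a *single*
scene is a quantized statistic (a handful of windows, each with a
discontinuous ratio factor), so its decay with displacement is monotone only
in expectation: a 32-px toroidal shift can drop the protein onto *other*
mitochondria.  The monotonicity tests therefore assert the displacement decay
on the 10-scene group mean — mirroring how any real analysis (25 images per
condition) would aggregate — and they hold for both phenotypes.

## Defaults and numerical choices

| parameter | default | why |
|---|---|---|
| window k | 6 (64 px) | standard analysis window; also near the sweep optimum on the synthetic benchmark |
| stride | = window | unambiguous window count; configurable |
| edge policy | partial | whole image scanned |
| median radius | 1 px | minimal shot-noise suppression |
| top-hat radius | 15 px | > tubule half-width, < background scale |
| threshold | Otsu | reproducible surrogate for manual picking |
| scene size | 256 px | holds windows up to k = 8 |
| scenes per group | 10 | benchmark scale; SEM small enough to order groups |

The synthetic benchmark (`run_synthetic_benchmark`) compares a fully
colocalized group against a membrane-localized control, n = 10 each, through
the full pipeline, and sweeps k = 2..8 (the full range a 256-px scene can
hold).  All randomness in a batch derives from one base seed
(`seed_i = (base·100003 + i) mod 2^31`), making every output byte-reproducible.
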