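# Methods

This note documents the models, parameters and design choices behind
`spikeseg`, in the order data flows through the package.

## Problem setting and assumptions

The package targets side-view images of single cereal plants
photographed in a greenhouse chamber against a uniform blue background
(acquisition format 2560 × 2976). The quantity of interest is the spike
(ear): its location (bounding box), its pixel-accurate extent (binary
mask, 1 = spike), and per-spike morphometric traits. Two regimes make
this hard: green spikes in a green canopy (GSGC) and yellow spikes in a
yellow canopy (YSYC), where color distributions of spike and leaf
overlap almost entirely. The working assumptions of the texture
pipeline are:

1. spikes carry dense, high-frequency texture (spikelet rows, awns),
   while leaves and stems are locally smooth;
2. residual false positives of a per-pixel classifier are thin and
   elongated (leaf edges, tillers, stems), while true spikes are
   compact;
3. the background is near-uniform, so its color alone nearly identifies it.

Assumption 1 justifies Laws texture energies as the main feature,
assumption 2 the vesselness-based component filter, assumption 3 the
inclusion of raw color channels and background-colored padding/fill
throughout the data preparation.

## Texture-energy features (`texture_ann`)

Gray conversion uses the standard luminance weights (scikit-image
`rgb2gray`, range [0, 1]).

**Haar LL subband.** With `use_dwt=true` (default) features are
computed on the level-1 Haar approximation subband and nearest-neighbor
upsampled back to full resolution. The subband is normalized to the
averaging convention — a constant image maps to the same constant, so
the LL of Haar is exactly the 2 × 2 block mean. This halves compute,
suppresses single-pixel noise, and costs some boundary resolution. Odd
image dimensions are edge-padded before the transform.

**Laws responses.** The nine 3 × 3 masks are the outer products of
L3 = (1, 2, 1), E3 = (−1, 0, 1), S3 = (−1, 2, −1), in the fixed channel
order L3L3, L3E3, L3S3, E3L3, E3E3, E3S3, S3L3, S3E3, S3S3. Responses
are sliding inner products with edge replication at borders. The L3L3
kernel has sum 16 (a smoothing mask); every kernel containing E3 or S3
sums to zero, so constant regions produce zero response. The sign
convention (inner product vs. strictly flipped convolution) is
irrelevant downstream because only |F| enters the energy.

**Macro-window energy.** `E = mean |F|` over a (2n+1) × (2n+1) window,
i.e. normalized by (2n+1)². A normalization by window *side* rather
than window *area* would make the statistic scale with window height
and no longer be a mean deviation, so the area normalization is used
deliberately. Default `n = 7` (15 × 15 window): large enough to pool
texture over several spikelet periods, small enough not to erase
spike-scale structure at the LL resolution. Exposed in `FeatureConfig`.

**Feature stack.** Nine energies, plus (default) the raw R, G, B values
scaled to [0, 1] — 12 features per pixel. Channel provenance is stored
with the stack and checked at prediction time.

## Shallow pixel classifier

A single-hidden-layer network (default 10 hidden units, logistic
activations, logistic output) maps the standardized feature vector to a
spike probability. Training draws a balanced sample —
`sample_per_class` (default 20 000) spike pixels and as many background
pixels, seeded, without replacement across all training images —
standardizes by the training mean/sd (stored in the model), and fits
with scikit-learn's `MLPClassifier` (Adam, learning rate 10⁻³, epoch
cap 300, seeded). Balanced sampling matters because spikes occupy ~1%
of a scene; an unbalanced fit would trivially predict background.
The trained weights, the scaler and the feature configuration are
serialized to a single JSON file; prediction uses an in-package numpy
forward pass (tested to agree with the training backend to 1e-10), so
inference does not depend on scikit-learn internals. The decision
threshold is 0.5 on the probability; it is a model field and can be
recalibrated without retraining.

The hidden width, activation and optimizer are deliberately minimal —
the point of the shallow baseline is a small, interpretable model that
trains in seconds on a CPU.

## Vesselness post-filter (`frangi_postfilter`)

Per scale σ ∈ {1, 2, 3, 4} px, the Hessian is computed from Gaussian
derivative filters and scale-normalized by σ². With eigenvalues ordered
|λ₁| ≤ |λ₂|, the response is
`exp(−R_B²/2β²) · (1 − exp(−S²/2γ²))` with `R_B = λ₁/λ₂` (blobness) and
`S = √(λ₁² + λ₂²)` (structureness), zeroed where polarity is wrong
(bright ridges need λ₂ < 0); the map is the per-pixel max over scales.
β defaults to 0.5 (the customary value).

**Auto-γ.** γ is set per scale to **half the 99th percentile of S**
rather than half its maximum. The classic half-max rule assumes S is
dominated by the structures one wants to enhance; here the strongest
Hessian responses come from spike texture, a sparse set of outlier
pixels, and normalizing by them crushes the response on
moderate-contrast lines — exactly the structures the filter must catch.
A high quantile keeps the rule parameter-free while being robust to
those outliers. Two guards: scales with essentially no structure
(max S < 10⁻¹²) contribute nothing — so a constant image yields an
all-zero map with no division by zero — and if the 99th percentile is
degenerate relative to the max (sparse-structure images), the rule
falls back to half-max. The image mean is subtracted before filtering
because truncated discrete derivative kernels do not annihilate
constants exactly.

**Component rule.** A connected component of the predicted mask is
removed only when all three hold: mean vesselness ≥ 0.15, eccentricity
≥ 0.97, major axis ≥ 50 px. The conjunction is what protects true
spikes — a spike ellipse with aspect ratio ≤ ~3.5 has eccentricity
below 0.96 and fails the elongation test regardless of its vesselness.
Operating on components rather than pixels avoids perforating spike
interiors. Filters only remove pixels, so the output is always a subset
of the input mask. A small-component sweep (`clean_small_components`,
area threshold in pixels) is available as a final cleanup.

## Synthetic scenes (`synthetic_data`)

The generator emulates the statistical structure of the greenhouse
setup, not its photometry: a blue background (default RGB (30, 60,
150)) with Gaussian sensor noise (σ = 3 intensity units); thin
near-vertical stems; curved smooth leaf strokes; and spikes as tilted
ellipses (half-width 7–11 px, aspect 2.4–3.3 at the default canvas)
carrying striped-plus-speckle texture and a fan of thin awns at the
tip. Spike and leaf hues are drawn from overlapping ranges per regime
(GSGC: green–green; YSYC: yellow–yellow) so that color alone cannot
separate them. The default canvas is 512 × 595, the acquisition aspect
ratio at ~1/5 scale, chosen so the full train/evaluate benchmark runs
in about a minute on one CPU; geometry scales with the canvas.

Spikes are sampled over three visibility categories with default mix
(0.53, 0.30, 0.17), the composition observed in greenhouse test images
(80 top / 45 inner / 27 occluded-emergent of 152):

* `top` — upper image quartile, zero leaf overlap;
* `inner` — ≥ 30% of the ellipse overlaps leaf strokes drawn behind the
  spike (a backing leaf is added when random placement cannot reach the
  quota);
* `occluded_emergent` — 40–55% of the ellipse is erased by an occluding
  leaf; the erased pixels leave the mask but the bounding box keeps the
  full pre-occlusion extent, mirroring how a partially hidden spike is
  still annotated as one object.

Every box encloses at least one mask pixel, all mask pixels lie inside
the box union, and a fixed seed reproduces the scene byte for byte.
Placement retries are capped at 1000 per spike; exhaustion raises a
placement error rather than silently dropping spikes.

`inject_linear_artifacts` fabricates the classifier's characteristic
failure mode at known positions: thin (2 px) straight segments traced
along rendered stems, kept ≥ 3 px clear of the spike mask and of any
mask passed as `avoid` (typically the prediction they will be unioned
with) so they form separate components; fragments with major axis
< 60 px are dropped. This gives a controlled false-positive set for
measuring the post-filter's removal rate.

What the scenes do **not** emulate: perspective and lighting gradients,
specular highlights, soil/pot clutter beyond a simple pot rectangle,
self-similar canopy texture, real spike morphology (barley/rye awns,
curvature), or annotation noise. Passing the synthetic benchmark
therefore demonstrates that the pipeline's machinery is correct and
that texture separates textured-compact from smooth-elongated
structures; it does not certify accuracy on real greenhouse images.

## Dataset preparation (`dataset_prep`)

* **Split**: seeded shuffle, |train| = round-half-up(ratio · N). At the
  published dataset size (292 images, ratio 0.8) this yields 234/58,
  matching the study the pipeline re-implements. Both parts are kept
  non-empty.
* **Frames**: non-overlapping S × S tiling (default 256), right/bottom
  edges padded to a multiple of S — image pixels with the median border
  color (the chamber background), mask with 0 — so stitching and
  cropping reconstructs the originals exactly. A frame is a *spike
  frame* when its spike-pixel fraction reaches 0.5% (one stray pixel
  should not label a frame positive; the threshold is exposed).
* **Balancing**: all spike frames are kept; near-constant
  pure-background frames (per-channel std < 8 intensity units) are
  dropped first; remaining background frames are subsampled, seeded,
  to `round(n_spike / ratio)` (default ratio 1:1). Background is never
  upsampled — if too few frames remain, all are kept and a warning
  is issued.
* **Augmentation**: one seeded draw per call — rotation uniform in
  [−30°, 30°] (bilinear for the image, nearest-neighbor for the mask so
  labels stay binary; exposed corners filled with the median border
  color rather than black), a fair-coin horizontal flip applied to both
  or neither, and a brightness factor uniform in [0.5, 1.5] multiplying
  all channels with clipping to [0, 255], mask untouched.

## Evaluation (`evaluation`)

Matching is greedy in descending confidence; each prediction takes the
unmatched ground truth of highest IoU if that IoU reaches the threshold
(default 0.5), else it is a false positive; unmatched ground truths are
false negatives. Confidence ties break by higher IoU, then input
order. IoU uses half-open box areas. A detection-level true negative
is defined at the image level (spike-free image, no predictions), since
per-box true negatives do not exist; undefined ratios are reported as
NaN with a warning, never silently as 0.

AP interpolates precision as `p(r) = max precision at recall ≥ r`:
the VOC flavor averages over 11 recall levels {0, 0.1, …, 1} at a
single IoU threshold; the COCO flavor over 101 recall points
{0, 0.01, …, 1} per threshold, averaged across the 10 thresholds
0.50:0.05:0.95. The dataset-level PR curve ranks predictions globally
but matches per image. Both implementations are tested to 10⁻¹⁰
against a brute-force oracle that enumerates confidence cutoffs and
re-matches from scratch.

Mask metrics: Dice and Jaccard on the spike class; aDC and mean IoU
average the class-wise scores over spike and background; pixel accuracy
is the per-pixel agreement rate. An empty-vs-empty class is defined as
1.0. Category-stratified reports attribute each TP/FN to its ground
truth's category and each FP to the nearest ground truth's category by
box-center distance (`uncategorized` on empty images); the mean
confidence of matched true positives is reported per category as the
probability-column analogue of detection summaries.

## Trait registry (`phenotyping`)

Exactly 70 descriptors per 8-connected region (version 1.0 of the
registry; columns are fixed in order so tables are comparable across
runs): 12 shape (area, perimeter, bbox width/height, aspect ratio,
extent, solidity, eccentricity, major/minor axis, orientation,
compactness 4πA/P²), 32 color (mean/sd/min/max of R, G, B, hue,
saturation, value, plus an 8-bin hue histogram), 26 texture (mean and
sd of the nine Laws energies inside the region, computed with a local
5 × 5 energy window, plus GLCM contrast/homogeneity/energy/correlation
at unit offsets 0° and 90° on a 32-level quantization of the region's
bounding-box crop). Hue mean/sd are circular to avoid the 0/360 wrap
artifact; hue min/max remain plain order statistics. Degenerate
regions (< 4 px or a 1-pixel-wide bounding box) fall back to flat GLCM
values (contrast 0, homogeneity 1, energy 1, correlation 0), zero
texture sd, and compactness 1 at zero perimeter, so no row contains
NaN. Regions are ordered row-major by centroid. The registry is this
package's own definition of a documented trait set; no equivalence with
any external tool's unpublished trait list is claimed.

## Numerical and interface conventions

* Boxes are 0-based half-open internally; VOC XML on disk keeps its
  native 1-based inclusive convention (LabelImg compatibility), YOLO
  dialects store normalized center/size and need the image size to
  round-trip (exact to ±1 px). Out-of-bounds boxes are clamped with a
  warning, not rejected.
* Masks accept 0/1 and 0/255 encodings on read (any value > 0 is
  spike); RGB mask files binarize by any-channel > 0 with a warning.
* All stochastic operations take integer seeds and use a dedicated
  `numpy` generator; nothing reads the clock or global RNG state.
  Derived seeds stay below 2³¹.

## Known limitations

* The texture features assume spikes are *more* textured than their
  surroundings; crops with strongly textured leaves (disease, specular
  water droplets) would erode the margin.
* Vesselness is computed on luminance; a line structure that is
  isoluminant with the background (but visible in chroma) is invisible
  to the post-filter and will survive it.
* The component filter removes whole components; a false-positive
  bridge that fuses two true spikes into one elongated component could
  in principle drag spike pixels away with it (mitigated, not
  eliminated, by the conjunction of three criteria).
* Frame balancing drops information (background frames); it is a
  training-set operation and must not be applied to evaluation data.
* The shallow classifier is a per-pixel model with no spatial
  regularization beyond the energy window; its boundaries are soft at
  the scale of the macro window, which bounds achievable Dice on thin
  structures like awns.
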