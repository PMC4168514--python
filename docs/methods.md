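# Methods

## Problem and pipeline

`tomatodetect` detects individual tomato fruits — mature, immature and
young — in flash-lit nighttime RGB images of greenhouse canopies.  The
central difficulty is that no fixed color/size threshold works across
images, so every decision is learned from labeled data.  The pipeline has
three stages:

1. **Pixel-based segmentation.**  Every pixel is described by 15 color
   features drawn from five color spaces — normalized rgb; H, S, V;
   CIE L\*a\*b\*; CIE L\*u\*v\*; YCbCr — and classified into
   {fruit, leaf, stem, background} by a CART decision tree.
2. **Blob-based false-positive elimination.**  8-connected components of
   fruit pixels become *blobs*: the minimal enclosing rectangle, binary
   mask and RGB crop.  Each blob is described by 19 features (the mask
   mean of the 15 color features; gray-histogram contrast; GLCM angular
   second moment; size = bbox width×height; aspect = width/height) and a
   random forest sorts blobs into multi-fruit / single-fruit / non-fruit.
   Non-fruit blobs are dropped; this stage only ever removes candidates.
3. **Individual-fruit localization.**  A single-fruit blob is located at
   its mask centroid.  A multi-fruit blob (a truss of touching fruits) is
   resolved through the specular highlight the camera flash leaves on each
   fruit: the highlight map V·(1−S) is computed over the blob, its values
   on mask pixels are clustered by 1-D X-means, the cluster with the
   highest mean is kept, and each 8-connected component of kept pixels of
   at least `min_region` pixels yields one detection at its centroid.

Evaluation matches detections to ground-truth fruit disks (greedy
one-to-one, nearest first, a detection is matchable when it lies within
the fruit's radius) and reports recall = matched fruits / all fruits,
per growth stage and overall, and precision = matched detections / all
detections.  Undefined ratios (no fruits, no detections) are reported as
absent rather than 0 or 1.  A vertical three-part crop protocol
(`partition_parts`, half-open row intervals, fruits assigned by centroid
row) supports part-by-part evaluation.

## Color conventions

The source imagery convention is fixed as: sRGB primaries and D65 white
point for L\*a\*b\*/L\*u\*v\*; BT.601 *full-range* YCbCr (Y, Cb, Cr in
[0, 255]); hue in degrees [0, 360), defined as 0 for achromatic pixels;
normalized rgb defined as 1/3 each at black.  All conversions run in
floating point without intermediate 8-bit re-quantization.  Grayscale for
texture features is BT.601 luma rounded to 8 bits.

## Texture dialect

The GLCM uses 256 gray levels, the single offset (0, 1) plus its
symmetric pair, normalized counts, computed over the full rectangular
patch (the rectangle is what the downstream classifier sees).  ASM is
Σp² ∈ (0, 1], exactly 1 for constant patches.  Histogram "contrast" is
interpreted as the variance of the gray-level distribution (the standard
first-order contrast statistic); mean absolute deviation or range are
defensible alternatives.  Patches too narrow for a horizontal pair take
the constant-texture limits ASM = 1, contrast = 0.  Blob color means use
mask pixels only, to avoid background bleed inside the rectangle; both
domains are deliberate and documented rather than inherited.

## X-means

`xmeans_1d` starts from one cluster and alternates: (a) each cluster
attempts a 2-means split, accepted when the two-cluster BIC of that
cluster's points beats the one-cluster BIC; (b) all centroids are refined
by global k-means, which re-snaps boundaries after a split.  One split —
the largest BIC gain — is applied per round, so every intermediate k is
visited; the model with the best global BIC over all visited rounds is
returned.  The BIC models each cluster as a Gaussian with its own MLE
variance, weighted by the mixing proportion, with free-parameter count
k·(d+1)+1 and penalty (p/2)·log n.  Ties keep the smaller model, biasing
against fruit over-counting.  2-means is deterministic multi-start: Lloyd
from nine quantile thresholds, lowest SSE wins, which keeps split
boundaries out of dense modes.  Numerical guards: per-cluster variances
are floored at (data span)²·10⁻¹⁸ so a perfectly separating split of
multimodal data gets a large but finite likelihood while constant data
never splits; splits producing a cluster below `min_cluster = 3` points
are not considered.  With `kmax = 1` the result is the global mean.
Defaults: `kmax = 20` per blob (generously above any plausible truss
size), `min_region = 5` pixels (suppresses single-pixel glints).

## Classifier settings

Pixel CART: Gini impurity, unlimited depth, `min_samples_leaf = 50`, no
class reweighting (training is fruit-heavy by design, 1.4:1:1:1), fixed
seed.  The large leaf floor keeps the tree compact and noise-resistant at
the ~10³–10⁵ sample scales used.  Blob forest: 500 trees, √19 features
per split, bootstrap, out-of-bag scoring, fixed seed; per-feature
mean-decrease-Gini importances are exposed, and on canopy-like training
sets blob *size* ranks first — tiny noise blobs versus fruit-scale blobs
is the dominant contrast.

Training data enters either as seed clicks (each click contributes the
pixel and its in-bounds 8-neighbors under one label) or as full label
masks; both produce the same `PixelSample` records.  Blob training sets
are collected classifier-in-the-loop: training scenes are segmented with
the fitted pixel model and every fruit-class component is labeled by the
number of ground-truth fruit centroids it contains (≥2 → multi-fruit,
1 → single-fruit, 0 → non-fruit).  This gives the non-fruit class the
same distribution of false positives the filter will face, including the
rare organ pixels whose color drifts into the fruit classes.  Non-fruit
components are subsampled at random across at least eight scenes.  A
model-free fallback labels components of the *true* class map and injects
small salt-speckle blobs as the non-fruit class.  Default scale follows
the field practice of ~30/200/2000 multi/single/non blobs and a
fruit-weighted pixel set (here 1400/1000/1000/1000 per class, a 1:100
scale-down of the ~140k/100k-pixel practice, chosen to keep a full
train-and-evaluate cycle in seconds on one CPU).

## Synthetic scenes

The generator emulates the imaging conditions the method assumes:
nighttime flash photography, so organs are bright against a dark
background and every fruit carries one small overexposed highlight.
A scene (default 480×640) contains:

- disk-shaped fruits in three stages with distinct radius ranges
  (young 6–10 px, immature 11–16, mature 15–22) and color families
  (young dark green, immature pale whitish-green, mature red), each with
  per-fruit color jitter (±6 gray levels per channel), radial flash
  shading (rim brightness 70% of center) and one near-white highlight
  disk (radius ≈ 0.22·r, offset ≈ 0.4·r, random direction);
- trusses: chains of mutually tangent fruits overlapping by 2 px so their
  fruit-pixel region is one 8-connected component (the multi-fruit case);
- elliptical leaves and thick slanted stems; the young-fruit color family
  is deliberately placed adjacent to the stem family, reproducing the
  hardest real confusion (young fruit vs stem) — the stage families stay
  pairwise distinguishable at zero noise;
- a 2% multiplicative per-pixel surface texture on every organ.  This is
  intrinsic scene realism, not sensor noise: perfectly flat per-object
  colors are degenerate inputs for an axis-aligned decision tree (one
  threshold can flip an entire organ), a failure mode no real photograph
  exhibits;
- salt speckles (isolated fruit- or highlight-colored pixels at rate
  2×10⁻³, kept ≥2 px away from true fruit pixels) emulating sensor salt
  noise and background glints — the raw material of non-fruit blobs;
- optional leaf occlusion of fruits (default off) and additive Gaussian
  sensor noise (default σ = 2 gray levels) clipped to [0, 255].

Ground truth is exact by construction: the full class map, every fruit's
centroid/radius/stage/truss and every highlight center.  All randomness
derives from one root seed; scenes are bit-reproducible.

What the generator does *not* emulate: perspective, shading from
neighboring foliage, specular anisotropy, camera optics, JPEG artifacts,
real tomato colorimetry, and fruits without any visible highlight.
Passing tests therefore demonstrate that the pipeline machinery is
correct and behaves as the method predicts under its stated assumptions;
they do not certify accuracy on real greenhouse imagery, whose headline
numbers depend on data unavailable here.

## Experimental design choices

- **Scale.**  Test runs use 5–20 scenes of 480×640 px with ~11 fruits per
  scene and the 1:100 pixel-training scale-down; these sizes keep the
  full suite and the acceptance script within minutes on one CPU while
  leaving every mechanism (speckle filtering, truss splitting, stage
  stratification) active.
- **Noise-degradation runs are matched train/test**: models are trained at
  the noise level they are evaluated at, with identical scene seeds
  across levels.  A single model evaluated across noise levels measures
  distribution-shift robustness, not scene difficulty, and is not
  monotone.
- **Stage-ordering comparisons use isolated fruits**, because truss
  members incur an additional, unrelated loss channel (highlight
  clustering) that would confound the color-difficulty ordering.
- Undefined metrics are surfaced as absent values and as errors from the
  low-level `recall`/`precision` functions, mirroring tabulation practice
  of leaving cells empty for absent stages.

## Known limitations

- Fruits without a specular highlight inside a multi-fruit blob cannot be
  localized; the method inherits this from its flash-lit acquisition
  assumption.
- Blob size is the dominant classification feature, so the filter is not
  scale-invariant across camera distances.
- The greedy within-disk matcher is a choice, not a standard: it is
  verified against an exhaustive maximum-cardinality oracle on small
  configurations but other matching radii/criteria would shift metrics.
- X-means on heavily overlapping highlight-value distributions (high
  sensor noise) under-splits by design (ties keep fewer clusters), which
  lowers truss recall before it inflates precision.
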