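# Methods

## The problem

Adult *C. elegans* lifespan and lifetime motility can be partially predicted
from transmission-light micrographs taken on adult days 1–3, but a
convolutional classifier gives no account of *which* anatomy carries the
signal. The package implements a tandem procedure that produces such an
account: a multi-decoder segmentation network (HydraNet) splits the worm
into anterior, mid-body and posterior parts; a shallow classifier (WormNet)
predicts the lifespan or movement class; and the classifier's class
activation map (CAM), binarized at its upper quartile and intersected with
the predicted part masks, quantifies how much of the class evidence falls
into each body part. Group differences between the three per-part
percentages are tested with one-way ANOVA followed by Tukey's HSD.

Everything runs at a working resolution of 96 × 96 px covering a
580.5 μm × 580.5 μm field of view (≈ 6.05 μm/px).

## Networks

All networks are trained by backpropagation on a small numpy core written
for this package (`wormsight.nn`): 3×3 "same" convolutions via im2col + BLAS
GEMM (with numba-JIT im2col/col2im kernels), batch normalization, spatial
(channel-wise) dropout, 2×2 max pooling, 2×2 stride-2 transposed
convolutions, dense layers, and Adam. Analytic gradients are verified
against central finite differences in the test suite. Channels-last float32
throughout; large conv scratch buffers are reused across batches so training
fits comfortably in a few GB of RAM on one CPU core.

**U-Net.** Encoder of `depth` = 4 stages, each (conv–BN–ReLU)×2 followed by
max-pool + spatial dropout (rate 0.25), filter counts 16→32→64→128 with a
256-filter bottleneck; mirrored decoder from transposed convolutions whose
output is concatenated with the skip tensor of the matching encoder stage;
1×1 output convolution. Heads: 1-channel sigmoid (binary whole-worm) or
4-channel softmax over {background, anterior, mid, posterior}
(multi-class). The filter schedule and dropout rate are package defaults
chosen to be CPU-trainable at 96²; both are configurable.

**HydraNet.** The same encoder, shared, with one *independent full decoder
per head*, each ending in its own 1-channel sigmoid. HydraNet3 has heads
for the three parts; HydraNet4 adds a whole-worm head. The joint loss is
the unweighted sum of per-head Dice losses; since Adam is invariant to a
global gradient scale, the implementation averages over heads, which leaves
the update direction identical.

**Training (segmentation).** Dice loss, `1 − (2Σpt + ε)/(Σp + Σt + ε)` with
ε = 1e-6, computed per sample and channel over the spatial axes; Adam with
starting learning rate 0.001 and library-default moments; the Jaccard index
of the 0.5-thresholded predictions is monitored per epoch. Jaccard is
always computed on binarized maps (monitored-metric convention).

**WormNet.** Five blocks of (conv3×3 – BN – ReLU – max-pool 2×2 – spatial
dropout), default filters 16, 32, 64, 128, 256, then either flatten + a
64-unit ReLU dense layer + 2-way softmax (`flatten_fc`), or global average
pooling + a single dense softmax layer (`gap_cam`). The GAP head is the one
whose class weights make CAMs computable; the flatten head follows the
classifier description. Loss is categorical cross-entropy over the 2-way
softmax — identical to binary cross-entropy for two classes. Adam with
learning rate 0.005, β₁ 0.9, β₂ 0.999, ε 1e-8, decay 0. Optional early
stopping monitors validation loss and restores the best weights.

**Augmentation.** Per epoch each training image is drawn `fold` times
(default 30) under an independently sampled transform: horizontal/vertical
flip with probability ½ each, shifts uniform within ±10 % of each
dimension, rotation uniform within ±90°, applied in the fixed order
flip → shift → rotate with bilinear interpolation and nearest-edge fill.
Masks are not augmented (augmentation is used for classification only).

## Class definitions

* **Lifespan:** "short" iff lifespan < 8 adult days, else "long". The
  nominal definition is ≤ 7 vs ≥ 8 days; lifespans in (7, 8) are resolved
  by the single threshold at 8.
* **Movement:** "high" iff total lifetime crawled distance exceeds the
  arithmetic cohort mean; ties go to "low".
* Splits are made per worm identity (`split_by_worm_id`), never per image,
  so no worm contributes to both sides.
* Day-stratified modelling is supported by filtering the cohort to one
  adult day; the day is never an input feature.

## Interpretation pipeline

For each image the classifier's predicted class (true class optional)
selects the CAM: `M(x,y) = Σ_k w_k[class] · f_k(x,y)` over the final conv
feature maps entering the GAP layer, bilinearly upsampled to input
resolution, not normalized. Salient pixels are those ≥ the 75th percentile
of the map (linear-interpolation percentile over *all* image pixels; ties
kept; a constant map is degenerate → all-salient with a warning and the
image is excluded from the statistics as "flagged" only when no salient
pixel hits the worm). The quartile is taken over the full image rather than
worm-restricted because salient regions legitimately spill off the worm at
this resolution; a worm-restricted variant is a one-line change on the
caller side.

Percentages are normalized within the worm: the denominator is
|salient ∩ (anterior ∪ mid ∪ posterior)|, so the three percentages sum to
100. Pixels claimed by several (possibly overlapping) predicted part masks
go to the part with the highest soft probability, ties toward the more
anterior part. Images whose salient set misses the worm entirely are
flagged, reported, and excluded from the ANOVA.

The per-part percentages are sensitive to where the predicted masks place
the two internal boundaries: the salient CAM mass often concentrates near
a part boundary, so a 1–2 px systematic shift (or a confidence asymmetry
between adjacent heads in the contested band) can move a large share of
salient pixels between neighbouring parts. Against exact part definitions
a posterior-planted feature is attributed to the posterior cleanly; through
predicted masks the attribution stays in the posterior body half but the
mid/posterior split itself blurs. Interpret per-part percentages from predicted masks
as a coarse, statistically aggregated attribution, not a per-pixel one.

One-way ANOVA (F = MS_between/MS_within) and Tukey HSD adjusted p-values
(studentized-range tail of q = |Δmean| / √(MS_within/2 · (1/nᵢ + 1/nⱼ)))
are computed by the package and cross-checked in the tests against scipy's
`f_oneway` and statsmodels' `pairwise_tukeyhsd` to 1e-6. Each worm's part
percentage is treated as an independent observation (the repeated-measures
structure across parts of the same worm is deliberately ignored, matching
the stated analysis).

## Synthetic worms

The generator renders one worm per 96² image so that every downstream stage
is testable without any external data:

* **Midline:** cubic spline through 5 waypoints of a correlated random walk
  (heading increments σ = 0.55 rad), rescaled exactly to a target arc
  length drawn from 70–110 px (≈ 0.42–0.67 mm of visible, curled worm) and
  placed uniformly at random subject to an 8 px margin after dilation by
  the half-width. Coiled geometries (non-neighbouring midline points closer
  than 2.2 body half-widths) are rejected and resampled.
* **Body:** a tube of half-width `w_max · sin(πs)^q(s)` with
  `w_max` ∈ 4–5.5 px (body width ≈ 50–65 μm) and the taper exponent
  interpolating from 0.25 at the anterior (blunt head) to 0.9 at the
  posterior (long pointed tail). Two landmark structures are rendered: a
  darker pharynx-like corridor from arc fraction 0.04 to the anterior/mid
  boundary (contrast 0.12) and a bright vulva-like marker just before the
  mid/posterior boundary (contrast 0.18 over 0.035 of the arc), both
  spanning most of the body width. The
  asymmetric taper plus the pharynx make the worm orientable — without
  them anterior/posterior assignment is unidentifiable in principle — and
  aligning the landmarks with the part boundaries makes the boundaries
  locally visible, as they are for annotators of real micrographs who
  follow anatomy. The parts themselves remain defined by arc-length
  fractions.
* **Appearance:** background = mean (0.60–0.75) + smooth field (σ = 8 px,
  amplitude 0.05) + granular noise (0.03); body intensity 0.25–0.40 with
  radial shading (amplitude 0.12, darkest at the midline) and per-part
  Gaussian-filtered texture with amplitude 0.04–0.08 and a distinct
  spatial frequency per part (anterior 0.22, mid 0.12, posterior
  0.17 cycles/px) — body parts of real worms differ in interior texture
  (pharynx vs gonad/intestine vs eggs), and this is what makes part
  identity locally readable for annotators and networks alike. The worm
  is darker than the background, as in transmission light.
* **Parts:** each pixel takes the arc-length fraction of its nearest
  midline point; parts split at cumulative fractions (⅓, ⅓, ⅓) by default
  (the real annotation convention is unknown; equal thirds is the simplest
  reproducible choice), ties toward the more anterior part. Anterior ∪ mid
  ∪ posterior equals the whole mask exactly, by construction.
* **Planted class feature:** positive-class worms get the texture amplitude
  of one chosen part increased by `effect_size` (default 0.3); negative
  class and all other parts are untouched. Labels are balanced exactly
   50/50 and coupled to the metadata (positive ⇒ short-lived, or ⇒
  above-mean distance) so the lifespan/movement label derivations recover
  them.
* **Metadata:** lifespan ~ U(3, 14) adult days (class-conditional
  U(3, 7.4) / U(8, 14) when coupled), lifetime distance ~ U(20, 300)
  (arbitrary units), adult day ∈ {1, 2, 3}. All randomness derives from a
  single master seed through a seed sequence; a rerun is byte-identical.

What the generator does *not* emulate: multiple worms or debris in the
field, postural self-overlap, day-to-day appearance drift of the same worm,
optical vignetting, and any genuine biological link between morphology and
lifespan — the planted texture is a stand-in with a known location.
Passing tests therefore demonstrate that the pipeline recovers a
part-localized signal when one exists and reports chance when none does;
they do not certify real-data accuracy.

## Benchmark scales and observed behaviour

The segmentation benchmark uses 130 worms split 90/40 by worm identity —
the annotated-dataset scale. The binary U-Net trains for 12–15 epochs; the
HydraNet4 / multi-class U-Net pair trains for 22–30 epochs with a step
decay of the learning rate (3e-4, then 1e-4) applied after the constant-lr
Jaccard plateau. These are the problem sizes used by
`scripts/acceptance.py` and the acceptance tests, chosen at the plateau of
the validation curves. On this benchmark the whole-worm U-Net reaches a
held-out Jaccard of ~0.99; HydraNet4 averages ~0.94–0.95 across its four
heads (whole ~1.0, parts 0.90–0.95, limited by 1–2 px bands at the two
internal part boundaries and thin tail tips of the pixel-exact geometric
ground truth), and consistently outscores the multi-class U-Net (~0.91) at
a matched budget. Classifier experiments use 100 + 100 planted worms
(effect 0.3, split 0.3 by worm) trained for ~25 epochs at batch 16. The
~25 % upper-quartile and metric-oracle properties are exact-scale, not
scaled down.

## Numerical and degenerate-input choices

* Dice smoothing ε = 1e-6; both-empty masks have Jaccard 1 by convention.
* Binarization threshold 0.5 everywhere unless stated.
* Percentile: numpy's linear-interpolation quantile; `>=` keeps ties.
* Batch norm: momentum 0.9, ε = 1e-5; evaluation uses running statistics.
* He-normal initialization; per-model seeded generators make training
  deterministic on one CPU (numba kernels and BLAS reductions are
  order-stable for fixed shapes).
* Zero-dynamic-range images are rejected at load; empty split sides, single
  class cohorts, undersized ANOVA groups raise explicit errors.
* `ClfMetrics.roc_auc` is None (undefined) on one-class evaluation sets;
  other metrics are still reported.

## Known limitations

* The numpy core targets 96² inputs on one CPU; the optional 800²
  preprocessing path (center-crop + background masking) is provided for
  data preparation, not for training at that resolution.
* CAMs live on the 3 × 3 final feature grid before upsampling, so
  localization is coarse — the same resolution limit the tandem procedure
  has at 96², and the reason its part attribution is statistical rather
  than per-image.
* Tukey HSD assumes equal variances; with strongly unbalanced flagged
  counts per class the comparison inherits the usual caveats.
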