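# Methods

`sproutquant` quantifies sprouting angiogenesis from single-plane
fluorescence images of endothelial (typically HUVEC) spheroids embedded in
a gel. Each input image contains one spheroid: a bright, dye-dense body
from which dimmer, curvilinear sprouts radiate. The pipeline reduces such
an image to one record of morphometric parameters: total spheroid area,
sprouting area, numbers of attached and migrated sprouts, and the
cumulative sprout length (CSL).

## Segmentation model

The method is contrast-based, not intensity-based: it assumes the spheroid
and its sprouts are locally brighter than the gel background, but makes no
assumption about absolute brightness (fluorescence fades with time and
cell division). The total spheroid area is segmented from *edges*:

1. **Median filter** (`noise_median_kernel`, default 1 × 1 = identity).
   Kept for acquisitions with impulse noise; stitched and downsampled
   plate-reader images are usually already smooth.
2. **Contrast-limited adaptive histogram equalization** (8 × 8 tiles,
   clip 0.01) raises dim sprouts toward the dynamic range of the body.
3. **Sobel edge detection**, binarized at `sensitivity × RMS(gradient)`.
   The RMS normalization makes the mask invariant to global intensity
   scaling. Default sensitivity 3: real structures produce contiguous
   gradient ridges well above the RMS, while amplified background noise
   sits near it; at sensitivity 1 essentially every noise grain passes.
4. **Gaussian spreading**: the binary edge mask is convolved with a
   unit-sum Gaussian kernel (support 100 × 100 px, σ = 3 px). Each sprout
   contributes a pair of parallel edges ~3 px apart; the blur fuses the
   pair into one solid ridge and closes the body's edge ring into a filled
   region. σ is the critical scale: it must exceed the sprout half-width
   (else sprouts stay hollow) and stay below half the typical gap between
   adjacent sprouts (at σ ≳ 10 px, sprouts 30–50 px apart merge into a
   single webbed blob whose skeleton no longer follows individual
   sprouts). σ = 3 was calibrated on synthetic ground truth; the kernel
   support is deliberately generous and does not affect the result.
5. **Adaptive threshold** at `median + 0.3 × SD` of the *nonzero* pixels
   of the convolved image (sample SD, N−1). Restricting the statistics to
   nonzero pixels removes the dependence on how much empty background the
   crop contains. The comparison is strict (>), so a degenerate flat
   plateau yields an empty mask rather than keeping everything.
6. **Hole filling** (the body is solid tissue; the area metric is a region
   area). An optional largest-component filter exists for crops that catch
   fragments of neighboring spheroids at their borders, but it is off by
   default: detached (migrated) sprout fragments are separate components
   by definition and must survive segmentation.

The **spheroid center** (the body) is found independently on the raw
image: median-smooth with an 11 × 11 kernel, keep pixels ≥ 90 % of the
smoothed maximum, take the largest connected region, dilate with a 5 px
disk to cover the body's dim rim, and intersect with the total mask. The
**sprouting area** is the set difference total ∖ center; the three masks
satisfy |total| = |center| + |sprout area| by construction, and the
pipeline asserts it.

## Skeleton model

Sprout counts and CSL come from a one-pixel-wide skeleton:

1. The total mask is thinned (`skimage.morphology.skeletonize`); with the
   default minimum branch length of 1 every branch is kept.
2. The center is subtracted from the skeleton, removing "sprout
   extensions" inside the body and cutting each attached sprout free at
   the body boundary.
3. The fragments are **refined**. The classical formulation dilates with
   a diamond (L1-ball) of radius 2 and re-thins, which reconnects
   everything whose dilations meet — gaps up to 4 px — but re-thinning a
   dilated tube also retracts its free ends by about the radius on *every*
   application, so the classical operator erodes sprout tips and is not
   idempotent. This implementation produces the identical connectivity
   directly: minimal straight bridges are drawn between components whose
   L1 distance a radius-2 diamond dilation would merge, a diamond closing
   at the same scale fuses parallel strands, thinning restores one-pixel
   width, and side branches shorter than 10 px (`refine_prune_px`) are
   pruned. On its own output every step is the identity, so refinement is
   idempotent as a pixel set, and free sprout ends stay where segmentation
   put them. Spur pruning itself identifies branch points by the crossing
   number (number of connected neighbor groups in the 8-ring), not the
   plain neighbor count, which misfires when a spur tip rests against a
   straight run; where several short spurs meet at one junction only the
   shortest is removed per pass, since deleting it may make a sibling the
   main line's continuation.
4. Connected components (8-connectivity, the convention throughout) with
   fewer than 6 pixels are discarded as noise; components of exactly 6
   pixels are kept.
5. Each surviving component is one **sprout**. A component within
   `attach_tolerance_px` (5 px) of the center mask is **attached**,
   otherwise **migrated**. The tolerance is not free: refinement leaves
   cut ends up to `diamond_radius` short of the cut, and segmentation
   erodes another pixel or two where the sprout neck meets the much
   brighter body, so genuinely attached sprouts end 2–4 px from the
   center mask. Genuinely migrated fragments lie tens of pixels away, so
   the two classes cannot be confused at this tolerance. With only one
   focal plane, "migrated" means *disconnected on this plane*; a fragment
   may be attached on another Z level, which single-plane imaging cannot
   resolve (maximum-intensity projections are not used because the body's
   halo would bridge everything).
6. **CSL** is the pixel count of the final skeleton — a digital length,
   not a Euclidean path length — converted to µm via the pixel size
   (default 2 µm/px).

### Known biases

* **Sprout undercounting.** A sprout that bifurcates is one connected
  component and is counted once. This reproduces the method's documented
  behavior (component counting, not branch counting); a fixture test pins
  it. Relative comparisons between conditions are unaffected.
* **CSL underestimate.** The final skeleton starts at the dilated center
  boundary (~5 px outside the body) rather than at the body edge, and
  skeleton chains are minimal 8-connected digitizations. On synthetic
  ground truth the measured CSL runs ~5–8 % below the rendered centerline
  length, consistently across images — again immaterial for relative
  comparisons.

## Synthetic data generator

The generator renders the phenotype the assay produces, with exact ground
truth: a filled core disk (default radius 40 px = 80 µm at 2 µm/px,
intensity 1.0); `n_attached` sprout centerlines launched from the core
boundary at evenly spaced, jittered angles (minimum pairwise separation
360°/2n), each a bounded-curvature random walk (±0.08 rad/px drift,
clamped to ±0.3 rad of the launch direction so sprouts stay inside their
angular sectors), dilated to 3 px width at intensity 0.5; optionally
`n_detached` fragments of 20–50 px placed ≥ 30 px outside the core;
additive Gaussian noise (σ = 0.03) clipped to [0, 1]. Default sprout
lengths are 60–150 px (120–300 µm), typical of a 24 h sprouting assay at
this scale.

Two rendering details are essential for honest validation:

* **Centerlines are minimal 8-connected chains** (Bresenham segments
  through waypoints every 4 px). Rasterizing each unit step separately
  adds ~10 % extra pixels through rounding zig-zag, which would inflate
  the "true" length relative to anything a thinned skeleton can contain
  and make the length comparison meaningless.
* **Detached fragments are placed by rejection sampling with ≥ 20 px
  clearance** from every already-rendered structure. The ground truth
  records *m distinct fragments*; a render in which a fragment touches an
  attached sprout would make that truth false in the image itself.

What the generator does **not** emulate: the body's fluorescence halo,
out-of-focus light from other Z planes, uneven illumination, gel texture,
sprout intensity tapering toward the tip, and crossing sprouts.
Consequently, passing the recovery tests shows the algorithm correctly
measures well-separated sprout geometry under moderate noise — it does not
show robustness to projection artifacts or densely overlapping sprouts,
which real images can contain.

## Parameter calibration

All constants stated by the processing chain's published description
(median 1 × 1; Gaussian kernel width 100; threshold coefficient 0.3;
center smoothing 10 × 10, implemented as the nearest odd 11 × 11; diamond
radius 2; component threshold 6; minimum branch length 1; 2 µm/px) are
defaults here. Parameters that description leaves open — Gaussian σ,
Sobel sensitivity, center brightness fraction and dilation radius, prune
length, attachment tolerance — were fixed by measuring ground-truth
recovery (attached-count exactness, migrated-increment exactness, CSL
error) on seeded synthetic images and choosing values with wide flat
optima; they are not per-dataset fits, and all remain configurable for
other acquisitions.

## Numerical and convention choices

* Intensities are normalized by the **dtype maximum** (255 / 65535), not
  the per-image maximum, so thresholds are comparable across images of
  one acquisition. Float inputs must already be in [0, 1].
* Median filtering replicates edges; convolution zero-pads; CLAHE
  operates on the image clipped to [0, 1]. A perfectly flat image is its
  own equalization.
* Z-stacks: exactly one configured plane is analyzed (default the first);
  never a projection.
* Ties and degenerate inputs: an all-zero image yields threshold 0, empty
  masks, zeroed metrics and a warning; a sprout-free spheroid yields its
  body area with zero sprout metrics and a warning. Batch analysis never
  aborts on a single bad file — it logs the error, reports it in the exit
  status, and continues.
* Determinism: every stage is deterministic; the generator is fully
  determined by its spec (including seed). Batch CSV rows are sorted by
  `image_id`, so results are independent of filesystem enumeration order
  and repeat runs are byte-identical.

## Validation problem sizes

The shipped tests and the acceptance script use 512 × 512 px images, 20
images per recovery experiment (3–8 attached sprouts each, 1–3 detached
fragments in the migrated experiments), and 100 random 32 × 32 rasters
for the threshold oracle — sizes at which every statistic stabilizes
while the whole suite runs in well under a typical CI budget.
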