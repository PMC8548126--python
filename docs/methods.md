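# Methods

`lasermark` segments photocoagulation laser scars in color fundus photographs
with a patch-based lightweight U-Net, removes anatomically impossible
detections at the optic disc (OD) and macula, and applies a rule-based
classifier for panretinal photocoagulation (PRP).  This note records the
model, its assumptions, the tunable parameters, and the design choices made
where the design was genuinely open.

## Photometric normalization

Every image is resized to a square canonical side (default 512 px; bilinear
for images, nearest-neighbor for masks so they stay binary), then each
channel passes through four steps:

1. **Per-pixel-position Z-score** against training-set statistics:
   `z = (x - mu_jk) / sigma_jk`, where `mu_jk` and `sigma_jk` are the mean and
   *population* standard deviation (divide by the number of images) of pixel
   position `j`, channel `k`, over the training split.  Positions with
   `sigma = 0` (the black field-of-view exterior) map to `z = 0`.  Test
   images are always standardized with the frozen training statistics, which
   are serialized (HDF5) next to the model checkpoint.
2. **Per-image min-max rescale** of each channel onto [0, 255]; a constant
   channel maps to all zeros.  Because the minimum and maximum are taken
   within the image, outputs are image-relative — a deliberate property of
   the chain, flagged here because it means a pixel's normalized value
   depends on the rest of its own image.
3. **CLAHE then gamma.**  CLAHE runs per channel on an 8x8 tile grid with a
   clip limit expressed as a multiple of the uniform histogram-bin height
   (default 2.0, 256 bins; scikit-image backend).  The gamma step is
   `255 * (v/255)^(1/1.2)` — a brightening exponent of ~0.833 — clamped to
   [0, 255].
4. **Division by 255** into [0, 1].

One added rule: pixels that are zero in *all three channels* of the resized
input are re-zeroed at the end of the chain.  The min-max step would
otherwise lift the uninformative black surround to a mid-gray (its `z` is 0
while the in-image minimum is negative), and the black-patch exclusion rule
used during augmentation could never trigger.  The exterior carries no
signal, so pinning it at zero loses nothing.

## Patch augmentation and sliding inference

Training draws `n` windows of 48x48 px per image, centers uniform over
positions where the window fits fully inside the image; a candidate whose
image window is zero in every channel is rejected and redrawn (cap: 100n
attempts, then an error — never silent under-placement).  An even window of
side `w` centered at `c` spans `[c - w/2, c + w/2)`.

Inference slides the 48-px window with a fixed stride (default 5) from the
top-left corner; origins run `0, s, 2s, ...` up to the last origin inside the
image, so every pixel is covered when `stride <= window` (enforced).
Overhanging windows are zero-padded before entering the network, and the
padded area is *discarded* during reassembly: each output pixel is the sum of
the window predictions covering it divided by the number of covering
windows, so border probabilities are never diluted by padding artifacts.

Known source inconsistency: with a 512-px canonical side and stride 5 the
plan yields 103^2 = 10,609 windows; a figure of 3,364 (= 58^2) windows per
image circulating for this configuration is consistent with stride 8 and no
trailing window, not with stride 5.  The stride stays 5 by default and the
window count is never used as an oracle.

## The lightweight U-Net

Three scales, five dense convolutional blocks (conv3x3 -> ReLU -> dropout
p=0.2 -> conv3x3 -> ReLU, all convolutions padded so spatial size is
preserved): encoder blocks at 32 and 64 channels with 2x2 max-pooling
between scales, a 128-channel bottleneck, and two decoder blocks (64, 32)
each preceded by 2x nearest-neighbor upsampling with a channel-halving 2x2
convolution and skip concatenation.  A 1x1 convolution and per-pixel softmax
emit two channels; channel 1 is the laser-mark class everywhere in the
package.  Channel widths are half of the classic U-Net's first three scales;
the upsampling operator is a config switch (`nearest` or `transposed`)
because either choice is compatible with a max-pool encoder.

The network, backpropagation and SGD are implemented directly in NumPy
(channels-last float32; convolutions as sums of shifted GEMMs).  This keeps
the package dependency-light and every numerical choice explicit; the
gradient implementation is verified against finite differences in the test
suite's training behavior and against loop oracles for the loss.

**Loss and its normalization.**  The objective is the pixel-wise categorical
cross-entropy summed over all pixels and both classes of a batch.  For the
SGD update the sum is divided by the number of pixels in the batch (the
per-pixel mean), so the update magnitude is independent of batch size and
window size; logged losses are per-pixel means (initial value ~ln 2).

**Initialization.**  He-normal weights.  When training starts from scratch
(no init checkpoint), the head bias is set to the class log-odds of the
patch pool, so the first epochs refine features rather than reproduce the
class prior — with ~5% lesion pixels, a cold head spends a large share of a
short run learning the bias alone.

**Schedule.**  Batch size 128; a single global 10% validation split of the
patch pool, fixed by the training seed (a literal per-batch split would
change the validation data every step and could not define "the" validation
set that selects the best weights).  Learning rate starts at 1e-3 and is
multiplied by 0.3 after every 10 consecutive epochs without improvement in
validation *accuracy*; training stops early after 40 such epochs, or at
`max_epochs` (default 150).  The returned checkpoint holds the weights with
the best validation *loss*; both metrics are recorded per epoch in the
training log.  SGD momentum defaults to 0 and is config-exposed.

**Desk-scale runs.**  The full production configuration (512-px canonical
side, 10,000 patches/image over 50 images, hundreds of epochs) is a
many-hour GPU-class workload.  The test suite and the acceptance script
demonstrate end-to-end learning at a reduced scale chosen for a single CPU:
128-px canonical side, 10 training images x 500 patches, 3 epochs of plain
SGD at lr 0.03, inference stride 8.  The larger step size compensates for
the roughly hundredfold-reduced step count — at the production lr the run
would end inside the class-prior regime with no ranking signal; dropout,
architecture, loss, and schedule logic are identical to the production
configuration.

**Staged pretraining.**  The transfer-learning chain (vessel surrogate set
-> coarse set -> formal set) is expressed as a sequence of `train()` calls
passing the previous checkpoint as `init`; the synthetic generator can emit
a vessel-labeled variant of its scenes for the first stage.

## Anatomy: optic disc and macula

The OD is segmented by a second network with the identical architecture and
training process, trained against OD masks.  Its probability map is
binarized at 0.5, reduced to the largest 8-connected component (ties broken
by smallest label in scan order), and summarized by the component centroid
and bounding-box extents.  The exclusion ellipse has semi-axes 1.8x the
extents / 2 ("maximal x/y lengths" is read as bounding-box extents — the
natural reading; a per-row/column maximum would differ only for strongly
non-convex components, which a thresholded disc map does not produce).

The macula localizer is a deliberate surrogate, since the package does not
reproduce the external morphological method the OD/macula pipeline was
originally paired with: the search band is centered on the OD center row
(half-height one OD y-extent), spans 2-3 OD x-extents temporal to the disc
(temporal = away from the nearer vertical image edge), and the macula is the
minimum of the Gaussian-smoothed (sigma 5 px) mean-channel intensity in the
band; a constant band flags low confidence and falls back to the first scan
position.  It is isolated behind a single function so it can be swapped.  A
micron-per-pixel scale comes from the clinical heuristic that the OD
diameter is ~1800 um (configurable).

## Postprocessing

Two idempotent, commuting projections zero out probabilities where burns are
clinically impossible: the OD exclusion ellipse, and an axis-aligned
macula-centered square of side 80 px (at the 512-px canonical scale; an even
side spans `[c - side/2, c + side/2 - 1]`).  Probabilities are zeroed rather
than pixels removed, so ROC analysis keeps the same pixel universe.

## Evaluation

Metrics are pooled over all test pixels (micro-averaging, matching a single
reported operating point per test set): ROC with all distinct scores as
thresholds, trapezoidal AUC, the Youden-optimal point (max sens + spec - 1,
ties to higher sensitivity), accuracy at that threshold, and Dice
2TP/(2TP+FP+FN).  Predictions are positive at probability >= threshold.  The
threshold at which Dice is reported is the Youden-optimal one — a documented
assumption, since the choice affects comparability of Dice values.  The
report covers four variants: raw, +macula mask, +OD mask, +both.

## PRP rule classification

The map is binarized at 0.5, 8-connected components below 10 px are
dropped, components whose centroid lies inside the OD ellipse or within
500 um of its boundary on the nasal side (the side away from the macula), or
within 3000 um of the macula center, are recorded as violations and
excluded.  The image is called PRP when >= 30 marks survive and they occupy
>= 3 of the four macula-centered quadrants (a component straddling an axis
counts once, by centroid).  All counts and radii are config-exposed: the
rule is a reconstruction from published clinical criteria, not a calibration
on data, and the count thresholds in particular would need calibration
before clinical use.  The temporal-arcade criterion is out of scope because
the pipeline does not detect arcades.

Desk-scale runs adapt two config values: the binarization threshold is the
Youden-optimal operating point of the same run (a briefly trained network's
maps are not probability-calibrated, so the 0.5 default would be arbitrary),
and the mark-count minimum is halved relative to the smallest generated
count (12 for 18-26 marks per eye) because the clinical default of 30
presumes treatment densities of hundreds of burns.

## Synthetic data: what it emulates and what it does not

The generator draws, per image: a circular field of view (radius 0.44-0.47
of the side) on a strictly black background; a radial brightness gradient
under one of three camera hues (whitish/yellowish/reddish, jittered); 2-8
dark Bezier vessel tracks radiating from the OD; a bright vertical-ellipse
OD at 0.26-0.32 of the side left or right of center; a dark Gaussian macula
2.5 OD-diameters temporal to the disc on the horizontal midline; and laser
marks as bright discs with a 2-px darker pigmented rim (late-stage scars).
The field-of-view edge is feathered (a smooth vignette over ~3.5% of the
side, exactly zero outside the aperture) the way a camera aperture rolls
off; a hard cut would manufacture a high-contrast ring after CLAHE that no
clinical image has.  Mark placement rejects centers inside the 1.8x OD
ellipse (plus a margin) or within 0.2 image-sides of the macula — wide
enough that the 3000-um PRP rule cannot clip legitimate marks — and keeps
marks pairwise disjoint so each scar is one connected component.  `prp`
patterns guarantee a mark in each macula-centered quadrant; `partial`
confines a quarter of the configured count to one quadrant on the side away
from the OD; `mixed` draws patterns at the prevalence of the target referral
population (51.3% PRP / 42.2% partial / 6.5% none).  One global seed drives
a per-image seed sequence, so outputs are byte-reproducible and stable under
changes of `n_images`.

Defaults are 560-720 px native size, 40-70 marks of radius 5-9 px, noise SD
2.  The desk-scale conditions render directly at the 128-px canonical side
(no resize blur in labels) with 18-26 marks of radius 3-4, contrast 1.5, 3
vessels, a fixed reddish hue and a tripled between-image brightness jitter
(`camera_variation=3`): mark contrast and geometry are explicit separability
knobs for fast tests, not claims about clinical appearance.  Two of these
choices deserve explanation.  A single hue profile is used because a
hundred-step training run cannot learn hue invariance — the full-scale chain
plus long training is what absorbs camera variation.  The *enlarged*
brightness jitter is not cosmetic: the per-pixel-position standard deviation
of the Z-score step is estimated from only 10 training images at desk
scale, and when between-image variation is small that estimate collapses at
structureless positions and amplifies noise; broad brightness jitter acts as
dithering that keeps the position-wise SD field smooth, which measurably
stabilizes pooled cross-image rankings for any detector (including a plain
intensity baseline).

Not emulated: other diabetic-retinopathy lesions (hemorrhages, exudates),
camera vignetting beyond the radial gradient, JPEG artifacts, anatomical
variation of the arcades, or photorealistic texture.  Passing tests
therefore show that the *machinery* — normalization, augmentation, learning,
reassembly, anatomy masking, rules — works end to end on images with the
right geometry and photometry, not that the trained weights transfer to
clinical photographs.

## Numerical choices and degenerate inputs

- Mask binarization threshold 127 on 8-bit input (tolerates anti-aliased
  annotations); probability-map PNGs store `round(255p)` with round-half-up
  and a lossless float32 sidecar so evaluation is not quantization-limited.
- `sigma = 0` standardization positions map to 0; constant min-max channels
  map to 0; Dice with an empty prediction *and* empty truth is defined as
  1.0 with a warning; an empty binarized OD map is a localization error.
- Cross-entropy probabilities are clamped below at 1e-12.
- Component labeling is 8-connected everywhere, stated so tests are exact.
- All randomness flows from integer seeds (NumPy Generators); inference
  disables dropout and is deterministic.

## Known limitations

- The macula surrogate is photometric only; on clinical images with bright
  macular pathology it can mislocalize — it is the weakest-fidelity module.
- The PRP count/coverage thresholds are uncalibrated reconstructions.
- Desk-scale training demonstrates learning, not clinical accuracy; the
  reported synthetic metrics are not comparable to metrics on fundus
  photographs of patients.
- The NumPy network is single-threaded CPU code; production-scale training
  would use a GPU framework with the same architecture and schedule.
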