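# Methods

This note documents the models, conventions and numerical choices behind
`halluxmetry`, and what the synthetic test bed does and does not establish.

## Angle conventions

Pixel coordinates are (x, y) with y growing downward; every angle is
computed after flipping to a y-up frame, so positive angles are
counterclockwise rotations as the radiograph is displayed, measured from
the right-facing horizontal. Axes are directed proximal→distal. The
direction convention is a package choice (only the undirected axis is
observable in a heatmap): with toes at the top of a dorsoplantar view it
puts every bone axis near +90°, so HVA = PH1a − MT1a and IMA = MT2a − MT1a
are small signed differences. All angles are wrapped to (−180°, 180°], with
ties at ±180° resolved to +180°.

Signed HVA/IMA depend on foot side (mirror images negate them);
`normalize_side` reflects left-foot angles (θ → 180° − θ) onto the
right-foot convention. Clinical reporting uses the magnitudes; the sign
that corresponds to valgus on each side is a convention of the phantom
generator, not a clinical claim.

## Heatmap encoding

Per bone: rasterize the axis segment with an 8-connected 1-px line, dilate
with a radius-2 disk to a 5-px cross-section, blur with an isotropic
Gaussian (zero-padded boundaries, kernel truncated at 4σ), and renormalize
the channel peak to 1.

* σ = h/(2.5·L) for PH1 and σ = h/L for MT1–MT5, with h the image height
  and L the segment length in pixels. `h/2.5L` is read as h/(2.5·L); the
  alternative reading (h/2.5)·L gives kernel widths of thousands of pixels.
* Peak renormalization after blurring makes the regression target's scale
  independent of bone length; whether to renormalize at all was an open
  choice, made so that RMSE weights all bones comparably.
* Channels are built independently and may overlap — that is the point of
  axis heatmaps versus exclusive segmentation labels.

## Preprocessing and augmentation

Images are padded to square with black (split evenly, odd pixel to the
trailing side), resized to 512×512 (bilinear, anti-aliased when shrinking),
and min–max rescaled to [0, 1] per image (a constant image maps to zeros).
Annotations ride through the identical affine transform, so inclination
angles are preserved exactly by the similarity transform.

Augmentation makes up to 6 copies per image: horizontal flip with
probability 1/2 (which toggles the recorded foot side), then rotation by a
uniform angle in [−15°, +15°] about the image center (bilinear resampling,
black fill, exact affine for endpoints). All transforms are logged per
sample and reproducible from the generator seed.

`split_dataset` partitions by largest-remainder rounding of n·(0.70, 0.20,
0.10) after a seeded shuffle; remainders are rounded to 9 decimals and ties
go to the earlier group so the split is platform-independent.

## Network and training

The regression network is an encoder–decoder with skip connections:
`n_levels` = 5 resolution levels, filter counts doubling from
`base_filters`, 3×3 stride-1 convolutions each followed by per-channel
instance normalization (learnable scale/shift) and ReLU, 2×2 max pooling,
nearest-neighbour upsampling, and a 1×1 sigmoid head bounding the 6-channel
output to [0, 1]. It is implemented directly in numpy (im2col convolutions
over BLAS, manual backpropagation verified against central differences,
Adam). Internal block composition is not dictated by the method; the
default is two convolutions per block, and the desk-scale preset uses one.

Two initialization/conditioning choices matter a great deal on these
sparse targets. First, the sigmoid head's bias starts at −2: targets are
mostly background, and a zero-bias start drives the head into deep
saturation ("predict zero everywhere") where gradients vanish. Second,
the instance normalization is what keeps that saturation from recurring
during training — without it, trunk feature magnitudes grow with depth,
so even tiny optimizer steps on the head weights swing its
pre-activations by several units; the quickest descent direction is then
the all-zero prediction, a plateau (loss exactly equal to the target RMS)
from which sigmoid gradients cannot recover. With normalization the same
protocol converges reliably across seeds.

The training protocol follows the fixed full-scale hyperparameters: Adam,
minibatch 7, at most 12 epochs, initial learning rate 1e-4, validation
every 200 iterations, early stopping after 10 consecutive non-improving
validations, best-validation weights restored. "Patience 10" is read as
consecutive non-improving validation evaluations.

### Desk-scale preset

The tests train at 128×128 with 200 phantoms, `base_filters` 8 and one
convolution per block for 8 epochs — under 250 minibatches, two orders of
magnitude fewer than a clinical-scale run. At learning rate 1e-4 (and
still at 1e-3) the thin network is far from convergence when the epoch cap
ends, so the preset raises the rate to 3e-3 (1e-2 is unstable) and
validates every 50 iterations. These problem sizes were chosen so a
complete training run finishes in minutes on a single CPU core while still
reaching held-out HVA errors well inside the 3° acceptability margin.

## Axis extraction

The "high-value area" of a channel is the set of pixels ≥ τ·max (τ = 0.5 by
default, minimum 20 pixels). Its value-weighted second-moment matrix gives
the total-least-squares line through the area; the principal eigenvector's
angle (undirected, in [0°, 180°)) is the axis inclination. TLS rather than
y-on-x regression because metatarsals are near-vertical in dorsoplantar
view, where y-on-x is ill-conditioned; the principal-axis fit is
rotation-invariant and provably minimizes weighted perpendicular scatter
(asserted against an exhaustive 0.05° grid search in the tests).

Failure modes are per-bone and non-fatal to the other channels: too few
supra-threshold pixels → insufficient signal; major/minor eigenvalue ratio
below 1.05 → no principal direction (e.g. an isotropic blob). The
180°-ambiguity of the undirected axes is resolved in two steps: MT1 is
oriented toward the toe side of the image (the PH1 channel centroid
relative to the metatarsal centroids, falling back to image-up), and every
other bone then takes the 180° representative nearest MT1's direction.
The relative rule is robust: forefoot axes never diverge more than 90°
from MT1, and an (unlikely) global flip of MT1 shifts all inclinations by
180° together, which cancels exactly in the HVA/IMA differences.

## Phantoms and simulated raters

A phantom is a dark canvas (background 0.10) with six bright (0.85)
capsule-shaped bones whose midlines are the ground-truth axes, soft-edged
over ~2 px, plus additive Gaussian intensity noise (default SD 0.03) and
clipping to [0, 1]. Capsules were chosen because they have an unambiguous
midline. The construction is driven by the target angles — MT1 at its base
angle, MT2 at base + IMA, PH1 at base + HVA placed end-to-end with MT1
across a simulated metatarsophalangeal gap, MT3–MT5 fanned laterally — so
`derive_angles` on the ground truth reproduces the requested HVA/IMA to
machine precision. The `overlap_factor` crowds the metatarsal bases to
force partial bone overlap, the failure mode that motivates axis heatmaps.
Random specifications draw angle magnitudes from a clinic-like spread
(HVA ~ N(30°, 14.6°), IMA ~ N(14.3°, 4.3°), clipped) with random side and
crowding.

Simulated raters jitter both endpoints of every segment with isotropic
Gaussian noise and rotate each segment about its midpoint by a Gaussian
angle (defaults 2 px at a 512 canvas and 1.5°), giving zero-mean angle
errors; the end-to-end pipeline scales the endpoint noise with canvas size
so the implied angle spread does not depend on resolution (a fixed 2-px
jitter on an 18-px phalanx at 128² would imply >15° of inter-rater spread).

What the phantoms do **not** emulate: cortical/trabecular texture, soft
tissue, sesamoids, joint-space anatomy, exposure variation, or the
contour distortions of erosive disease (beyond simple overlap). Passing
the synthetic end-to-end tests therefore demonstrates that the pipeline's
machinery — encoding, regression, extraction, statistics — is correct and
self-consistent, not that the trained network reaches clinical accuracy on
real radiographs.

## Statistics

* MAE is computed against the per-parameter median of the three raters;
  the one-sample t-test is one-tailed with H1: mean AE < 3°, and the
  reported CI bound is the one-sided 95% upper confidence limit of the
  mean (consistent with the test; the sidedness was an open choice).
  Zero-variance error vectors yield p = 0 (mean below the bound) or 1.
* Error bands use [0, 3), [3, 5], (5, ∞) — the verbal "less than 3°,
  between 3° and 5°, exceeding 5°" leaves endpoints open; this convention
  is documented and tested.
* Diff_12/Diff_23/Diff_31 are per-case pairwise absolute differences;
  Diff_123 is their per-case mean. MAE vs Diff_123 is a two-tailed paired
  t-test on per-case differences. Diff_123 dispersion is reported both
  across cases and across the three case-averaged pairs (the latter matches
  the very small SDs typical of published agreement tables); both columns
  are emitted.
* `required_sample_size` iterates the noncentral-t power of the one-sided
  test over n. α is taken as one-sided 0.05 (the conventional global
  significance level); with a true mean of 1.5°, SD 3.58°, margin 3° and
  power 0.99 the smallest adequate n is 92.

## Degenerate inputs and numerical choices

* Zero-length segments are rejected at construction; L = 0 cannot reach the
  σ formulas.
* Gaussian blur: `scipy.ndimage.gaussian_filter`, zero padding, truncation
  at 4σ (the truncation radius is not dictated by the method).
* Heatmap serialization is a compressed `.npz` with an explicit channel
  order; round trips are bit-exact. Checkpoints store weights plus the
  architecture config and its hash; the loader rejects mismatches.
* Angles in CSV outputs are rounded to 2 decimals; internal computation is
  double precision throughout.

## Known limitations

* The numpy backend is single-core and makes clinical-scale training
  (512×512, thousands of augmented radiographs) impractical; the package
  demonstrates the method at phantom scale and the full-scale protocol is
  retained as configuration defaults.
* The exact thresholding/regression variant used in the original
  supplementary algorithm for "high-value areas" is not public; the TLS
  fit here is a documented stand-in shown equivalent to an exhaustive
  scatter-minimization oracle, not a re-implementation of that supplement.
* Only three-rater agreement statistics are implemented (no ICC/kappa, no
  Bland–Altman, no >3-rater generalization).
* Postoperative axis definitions (metatarsal-head reference points) and
  DICOM ingestion are out of scope.
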