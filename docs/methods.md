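# Methods

This note records the models, conventions and numerical choices behind
`facequant`, in the order the pipeline uses them.

## Synthetic face model

The generator is a parametric template, not a photo-realistic face
model: downstream geometry and statistics depend only on the landmark
coordinates and on regional intensity structure, so realism buys
nothing for testing while costing reproducibility. Each face is drawn
as a bright ellipse (head) on a dark background with darker eye, nose
and mouth primitives placed at the landmark positions.

Landmarks follow the canonical 68-point annotation (jaw 0–16, brows
17–26, nose 27–35, eyes 36–47, mouth 48–67). Per face, the template is
perturbed by a small similarity transform (±3 % scale, ±2° rotation,
±1 % translation) plus i.i.d. per-point Gaussian jitter with standard
deviation 1 % of the image side — enough that no two faces or their
region partitions are identical.

The class signal is a **constant intensity elevation** of height
`effect_amplitude` added inside the effect-region polygons of the
case faces (default regions: nose, left cheek, right cheek), plus
i.i.d. Gaussian pixel noise of standard deviation `noise_sd` everywhere
for both classes. Rasters are float and deliberately unclipped so the
planted contrast is exact: with zero noise the case-minus-control mean
inside an effect region equals the amplitude to float32 precision.
Defaults, chosen once as the reference conditions: image size 224
(generators accept ≥ 64; tests and the pipeline use 64 for speed),
amplitude 0.5, noise 0.05.

What the generator does **not** emulate: demographic and pose
variation, illumination, texture of real skin, camera effects, or
label noise. Passing recovery tests therefore demonstrates that the
pipeline's geometry, saliency and statistics are correct — not that a
classifier trained on real clinical photographs would behave this way.

The 70/30 split is global over the merged pool (not stratified), with
train size `floor(0.7·N)`; class balance on each side fluctuates
around the pool's. The split, like every generator output, is a pure
function of its seed.

## Six facial areas

The partition is built from convex hulls, similarity-covariant
dilation and boolean clipping only, which makes it equivariant under
similarity transforms of the landmarks and mirror-symmetric under the
canonical horizontal flip permutation:

* **Eyes**: hull of the eye landmarks united with the same-side brow
  landmarks, dilated by 5 % of the inter-ocular distance (quadratic
  buffer segments, 4 per quarter circle).
* **Nose**: hull of landmarks 27–35, dilated likewise. **Mouth**: hull
  of 48–67, dilated likewise.
* **Cheeks**: hull of the same-side jaw landmarks (1–7 / 9–15)
  together with the cheek-facing halves of the eye, nose and mouth
  polygons, then clipped against those polygons. "Cheek-facing half"
  is decided in face-intrinsic axes (lateral axis = right-eye centroid
  to left-eye centroid; vertical axis perpendicular, oriented toward
  the chin), not image axes, to preserve equivariance under rotation.

Precedence on contested ground is eyes > nose > mouth > cheeks; each
lower-precedence polygon is differenced against the higher ones, so
region interiors are pairwise disjoint by construction. Region names
use the anatomical (subject-side) convention of the landmark scheme:
"right-eye" is built from landmarks 36–41, which sit at image-left for
an upright frontal annotation.

Rasterization marks a pixel inside a region iff its integer-coordinate
center is covered by the polygon (boundary inclusive). A contour is
assigned to **every** region its filled pixels overlap by at least one
pixel: the per-region proportions are computed independently per
region, so multi-assignment is the consistent choice for a feature
straddling a boundary; exclusive assignment would make the six
proportions sum-constrained in a way the reporting format does not
assume.

## Classifier harness

Three compact backbone families (VGG-like plain stacks, ResNet-like
residual blocks, Inception-like parallel branches; 2–3 conv stages,
8–32 channels, global average pooling, 2-logit head) are implemented
in numpy with hand-written backward passes — which is also what exposes
the intermediate-activation gradients Grad-CAM needs. Correctness is
pinned by finite-difference gradient checks in the test suite.

Conventions and defaults, stated because no framework default exists
here: He-normal initialization (the `weight_init` flag switches to
Xavier-uniform); SGD momentum 0.9; Adam β = (0.9, 0.999), ε = 1e-8;
batch size 32; inputs standardized by the training pool's global
mean/std. The decision rule is argmax over the two logits. "Last five
layers" freezing trains the last five weight-bearing layers (conv /
batch-norm / linear), counted in forward order; "last-fc-only" trains
only the head. Freezing presupposes pretrained (stub) weights — a
checkpoint saved from a prior synthetic run, a semantic stand-in for a
large-corpus pretrained model, not an equivalent.

**Stopping rule**: training ends at `epochs_max` or when the window-3
moving average of the epoch training loss fails to improve by ≥ 1e-4
for 5 consecutive epochs — a deterministic realization of "stop when
the training loss no longer decreases".

**Batch-norm calibration**: at high learning rates the exponential
running statistics (momentum 0.1) lag the rapidly moving weights, so
eval-mode behavior can diverge from the trained network. After
training, one full pass recomputes each BN layer's population
statistics under the final weights (mean of batch means; mean of batch
variances plus the between-batch variance of means). This "precise BN"
pass is deterministic and part of `train`.

## Grad-CAM

Standard definition: per-channel weights are the spatial average of
the raw (pre-softmax) class-score gradient at the chosen layer's
output; the map is the ReLU of the weighted channel sum, bilinearly
upsampled to the input size, then min–max normalized per image with an
all-zero guard (an everywhere-non-positive map stays zero; a constant
positive map maps to 1). Per-image normalization is the convention
used throughout, including before binarization.

The library default layer is the last convolution-bearing layer, the
standard choice. The **pipeline** default for quantification is instead
the *first* (finest) conv layer: at desk scale the last stage is 8×8,
and a single upsampled blob covers most of a 64-px face, which washes
out regional contrasts. This is a documented consequence of
downscaling, not a property of the method at full scale.

Quantification targets the image's **true** class label, so group
comparisons measure where class evidence concentrates per group; the
target is configurable.

## Heatmap quantification

Binarization threshold 0.5 of the normalized range (Otsu available as
an option); the raw normalized heatmap is binarized, never a
color-mapped rendering. Smoothing uses the 3×3 binomial kernel
[[1,2,1],[2,4,2],[1,2,1]]/16 (the σ-from-kernel-size convention) with
zero padding, re-thresholded at ≥ 0.5 — an isolated pixel blurs to
0.25 and vanishes; the interior of any solid 3×3 block survives, both
verified bit-exactly in tests. Contours are 8-connected components;
the size filter keeps a contour iff its bounding box is ≥ 10 px in
*both* dimensions (strictly smaller in either dimension discards;
exactly 10 survives). The 10 px rule is defined in the 224-px
reference frame; at other image sizes the pipeline scales it
proportionally (minimum 2 px).

"Number of appearances" is per-image *presence*: a region's count is
the number of images in the group with at least one surviving contour
touching it, so proportions are n/N over the group size. Proportions
are reported as percentages rounded half-up to two decimals, computed
in exact decimal arithmetic from the integer counts.

## Statistics

ACC/SEN/SPE are exact rational percentages (half-up, two decimals);
zero-denominator metrics raise a named error rather than returning a
sentinel. The 2×2 comparison is the Pearson chi-square without Yates
continuity correction (df = 1); the cell counts this pipeline produces
are large enough that the correction is immaterial, and it is
available as a flag. No multiple-testing correction is applied across
the six regions. Validation sizing uses the Buderer-type precision
formula for sensitivity (`power` is recorded but unused by that
formula); scenario expansion rounds half-up. The pipeline caps the
sensitivity estimate fed to the formula at 0.95 so a perfect desk-scale
classifier still yields a non-degenerate design.

## Problem sizes

Unit tests run at image size 64 with dataset sizes of tens to a few
hundred images; the recovery experiments use amplitude 0.8 with
200/400 training images for the planted case, 200/200 for the null
(a balanced null makes the chance band around 0.5 meaningful), and 100
replicates of 100 + 100 synthetic heatmaps for the concentration
recovery. These sizes were chosen so the full suite completes in a few
CPU-minutes while keeping every statistical check well-powered.

## Known limitations

* The template face and constant-elevation signal are far easier to
  classify than real imagery; absolute accuracies here say nothing
  about clinical performance.
* Landmarks are inputs (ground truth from the generator, or sidecar
  JSON for user data); the package does not detect landmarks in
  photographs.
* The exact landmark-to-region convention is one defensible
  reconstruction among several; alternative cheek constructions would
  shift region boundaries by a few pixels.
* At desk scale the coarse-layer Grad-CAM saturates (most images flag
  most regions); the finest-layer default mitigates but does not
  remove this.
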