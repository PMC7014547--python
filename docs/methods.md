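# Methods

This note documents the models, algorithms and numerical choices behind
`irgaze`, and what the synthetic validation does and does not establish.

## 1. The 3D gaze model

**Geometry.** The camera is an ideal pinhole at the origin of a
right-handed frame (x right, y down, z from camera toward the user), zero
distortion, principal point at the image center.  The default device is a
5-inch handset: 3840x2160 sensor, 75 deg horizontal field of view (focal
length 1920/tan 37.5 deg ~ 2503 px), a 115.2 x 64.8 mm display in the
camera plane below the camera, and two IR LEDs near the top-right and
bottom-left display corners.  The exact LED offsets of any real prototype
are hardware-specific; the defaults are documented assumptions and
everything is overridable through `DeviceGeometry` / the YAML config.

**Cornea and glints.** The corneal front surface is a sphere of radius
`R` about the center of corneal curvature `C`.  A glint is the reflection
of an LED into the camera nodal point.  By symmetry the reflection point
lies in the plane spanned by LED, nodal point and `C`; within that plane
the law-of-reflection residual (the cross product of the surface normal
with the bisector of the two view directions) is a monotone function of
the surface angle between the camera-facing and LED-facing poles, so the
point is found by bisection to 1e-12 rad.  Points on the occluded
hemisphere or eyes behind the camera raise `NoSolutionError`.

**Pupil.** The pupil center sits at `C + K*omega` (optic axis `omega`,
unit).  Its image is formed through refraction at the corneal surface; we
use a single effective refractive index of 1.3375 (the standard
keratometric value combining cornea and aqueous).  The refraction point is
solved in the camera-C-pupil plane by bracketing + Brent root finding on
the skew between the refracted ray and the pupil center.  A flagged
`refraction=False` mode projects the pupil directly; it exists for unit
tests and degenerate checks (e.g. K -> 0), and forward and inverse must
always use the same mode.

**Inverse model.** Given valid features: (i) each glint constrains `C` to
a 1-D locus (walk along the back-projected glint ray; the surface normal
must bisect camera and LED directions; step `R` inward).  The two loci are
intersected in least squares over their two ray parameters by
Gauss-Newton (60 iterations max, step tolerance 1e-10, initialized at the
nominal 300 mm operating distance).  Near-coincident glints make the
normal equations singular and raise `IllConditionedError` (threshold:
glints closer than 0.25 px).  (ii) With `C` known, the pupil ray is
intersected with the R-sphere, refracted by Snell's law, and intersected
with the K-sphere — closed form, near root both times.  A vectorized
batch path (`estimate_pog_batch`) runs thousands of feature sets per
objective evaluation during calibration; it matches the scalar path to
1e-6 and returns NaN rows instead of raising.

**Visual axis.** The optical-to-visual-axis offset is applied in
azimuth/elevation angle space: azimuth (about the eye's vertical axis)
shifted by `alpha_h` first, then elevation by `alpha_v`.  Angle-space
addition makes the transform exactly invertible — applying the negated
angles restores the optic axis to machine precision — which a sequential
rotation about recomputed axes would not satisfy.  Sign convention:
positive `alpha_h` rotates toward +x, positive `alpha_v` upward (-y).

**Point of gaze.** Ray-plane intersection with the screen plane
(orthonormal in-plane axes enforced); gaze bias in degrees is
`atan(error_mm / distance_mm)`.

Because the inverse uses only the current frame's features and the
subject's fixed physiology, the PoG is invariant to head/device
translation: the round trip recovers a fixated point to <1e-9 mm at any
distance in 200-400 mm, and the property suite asserts a <0.05 deg bias
spread over that range from a single 300 mm calibration.

## 2. Calibration

Five targets in a plus pattern; 50 valid feature sets per target by
default.  `scipy.optimize.least_squares(method="lm")` over
(R, K, alpha_h, alpha_v), seeded at the physiological averages
(7.8 mm, 4.2 mm, 5 deg, 1.5 deg).  Each feature set contributes its own
per-axis PoG-target residual (no pre-averaging), so LM minimizes the sum
of squared distances; the reported residual is the mean Euclidean
distance in mm, the quantity the protocol describes.  Finite-difference
Jacobian with relative step 1e-6; tolerances 1e-12; at most 200
iterations' worth of function evaluations.

Under feature noise R and K are weakly identified individually (they
trade off along the depth direction) while the PoG stays accurate; this
is expected and the tests assert the gaze-level property (bias < 0.5 deg
across the screen under 0.25 px feature noise) as well as exact parameter
recovery in the noiseless limit (<1% on R and K, <0.1 deg on the offsets).

Calibrations serialize to JSON with a device-geometry hash; loading onto
a different geometry is refused.

## 3. Feature-extraction networks

**Base architecture.** 1-5 conv layers (4-128 kernels, widths 3-9, same
padding, batch norm, ReLU, optional 2x2 max-pool), then 0-2 hidden dense
layers (64-2048 neurons) with inverted dropout (0.3-0.7) before the output
layer.  Inputs are 64/96/128/256-px crops optionally block-mean
down-scaled by 2/4/8, then standardized per image (zero mean, unit
variance) to remove illumination/gain variation.  Configurations that
pool a map below 1 px or exceed an 11 GB training-memory estimate at
batch 32 are rejected (and resampled during random search).

**Heads and losses.**

* *Classifier*: two softmax neurons (invalid, valid); summed binary
  cross-entropy; probabilities clamped to [1e-7, 1-1e-7].  Validity
  threshold 0.5 at inference.
* *Regression*: two linear neurons for the location relative to the crop;
  loss is the summed Euclidean distance in input px.
* *Center of mass (soft-argmax)*: one neuron per (down-scaled) input
  pixel, softmax over the map, then the probability-weighted mean pixel
  coordinate.  Trained by back-propagating the same Euclidean loss
  through the expectation (gradient through softmax in closed form).  An
  alternative mode treats the nearest pixel as a one-hot classification
  target; it is provided for comparison but the soft-argmax objective is
  the default, keeping one position loss for all estimators.  Map
  coordinates convert to native full-frame px via
  `native = input*d + (d-1)/2 + crop_offset` (block-mean pixel centers).

**Head span.** The center-of-mass map spans the pixels of the
*down-scaled* network input; mapping back through the crop offset and
scale restores native resolution.  (For a down-scaled net, a map over
pre-downscale pixels would multiply the head size by d^2 for no spatial
information gain.)

**Training protocol.** Adam (lr 1e-3, beta 0.9/0.999), batch 32, up to 20
epochs, seeded shuffling; a step decay multiplies the learning rate by
0.3 at 25%, 50% and 75% of the epoch budget.  The decay is what polishes
the soft-argmax heads to sub-pixel precision (higher base rates collapse
the softmax map to its uniform fixed point), and front-loading it brings
every network to its validation plateau early in the budget, so the
epochs among which the early-save rule selects are all converged — the
regime the rule was designed for.  The global gradient norm is
clipped at 300 for the position networks: rare outlier batches otherwise
cause transient validation spikes that destabilize epoch selection.
Before each epoch-end evaluation the batch-norm inference statistics are
recalibrated exactly over a training subsample (running estimates lag the
weights, and one late outlier batch would otherwise skew every evaluated
metric).  The early-save rule then snapshots the parameters only when
|training error - validation error| is smaller than at every previous
epoch, and the best snapshot is restored at the end; ties keep the
earliest epoch.  The epoch's training error is the running mean of its
training loss (the standard per-epoch fit metric, dropout active), which
starts far above the validation error and converges toward it from
above; undertrained early epochs are therefore never selected, and with
the front-loaded decay the gap shrinks essentially monotonically, so the
rule retains a late, converged epoch while still guarding against a
train/validation divergence.  A non-finite loss raises
`DivergenceError`.

**Evaluation.** Position networks are scored by the mean Euclidean error
in native px on held-out regions, excluding gross errors above 7.5 px
(reported separately as a rate).  The filter is applied only in
evaluation: it makes errors comparable across crop sizes, never shapes
training.

**Flop accounting.** A documented fixed convention: multiply-accumulate
= 2 flops; conv/dense count MACs plus bias adds; batch norm 2
flops/element (fused inference form); ReLU 1; 2x2 pooling 3 comparisons
per output; softmax ~3/element; center-of-mass ~4/element.  Under this
convention the selected fine pupil net counts 32.1 mflops, glint-A 11.8,
the coarse localizer 2.6 and the classifier 20.2 — within a few percent
of the costs the selection was based on.  The medium localizer and
glint-B differ more (3.9 vs 2.5, 18.5 vs 12.6): framework counters
disagree on what they include, so published costs are treated as
reference points, not targets.

**Implementation.** The layers are numpy (float32, NHWC); convolutions
are GEMM-backed via im2col, with a numba-JIT patch-matrix builder and a
scatter-add col2im for the input gradient (a pure-numpy fallback keeps
the package functional without numba).  Gradients of every layer are
verified against finite differences and `scipy.signal.correlate2d` in the
test suite.  The first conv layer skips its input gradient.

**Selected networks.** The five position architectures follow the
published selections (kernels/widths per layer, one hidden dense layer,
dropout; pooling and batch norm everywhere).  The classifier's internals
were never published beyond 64-px crop, no down-scaling, ~20 mflops and
98% validation accuracy; the configuration shipped here (three conv
layers of 16 width-5 kernels with pooling, one hidden dense layer of 64)
is drawn from the same hyperparameter space and reproduces the cost.

**Cascade.** Proposal (previous pupil or an external eye-region center)
-> coarse 256-crop/8x localizer -> medium 128-crop/4x -> 64-px crop ->
classifier gate at 0.5 -> fine pupil (1x), glint A and glint B (2x).
Crops are clamped into the frame; a proposal outside the frame raises.
The two-stage coarse hierarchy exists because the 64-px crop must contain
the pupil and both glints (bounding boxes reach 58 px at the nearest
distances), which requires localization errors under ~6 px per axis —
cheaper to reach in two stages than with one large-crop network.

## 4. Synthetic data

**What it emulates.** Handheld-phone IR captures: per subject a fixed
appearance (pupil/iris radius in mm, contrasts); per frame a device pose
with eye-camera distance uniform in 200-400 mm and angular (not metric)
lateral offsets — people hold a phone roughly facing them — and a
fixation target on the screen; two eye regions per frame (left/right eye,
58-66 mm apart, both fixating the target); feature positions from the 3D
forward model; ten crops at uniform random offsets within +-crop/8 of the
pupil.  Per 20 frames of a subject, a random ~6 are captured with one or
both LEDs disabled (invalid by construction); blinks (13% of frames,
eyelid covering 50-100% of the pupil) and heavy blur (5%) supply natural
invalid regions, landing the class balance near 55/45 valid/invalid.
Poses whose pupil-centered feature bounding box would exceed 58 px are
resampled, emulating the envelope seen in real handheld collections.

**Rendering.** Bright sclera, uniform iris disk, elliptical pupil
(axis ratio 0.88-1.0 for gaze foreshortening), all with ~1 px anti-aliased
edges so sub-pixel positions are observable; Gaussian glints (sigma
0.9-1.6 px) only for enabled LEDs, occluded when behind the eyelid; an
upper-eyelid skin band whose cut height is solved exactly from the target
occlusion fraction via the ellipse-segment area; Gaussian optical blur,
box motion blur, additive sensor noise, clipping to [0, 1].  "Invalid" is
crisp by construction: missing/occluded glint, occlusion fraction >25%,
blur sigma >1.5 px, or motion blur >3 px.  Valid-frame occlusion is drawn
from 0-15%, leaving a deliberate gap to the blink range so the synthetic
labels avoid the 1-2% annotator-ambiguous borderline of real data.

**Labeling-noise models.** Single-click glint labeling quantizes to whole
pixels: per-axis error ~U(-0.5, 0.5) px, mean absolute error 0.25 px,
quadrature combination sqrt(2)/4 ~ 0.354 px (Monte-Carlo in
`quantization_error_model`, analytic in the tests).  Pupil labeling fits
an ellipse (scikit-image `EllipseModel`) to ten clicked boundary points
and takes its center; with 0.25 px click noise the center is good to
<0.3 px.

**What passing does not show.** The renderer is not photorealistic: no
iris texture, eyelashes, glasses reflections, off-axis LED artifacts or
sensor nonlinearity; its ground truth is exact rather than click-
quantized.  Synthetic benchmark numbers therefore bound the method's
behavior under the modeled variability only; real-data error levels and
the real-subject grid percentages are not claims this package makes.

## 5. Evaluation harnesses

**Distance sweep.** Calibrate once at 300 mm; at each of 200/250/300/350/
400 mm collect 50 estimates on each of 5 targets (X pattern).  Bias per
target = distance between the target and the *mean* of its estimates
(definition check in the tests: a symmetric cloud has zero bias),
converted to degrees with the viewing distance, averaged over targets.

**Grid test.** Boxes of a columns x rows tiling are highlighted in random
order; 15 raw estimates per box; the moving-average filter of length n is
applied; an averaged estimate is correct iff inside the highlighted box.
Box membership is half-open (low edge inclusive) so edge points belong to
exactly one box.  The 500 ms settling delay of a live protocol is
represented by an optional number of discarded initial samples (default 0
for synthetic trackers).

**Moving average.** A track of S raw samples yields S - n averaged
estimates: the first raw sample is discarded and windows slide over the
remainder.  This convention is pinned by the protocol arithmetic (15 raw
-> 11 four-sample averages; 11 x 24 targets x 8 subjects = 2112) even
though S - n + 1 is the more common choice; n = 1 consequently returns
S - 1 raw samples.  Windows containing an invalid sample are invalid.

**Simulated tracker.** The harnesses run on a geometry-exact simulated
front end (forward model with the subject's true parameters + isotropic
Gaussian feature noise, inverted with the calibrated parameters).  It
isolates the gaze-model properties from CNN behavior; the cascade is
validated separately on rendered frames.

## 6. Desk-scale benchmark sizes

The published experiments used 40 000 augmented regions and 20-epoch
training per network (and a 256-configuration random search).  The
package's benchmarks reproduce the protocol at workstation scale: 40
subjects x 20 frames x 2 eyes x 7 crops (~4900 valid training and ~1200
held-out regions from disjoint subjects) (the
classifier trains on 4 of the 7 crops per region), with 7 epochs for the
classifier, 5 for the fine pupil network and 16 for the glint networks —
the validation plateaus sit inside these budgets under the front-loaded
decay, with the glint networks needing the deepest low-learning-rate
phase.  Augmentation favors subject diversity over
near-duplicate crops at equal totals, mirroring the published dataset's
subject structure.  The random search command (`irgaze search`) defaults to
12 configurations at 2 epochs as a demonstration; all scales are
parameters.

## 7. Known limitations

* Spherical cornea: no aspheric periphery, so gazes that place a glint
  near the corneal margin are modeled optimistically (real devices show
  degraded corners for exactly this reason).
* No torsion; the eye frame is defined from the camera frame's vertical.
* Single effective refractive surface for the pupil path.
* Binocular fusion is plain per-eye estimation (left/right averaging is
  exposed but not studied).
* The early-save rule follows the published wording; when the train/val
  gap is dominated by dropout rather than over-fitting it can retain a
  slightly pre-convergence epoch.  With the decay schedule the final
  epochs win in practice.
* Synthetic-only validation; see §4.
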