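# irgaze

Infrared smartphone eye-tracking: CNN feature extraction with a
center-of-mass output layer, feeding a 3D spherical-cornea gaze model.

## The problem

Remote eye trackers that rely on visible light and appearance-based
regression reach gaze errors of ~3 visual degrees on handheld devices —
too coarse for most applications.  Trackers that actively illuminate the
eye with infrared LEDs and model the eye's 3D geometry can do an order of
magnitude better, but they need the positions of the **pupil center** and
of two **corneal reflections** (glints — virtual images of the IR LEDs
formed by specular reflection off the cornea) located at sub-pixel
accuracy, under the large appearance variability of a phone held freely in
the hand.

`irgaze` implements this hybrid design end-to-end for researchers working
on mobile gaze estimation:

1. **Feature extraction** — a coarse-to-fine cascade of six small CNNs:
   two cheap, heavily down-scaled pupil localizers (256-px crop at 8x,
   128-px at 4x) tighten the eye region; a classifier rejects invalid
   regions (blinks, missing glints, motion blur) at probability threshold
   0.5; three precise estimators locate the pupil and both glints.  The
   position networks end in a **center-of-mass (soft-argmax) output
   layer**: one neuron per input pixel, a softmax across the map, and the
   probability-weighted mean pixel coordinate as the estimate — trained by
   back-propagating the Euclidean position loss through the expectation.
2. **Gaze geometry** — a one-camera / two-LED spherical-cornea model.
   From the two glints and the corneal radius *R* the center of corneal
   curvature is recovered; from the pupil image (refracted at the corneal
   surface, effective index 1.3375) and the cornea-pupil distance *K* the
   optic axis follows; rotating by the subject's offset angles
   (&alpha;<sub>h</sub>, &alpha;<sub>v</sub>) between optical and visual
   axis and intersecting with the screen plane gives the point-of-gaze
   (PoG).  The construction uses only the current frame's features, so it
   is invariant to head and device motion.
3. **Calibration** — the four subject parameters (R, K, &alpha;<sub>h</sub>,
   &alpha;<sub>v</sub>) are fitted by Levenberg-Marquardt from fixations on
   five known targets, starting at physiological averages; they are stable
   physiology and are saved for reuse across sessions.
4. **Synthetic data** — no public dataset of labeled IR smartphone eye
   regions exists, so the package renders its own: anti-aliased
   pupil/iris/sclera with Gaussian glints placed by the 3D forward model,
   blinks, motion blur, sensor noise, disabled-LED frames, exact sub-pixel
   ground truth, and subject-disjoint splits.  Every stage is validated
   against this generator.

The CNN stack itself (conv / batch-norm / max-pool / dense layers, three
output heads, Adam, backprop through the soft-argmax) is a compact numpy
library inside the package — small networks of this size train in minutes
on a single CPU core.

## A worked example

```python
import numpy as np
from irgaze import (DeviceGeometry, EyeParams, EyeState,
                    forward_features, optic_axis_from_visual)
from irgaze.calibration import estimate_pog

dev = DeviceGeometry()     # 4K IR camera, 75 deg FOV, 115.2 x 64.8 mm screen
par = EyeParams()          # R=7.8 mm, K=4.2 mm, alpha=(5.0, 1.5) deg

target = np.array([80.0, 40.0])              # fixated point, screen mm
cornea = np.array([3.0, 28.0, 300.0])        # eye 30 cm from the camera
v = dev.screen_to_camera(target) - cornea
v /= np.linalg.norm(v)
eye = EyeState(cornea, optic_axis_from_visual(v, par))

f = forward_features(eye, par, dev)          # project pupil + two glints
print(np.round(f.pupil, 2))                  # [1944.01 1320.52]  (px)
pog = estimate_pog(f, par, dev)              # invert from features alone
print(np.round(pog.screen_mm, 6))            # [80. 40.]  (mm)
```

The forward model projects the eye to image features (pupil at pixel
(1944.01, 1320.52) here); the inverse pipeline recovers the fixated screen
point to ~1e-10 mm from noiseless features — and stays within 0.05 deg
across 200-400 mm viewing distance from a single calibration.  The
`examples/` scripts walk through rendering (`02`), training a sub-pixel
pupil estimator (`03`), calibration and the distance sweep (`04`), and the
grid target-identification test (`05`), each printing and explaining its
numbers.

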