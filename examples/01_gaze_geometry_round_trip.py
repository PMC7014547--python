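"""Forward/inverse 3D eye model: project features, invert them, compare.

Builds an eye fixating a known screen point, projects the pupil center and
both corneal reflections into the camera, reconstructs the eye from those
features alone and intersects the visual axis with the screen.  The
recovered point-of-gaze should match the fixated point to numerical
precision, at every distance, without recalibration.
"""

import numpy as np

from irgaze import (DeviceGeometry, EyeParams, EyeState, bias_deg,
                    forward_features, optic_axis_from_visual)
from irgaze.calibration import estimate_pog

dev = DeviceGeometry()          # 5-inch handset: 4K IR camera, 2 IR LEDs
par = EyeParams()               # physiological averages: R=7.8, K=4.2 mm

target = np.array([80.0, 40.0])  # fixated screen point (mm)
print(f"fixation target: {target} mm on a "
      f"{dev.screen_size[0]:.0f} x {dev.screen_size[1]:.0f} mm display\n")

for z in (200.0, 300.0, 400.0):
    cornea = np.array([3.0, 28.0, z])
    v = dev.screen_to_camera(target) - cornea
    v /= np.linalg.norm(v)
    eye = EyeState(cornea, optic_axis_from_visual(v, par))

    feats = forward_features(eye, par, dev)
    pog = estimate_pog(feats, par, dev)
    err = np.linalg.norm(pog.screen_mm - target)
    print(f"z = {z:5.0f} mm | pupil px ({feats.pupil[0]:7.2f}, {feats.pupil[1]:7.2f})"
          f" | PoG ({pog.screen_mm[0]:6.2f}, {pog.screen_mm[1]:6.2f}) mm"
          f" | error {err:.2e} mm = {bias_deg(err, z):.2e} deg")

print("\nThe error stays at numerical precision across 200-400 mm: the"
      "\n3D model is invariant to eye-device distance by construction.")
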