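"""Four-parameter subject calibration and the distance sweep.

Simulates a subject with unknown eye geometry fixating the five-point
calibration pattern at 300 mm (50 feature sets per target, quarter-pixel
feature noise), fits R, K and the two kappa offset angles with
Levenberg-Marquardt, then measures gaze bias at 200-400 mm *without
recalibrating*.  The bias stays flat across distances: the 3D model's
motion invariance.
"""

import numpy as np

from irgaze import DeviceGeometry, EyeParams
from irgaze.evaluate import (SimulatedTracker, run_distance_sweep,
                             simulate_calibration)

dev = DeviceGeometry()
rng = np.random.default_rng(7)
true = EyeParams(R=rng.uniform(7.2, 8.4), K=rng.uniform(3.8, 4.6),
                 alpha_h=rng.uniform(-6, 6), alpha_v=rng.uniform(-3, 3))
print("true subject parameters  :",
      np.round(true.as_array(), 3), "(R mm, K mm, ah deg, av deg)")

est, residual = simulate_calibration(true, dev, n_sets=50,
                                     feature_noise_px=0.25, seed=7)
print("calibrated parameters    :", np.round(est.as_array(), 3))
print(f"calibration residual     : {residual:.3f} mm mean gaze-target distance")

tracker = SimulatedTracker(dev, true, est, feature_noise_px=0.25)
sweep = run_distance_sweep(tracker, seed=8)
print("\ngaze bias by distance (deg), single 300 mm calibration:")
print(sweep.to_dataframe().round(3).to_string(index=False))
print("\nNote R/K can trade off against each other under feature noise"
      "\nwhile the gaze bias stays small and flat across the whole range.")
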