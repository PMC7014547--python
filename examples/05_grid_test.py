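"""Grid target-identification test with moving-average filtering.

Tiles the screen into boxes, highlights each in random order, collects 15
gaze estimates per box from simulated calibrated subjects and scores the
fraction of n-averaged estimates inside the highlighted box.  Accuracy
drops as boxes shrink and rises with the averaging window.
"""

import numpy as np

from irgaze import DeviceGeometry, EyeParams
from irgaze.evaluate import (GridSpec, SimulatedTracker, run_grid_test,
                             simulate_calibration)

dev = DeviceGeometry()
rng = np.random.default_rng(3)

# a deliberately noisy front end (1 px feature noise) so the grid test is
# not trivially perfect
NOISE_PX = 1.0
true = EyeParams(R=7.9, K=4.3, alpha_h=4.0, alpha_v=1.2)
est, _ = simulate_calibration(true, dev, feature_noise_px=NOISE_PX, seed=3)
tracker = SimulatedTracker(dev, true, est, feature_noise_px=NOISE_PX)

print(f"simulated front-end feature noise: {NOISE_PX} px\n")
print("grid    box (mm)      n_avg=2   n_avg=6")
for cols, rows in ((3, 2), (4, 3), (6, 4), (8, 6)):
    spec = GridSpec(cols, rows)
    bw, bh = spec.box_size_mm(dev)
    accs = [run_grid_test(spec, tracker, n_avg=n, simulated_subjects=2,
                          seed=10 + n).overall_accuracy for n in (2, 6)]
    print(f"{cols} x {rows}   {bw:4.1f} x {bh:4.1f}    "
          f"{100 * accs[0]:5.1f}%    {100 * accs[1]:5.1f}%")

res = run_grid_test(GridSpec(8, 6), tracker, n_avg=6, simulated_subjects=2,
                    seed=20)
print(f"\n8 x 6 per-box accuracy map (%, n_avg=6):")
print((res.per_box_accuracy * 100).round(0))
print("\nDenser grids are harder (smaller boxes); longer averaging windows"
      "\nreduce estimate scatter and recover accuracy.")
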