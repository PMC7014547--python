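"""Experiment harnesses: distance sweep, grid test, spatial accuracy maps.

The two protocols mirror how remote eye trackers are validated:

* **Distance sweep** -- calibrate once at 300 mm, then measure gaze bias at
  five eye-device distances (200-400 mm).  The bias per target is the
  distance between the target and the *mean* of its gaze estimates,
  converted to visual degrees with the known viewing distance, then
  averaged over targets.  A motion-invariant 3D model keeps this flat
  across distances without recalibration.
* **Grid test** -- the screen is tiled into approximately square boxes;
  each box is highlighted in random order, a burst of raw gaze estimates is
  collected on it, a moving-average filter of length n is applied, and an
  averaged estimate counts as correct when it falls inside the highlighted
  box.  Box membership is half-open (low edge inclusive, high edge
  exclusive) so every point belongs to exactly one box.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np

from .calibration import (CalibrationSession, GazeTrack, calibrate,
                          default_calibration_targets, moving_average,
                          sweep_targets)
from .geometry import (DeviceGeometry, EyeParams, EyeState, bias_deg,
                       estimate_pog_batch, forward_features,
                       optic_axis_from_visual)

__all__ = [
    "GridSpec", "GridResult", "DistanceSweepResult", "SimulatedTracker",
    "simulate_calibration_session", "simulate_calibration",
    "run_grid_test", "run_distance_sweep", "spatial_accuracy_map",
    "SUPPORTED_GRIDS", "SWEEP_DISTANCES_MM",
]

SUPPORTED_GRIDS = ((3, 2), (4, 3), (6, 4), (8, 6))
SWEEP_DISTANCES_MM = (200.0, 250.0, 300.0, 350.0, 400.0)
CALIBRATION_DISTANCE_MM = 300.0


@dataclass
class GridSpec:
    """A columns x rows tiling of the screen into equal target boxes."""

    columns: int
    rows: int

    def __post_init__(self) -> None:
        if self.columns < 1 or self.rows < 1:
            raise ValueError("grid must have positive dimensions")

    def box_size_mm(self, dev: DeviceGeometry) -> Tuple[float, float]:
        w, h = dev.screen_size
        return w / self.columns, h / self.rows

    def box_centers(self, dev: DeviceGeometry) -> np.ndarray:
        """(rows*columns, 2) centers in screen mm, row-major."""
        bw, bh = self.box_size_mm(dev)
        cx = (np.arange(self.columns) + 0.5) * bw
        cy = (np.arange(self.rows) + 0.5) * bh
        return np.array([[x, y] for y in cy for x in cx])

    def box_of(self, points_mm: np.ndarray, dev: DeviceGeometry) -> np.ndarray:
        """Row-major box index per point; -1 for points off the screen.

        Half-open boxes: a point exactly on a shared edge belongs to the
        box whose low edge it lies on.
        """
        pts = np.atleast_2d(points_mm)
        bw, bh = self.box_size_mm(dev)
        ix = np.floor(pts[:, 0] / bw).astype(int)
        iy = np.floor(pts[:, 1] / bh).astype(int)
        ok = (ix >= 0) & (ix < self.columns) & (iy >= 0) & (iy < self.rows)
        idx = np.where(ok, iy * self.columns + ix, -1)
        return idx


@dataclass
class GridResult:
    spec: GridSpec
    overall_accuracy: float
    per_box_accuracy: np.ndarray   # (rows, columns)
    n_estimates: np.ndarray        # (rows, columns) averaged estimates per box
    n_avg: int

    def __post_init__(self) -> None:
        assert 0 <= self.overall_accuracy <= 1


@dataclass
class DistanceSweepResult:
    distances_mm: np.ndarray
    bias_deg: np.ndarray           # mean over targets, per distance

    @property
    def average(self) -> float:
        return float(self.bias_deg.mean())

    def to_dataframe(self):
        import pandas as pd
        cols = {f"{d / 10:.0f} cm": [b] for d, b in
                zip(self.distances_mm, self.bias_deg)}
        cols["Average"] = [self.average]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# simulated end-to-end tracker
# ---------------------------------------------------------------------------


@dataclass
class SimulatedTracker:
    """Geometry-exact tracker with configurable feature noise.

    Stands in for the full camera + CNN front end: for each requested
    estimate it synthesizes image features of an eye fixating the target
    from a jittered pose (the forward 3D model with the subject's *true*
    eye parameters), perturbs them with isotropic Gaussian pixel noise of
    the front end's error scale, and inverts them with the *calibrated*
    parameters.  With zero noise and a perfect calibration it reproduces
    the fixated point exactly.
    """

    dev: DeviceGeometry
    true_params: EyeParams
    est_params: EyeParams
    feature_noise_px: float = 0.25
    z_jitter_mm: float = 10.0
    xy_range_mm: Tuple[float, float, float, float] = (-8.0, 8.0, 25.0, 38.0)
    refraction: bool = True

    def collect(self, target_mm: np.ndarray, n: int, distance_mm: float,
                rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
        """(points_mm (n, 2), valid (n,)) gaze estimates on one target."""
        t3d = self.dev.screen_to_camera(np.asarray(target_mm, float))
        pupils, gas, gbs = [], [], []
        for _ in range(n):
            c = np.array([rng.uniform(*self.xy_range_mm[:2]),
                          rng.uniform(*self.xy_range_mm[2:]),
                          distance_mm + rng.uniform(-self.z_jitter_mm,
                                                    self.z_jitter_mm)])
            v = t3d - c
            v = v / np.linalg.norm(v)
            eye = EyeState(c, optic_axis_from_visual(v, self.true_params))
            f = forward_features(eye, self.true_params, self.dev,
                                 refraction=self.refraction)
            if self.feature_noise_px > 0:
                f = f.with_noise(self.feature_noise_px, rng)
            pupils.append(f.pupil)
            gas.append(f.glint_a)
            gbs.append(f.glint_b)
        pts = estimate_pog_batch(np.asarray(pupils), np.asarray(gas),
                                 np.asarray(gbs), self.est_params, self.dev,
                                 refraction=self.refraction)
        valid = np.isfinite(pts).all(axis=1)
        return pts, valid


def simulate_calibration_session(true_params: EyeParams, dev: DeviceGeometry,
                                 n_sets: int = 50,
                                 feature_noise_px: float = 0.25,
                                 distance_mm: float = CALIBRATION_DISTANCE_MM,
                                 seed: int = 0) -> CalibrationSession:
    """Collect a five-target calibration session from the forward model."""
    rng = np.random.default_rng(seed)
    targets = default_calibration_targets(dev)
    fsets = []
    for t in targets:
        t3d = dev.screen_to_camera(t)
        sets = []
        while len(sets) < n_sets:
            c = np.array([rng.uniform(-8, 8), rng.uniform(25, 38),
                          distance_mm + rng.uniform(-10, 10)])
            v = t3d - c
            v = v / np.linalg.norm(v)
            eye = EyeState(c, optic_axis_from_visual(v, true_params))
            f = forward_features(eye, true_params, dev)
            if not f.valid:
                continue
            if feature_noise_px > 0:
                f = f.with_noise(feature_noise_px, rng)
            sets.append(f)
        fsets.append(sets)
    return CalibrationSession(targets, fsets)


def simulate_calibration(true_params: EyeParams, dev: DeviceGeometry,
                         n_sets: int = 50, feature_noise_px: float = 0.25,
                         seed: int = 0) -> Tuple[EyeParams, float]:
    sess = simulate_calibration_session(true_params, dev, n_sets=n_sets,
                                        feature_noise_px=feature_noise_px,
                                        seed=seed)
    return calibrate(sess, dev)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

TrackerFactory = Callable[[int, np.random.Generator], SimulatedTracker]


def run_grid_test(spec: GridSpec, tracker: Union[SimulatedTracker, TrackerFactory],
                  n_avg: int, simulated_subjects: int = 8, seed: int = 0,
                  samples_per_target: int = 15,
                  distance_mm: float = CALIBRATION_DISTANCE_MM,
                  settle_discard: int = 0) -> GridResult:
    """Grid test over simulated subjects.

    Per subject every box is highlighted once in random order; 15 raw
    estimates are recorded per box (after discarding ``settle_discard``
    initial samples, the stand-in for the 500 ms settling delay) and the
    moving-average filter of length ``n_avg`` is applied, so each box
    yields ``samples_per_target - n_avg`` scored estimates.
    """
    rng = np.random.default_rng(seed)
    nb = spec.columns * spec.rows
    centers = spec.box_centers  # bound method, evaluated per device below
    hits = np.zeros(nb)
    counts = np.zeros(nb)
    for subj in range(simulated_subjects):
        trk = tracker(subj, rng) if callable(tracker) else tracker
        ctrs = centers(trk.dev)
        order = rng.permutation(nb)
        for box in order:
            pts, valid = trk.collect(ctrs[box], samples_per_target + settle_discard,
                                     distance_mm, rng)
            pts, valid = pts[settle_discard:], valid[settle_discard:]
            track = GazeTrack(np.arange(len(pts), dtype=float), pts, valid)
            avg = moving_average(track, n_avg)
            good = avg.valid
            idx = spec.box_of(avg.points_mm[good], trk.dev)
            hits[box] += int((idx == box).sum())
            counts[box] += int(good.sum())
    per_box = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    overall = float(hits.sum() / counts.sum())
    return GridResult(spec=spec, overall_accuracy=overall,
                      per_box_accuracy=per_box.reshape(spec.rows, spec.columns),
                      n_estimates=counts.reshape(spec.rows, spec.columns),
                      n_avg=n_avg)


def run_distance_sweep(tracker: SimulatedTracker,
                       distances_mm: Sequence[float] = SWEEP_DISTANCES_MM,
                       targets: Optional[np.ndarray] = None,
                       estimates_per_target: int = 50,
                       seed: int = 0) -> DistanceSweepResult:
    """Gaze bias vs. eye-device distance from one 300 mm calibration.

    Bias per target is the distance between the target and the mean of its
    estimates (not the mean of distances), converted to degrees with the
    viewing distance; the per-distance figure averages the five targets.
    """
    rng = np.random.default_rng(seed)
    if targets is None:
        targets = sweep_targets(tracker.dev)
    biases = []
    for z in distances_mm:
        per_target = []
        for t in targets:
            pts, valid = tracker.collect(t, estimates_per_target, z, rng)
            mean_pt = pts[valid].mean(axis=0)
            per_target.append(bias_deg(float(np.linalg.norm(mean_pt - t)), z))
        biases.append(float(np.mean(per_target)))
    return DistanceSweepResult(np.asarray(list(distances_mm), float),
                               np.asarray(biases))


def spatial_accuracy_map(result: GridResult, out_csv, out_png=None) -> np.ndarray:
    """Write the per-box percent-correct grid as CSV (and optional figure).

    Returns the percentage matrix (rows x columns).
    """
    pct = result.per_box_accuracy * 100.0
    np.savetxt(out_csv, pct, fmt="%.2f", delimiter=",")
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(pct, cmap="viridis", vmin=0, vmax=100)
        for (r, c), v in np.ndenumerate(pct):
            ax.text(c, r, f"{v:.0f}%", ha="center", va="center",
                    color="white", fontsize=8)
        ax.set_title(f"{result.spec.columns}x{result.spec.rows} grid, "
                     f"n_avg={result.n_avg}: "
                     f"{result.overall_accuracy * 100:.1f}% overall")
        fig.colorbar(im, ax=ax, label="% inside box")
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return pct
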