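"""Subject calibration and the runtime gaze pipeline.

Calibration estimates the four subject-specific eye parameters (corneal
radius R, cornea-to-pupil distance K, and the horizontal/vertical offset
angles between optical and visual axis) from fixations on known screen
targets.  Starting from physiologically average seed values, a
Levenberg-Marquardt optimizer varies the four parameters so that the
distance between the per-feature-set gaze estimates and their targets is
minimized.  Once estimated, the parameters describe fixed physiological
geometry and can be saved and reused across sessions without
recalibration.

The runtime pipeline composes eye-state reconstruction, the optical-to-
visual-axis rotation and the screen intersection; a moving-average filter
reduces the RMS error of gaze-estimate sequences.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from .geometry import (DeviceGeometry, EyeFeatures, EyeParams, GeometryError,
                       PoG, estimate_pog_batch, intersect_screen,
                       reconstruct_eye_state, visual_axis)

__all__ = [
    "CalibrationSession", "GazeTrack", "CalibrationError",
    "default_calibration_targets", "sweep_targets",
    "calibrate", "estimate_pog", "moving_average",
    "save_calibration", "load_calibration",
]


class CalibrationError(RuntimeError):
    pass


def default_calibration_targets(dev: DeviceGeometry) -> np.ndarray:
    """Five-point 'plus' calibration pattern (center + edge midpoints)."""
    w, h = dev.screen_size
    return np.array([[w / 2, h / 2], [w / 2, h / 6], [w / 2, 5 * h / 6],
                     [w / 6, h / 2], [5 * w / 6, h / 2]])


def sweep_targets(dev: DeviceGeometry) -> np.ndarray:
    """Five-point 'X' evaluation pattern (center + four corner thirds)."""
    w, h = dev.screen_size
    return np.array([[w / 2, h / 2], [w / 6, h / 6], [5 * w / 6, h / 6],
                     [w / 6, 5 * h / 6], [5 * w / 6, 5 * h / 6]])


@dataclass
class CalibrationSession:
    """Fixation targets (screen mm) and the eye features collected on each.

    ``feature_sets[i]`` holds the (by default 50) valid feature sets
    collected while the subject fixated ``targets[i]``.
    """

    targets: np.ndarray
    feature_sets: List[List[EyeFeatures]]
    seed_params: EyeParams = field(default_factory=EyeParams)

    def __post_init__(self) -> None:
        self.targets = np.atleast_2d(np.asarray(self.targets, float))
        if len(self.targets) < 2:
            raise CalibrationError(
                "calibration needs gaze at two or more known targets")
        if len(self.feature_sets) != len(self.targets):
            raise CalibrationError("one feature-set list per target required")
        for sets in self.feature_sets:
            if not sets or not all(f.valid for f in sets):
                raise CalibrationError("all calibration feature sets must be valid")


@dataclass
class GazeTrack:
    """Ordered gaze estimates with validity flags."""

    timestamps: np.ndarray
    points_mm: np.ndarray          # (N, 2); rows of NaN where invalid
    valid: np.ndarray              # (N,) bool

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, float)
        self.points_mm = np.asarray(self.points_mm, float)
        self.valid = np.asarray(self.valid, bool)

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "timestamp": self.timestamps,
            "x_mm": self.points_mm[:, 0], "y_mm": self.points_mm[:, 1],
            "valid": self.valid.astype(int)}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GazeTrack":
        import pandas as pd
        df = pd.read_csv(path)
        return cls(df["timestamp"].to_numpy(),
                   df[["x_mm", "y_mm"]].to_numpy(),
                   df["valid"].to_numpy().astype(bool))


def estimate_pog(f: EyeFeatures, params: EyeParams, dev: DeviceGeometry,
                 refraction: bool = True) -> Optional[PoG]:
    """Gaze estimate for one feature set, or ``None`` for invalid features.

    Composition: reconstruct the eye state from pupil + two glints, rotate
    the optic axis into the visual axis, intersect with the screen plane.
    Geometry failures propagate as ``None`` rather than exceptions so that
    streaming pipelines degrade gracefully.
    """
    if not f.valid:
        return None
    try:
        eye = reconstruct_eye_state(f, params, dev, refraction=refraction)
        return intersect_screen(eye, visual_axis(eye, params), dev)
    except GeometryError:
        return None


def _stack_session(sess: CalibrationSession):
    pupils, gas, gbs, targets = [], [], [], []
    for target, sets in zip(sess.targets, sess.feature_sets):
        for f in sets:
            pupils.append(f.pupil)
            gas.append(f.glint_a)
            gbs.append(f.glint_b)
            targets.append(target)
    return (np.asarray(pupils, float), np.asarray(gas, float),
            np.asarray(gbs, float), np.asarray(targets, float))


def _session_residuals(x: np.ndarray, stacked, dev: DeviceGeometry,
                       refraction: bool) -> np.ndarray:
    pupils, gas, gbs, targets = stacked
    try:
        params = EyeParams.from_array(x)
    except ValueError:
        return np.full(2 * len(targets), 1e3)
    pog = estimate_pog_batch(pupils, gas, gbs, params, dev,
                             refraction=refraction)
    res = pog - targets
    res[~np.isfinite(res)] = 1e3
    return res.ravel()


def calibrate(sess: CalibrationSession, dev: DeviceGeometry,
              refraction: bool = True, max_iter: int = 200
              ) -> Tuple[EyeParams, float]:
    """Levenberg-Marquardt estimation of the four eye parameters.

    Each collected feature set contributes its own gaze-to-target residual
    (no pre-averaging).  Returns the fitted parameters and the final
    objective: the mean Euclidean gaze-to-target distance in mm.

    R and K are weakly identified under feature noise (they trade off
    along the depth direction with little effect on the gaze itself), so
    an unbounded fit can drift to unphysiological values; if that happens
    the fit is repeated with a bounded trust-region step from the same
    seed, keeping the parameters in physiological ranges.
    """
    x0 = sess.seed_params.as_array()
    stacked = _stack_session(sess)
    lo = np.array([6.0, 3.0, -12.0, -12.0])
    hi = np.array([10.0, 6.0, 12.0, 12.0])
    try:
        fit = least_squares(
            _session_residuals, x0, args=(stacked, dev, refraction),
            method="lm", diff_step=1e-6, xtol=1e-12, ftol=1e-12, gtol=1e-12,
            max_nfev=max_iter * (len(x0) + 1))
        if not np.all(np.isfinite(fit.x)) or np.any(fit.x < lo) or \
                np.any(fit.x > hi):
            fit = least_squares(
                _session_residuals, x0, args=(stacked, dev, refraction),
                method="trf", bounds=(lo, hi), diff_step=1e-6,
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                max_nfev=max_iter * (len(x0) + 1))
    except Exception as e:  # scipy signals, e.g., invalid residual shapes
        raise CalibrationError(f"calibration failed: {e}") from e
    if not np.all(np.isfinite(fit.x)):
        raise CalibrationError("calibration did not converge")
    params = EyeParams.from_array(fit.x)
    r = fit.fun.reshape(-1, 2)
    residual = float(np.sqrt((r ** 2).sum(axis=1)).mean())
    return params, residual


def moving_average(track: GazeTrack, n: int) -> GazeTrack:
    """Average each run of ``n`` consecutive estimates into one.

    Windowing convention: a track of S raw samples yields S - n averaged
    estimates (the first raw sample is discarded and windows slide over the
    remainder), matching the published bookkeeping in which 15 raw
    estimates produce 11 four-sample averages.  Invalid raw samples
    invalidate every window containing them.
    """
    if n < 1:
        raise ValueError("window must be >= 1")
    s = len(track)
    if n >= s:
        raise ValueError(f"window n={n} needs a track longer than n (S={s})")
    pts = track.points_mm[1:]
    val = track.valid[1:]
    ts = track.timestamps[1:]
    m = s - n
    out_pts = np.full((m, 2), np.nan)
    out_val = np.zeros(m, bool)
    out_ts = np.empty(m)
    for i in range(m):
        w_val = val[i:i + n]
        out_ts[i] = ts[i + n - 1]
        if w_val.all():
            out_pts[i] = track.points_mm[1:][i:i + n].mean(axis=0)
            out_val[i] = True
    return GazeTrack(out_ts, out_pts, out_val)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def _geometry_hash(dev: DeviceGeometry) -> str:
    from dataclasses import asdict
    blob = json.dumps(asdict(dev), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_calibration(path, subject: str, params: EyeParams, residual: float,
                     dev: DeviceGeometry) -> None:
    """Persist a calibration (eye parameters are stable physiology and are
    reusable across sessions on the same device geometry)."""
    rec = {"subject": subject,
           "params": {"R": params.R, "K": params.K,
                      "alpha_h": params.alpha_h, "alpha_v": params.alpha_v},
           "residual_mm": residual,
           "device_hash": _geometry_hash(dev)}
    Path(path).write_text(json.dumps(rec, indent=2))


def load_calibration(path, dev: Optional[DeviceGeometry] = None
                     ) -> Tuple[str, EyeParams, float]:
    rec = json.loads(Path(path).read_text())
    if dev is not None and rec["device_hash"] != _geometry_hash(dev):
        raise CalibrationError(
            "calibration was made on a different device geometry")
    p = rec["params"]
    return rec["subject"], EyeParams(p["R"], p["K"], p["alpha_h"], p["alpha_v"]), \
        rec["residual_mm"]
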