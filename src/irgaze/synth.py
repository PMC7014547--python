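"""Synthetic infrared eye-region rendering with exact ground truth.

No public dataset of IR smartphone eye regions with labeled pupil/glint
positions exists, so every downstream stage (classifier, position networks,
calibration, end-to-end evaluation) is exercised on synthetic data rendered
by this module.  The renderer is deliberately simple but sub-pixel exact:

* bright sclera, mid-gray iris disk, dark elliptical pupil, all drawn with
  ~1 px anti-aliased edges so that sub-pixel positions are observable;
* one Gaussian specular spot per enabled IR LED at the glint position given
  by the 3D corneal-reflection model;
* optional upper-eyelid occlusion (blinks), Gaussian optical blur, motion
  blur, and additive Gaussian sensor noise.

Dataset generation emulates the statistical structure of a handheld-phone
collection: per subject a fixed appearance, per frame a fresh device pose
(eye-camera distance 200-400 mm) and fixation target, a random subset of
frames captured with one or both LEDs disabled, natural invalid frames from
blinks and heavy motion blur (the class balance lands near 55/45
valid/invalid), ten random-offset crops per labeled region, and a
subject-disjoint 80/20 train/validation split.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .geometry import (DeviceGeometry, EyeFeatures, EyeParams, EyeState,
                       forward_features, optic_axis_from_visual)

__all__ = [
    "RenderConfig",
    "Appearance",
    "LabeledRegion",
    "SyntheticDataset",
    "render_region",
    "sample_appearance",
    "generate_dataset",
    "quantization_error_model",
    "fit_pupil_ellipse",
]

_CROP_SIZES = (64, 96, 128, 256)


@dataclass
class RenderConfig:
    """Ranges and switches governing synthetic eye-region appearance.

    Radii are in native full-frame pixels; the dataset generator derives
    them from physical radii (mm) and the sampled eye-camera distance, then
    clips into these ranges.  Contrasts are relative drops in (0, 1]: the
    iris level is ``sclera*(1-iris_sclera_contrast)`` and the pupil level
    ``iris*(1-pupil_iris_contrast)``; the low end of the pupil-iris range
    emulates the weak contrast of light (blue) irises under IR.
    """

    crop_size: int = 64
    iris_radius_px: Tuple[float, float] = (34.0, 82.0)
    pupil_radius_px: Tuple[float, float] = (6.0, 26.0)
    glint_sigma_px: Tuple[float, float] = (0.9, 1.6)
    pupil_iris_contrast: Tuple[float, float] = (0.35, 0.8)
    iris_sclera_contrast: Tuple[float, float] = (0.3, 0.55)
    sensor_noise_sd: Tuple[float, float] = (0.005, 0.02)
    blur_kernel_px: Tuple[float, float] = (0.0, 0.8)
    eyelid_occlusion_fraction: Tuple[float, float] = (0.0, 0.15)
    blink_occlusion_fraction: Tuple[float, float] = (0.5, 1.0)
    heavy_blur_px: Tuple[float, float] = (2.5, 4.0)
    blur_invalid_px: float = 1.5
    occlusion_invalid_fraction: float = 0.25
    leds_on: Tuple[bool, bool] = (True, True)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop_size not in _CROP_SIZES:
            raise ValueError(f"crop_size must be one of {_CROP_SIZES}")
        for name in ("pupil_iris_contrast", "iris_sclera_contrast"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi <= 1):
                raise ValueError(f"{name} range must lie in (0, 1]")


@dataclass
class Appearance:
    """Per-region photometric parameters (held fixed across augmentation
    crops of the same underlying eye region)."""

    pupil_radius_px: float
    iris_radius_px: float
    sclera_level: float
    iris_level: float
    pupil_level: float
    skin_level: float
    pupil_axis_ratio: float  # minor/major, foreshortening of off-axis gaze
    pupil_angle: float       # rad, ellipse orientation
    glint_sigma_px: float
    glint_amp: float
    occlusion_fraction: float
    blur_sigma_px: float
    motion_blur_px: int      # 1 = none
    motion_axis: int         # 0 vertical, 1 horizontal
    noise_sd: float


def sample_appearance(cfg: RenderConfig, rng: np.random.Generator,
                      pupil_radius_px: Optional[float] = None,
                      iris_radius_px: Optional[float] = None,
                      blink: bool = False, heavy_blur: bool = False) -> Appearance:
    """Draw photometric parameters for one region from the config ranges."""
    u = rng.uniform
    sclera = u(0.65, 0.9)
    iris = sclera * (1.0 - u(*cfg.iris_sclera_contrast))
    pupil = iris * (1.0 - u(*cfg.pupil_iris_contrast))
    occ = u(*(cfg.blink_occlusion_fraction if blink else cfg.eyelid_occlusion_fraction))
    blur = u(*(cfg.heavy_blur_px if heavy_blur else cfg.blur_kernel_px))
    motion = int(u(5, 9)) if heavy_blur and u() < 0.5 else 1
    return Appearance(
        pupil_radius_px=float(pupil_radius_px if pupil_radius_px is not None
                              else u(*cfg.pupil_radius_px)),
        iris_radius_px=float(iris_radius_px if iris_radius_px is not None
                             else u(*cfg.iris_radius_px)),
        sclera_level=sclera, iris_level=iris, pupil_level=pupil,
        skin_level=sclera * u(0.78, 0.92),
        pupil_axis_ratio=u(0.88, 1.0), pupil_angle=u(0, math.pi),
        glint_sigma_px=u(*cfg.glint_sigma_px), glint_amp=u(0.75, 1.0),
        occlusion_fraction=occ, blur_sigma_px=float(blur),
        motion_blur_px=motion, motion_axis=int(rng.integers(0, 2)),
        noise_sd=u(*cfg.sensor_noise_sd))


@dataclass
class LabeledRegion:
    """A cropped eye image with exact labels in full-frame pixel coordinates."""

    image: np.ndarray             # (crop, crop) float32 in [0, 1]
    crop_offset: np.ndarray      # full-frame px of the crop's top-left pixel
    scale: float                  # down-scaling applied after cropping (1 = none)
    label_class: str              # "valid" | "invalid"
    pupil: Optional[np.ndarray]
    glint_a: Optional[np.ndarray]
    glint_b: Optional[np.ndarray]
    boundary_points: Optional[np.ndarray] = None  # (10, 2) on the pupil rim
    subject: int = -1

    @property
    def valid(self) -> bool:
        return self.label_class == "valid"


def _segment_fraction(t: float) -> float:
    """Fraction of an ellipse's area above a horizontal cut at normalized
    height t in [0, 1] measured from the top edge (exact for any ellipse)."""
    c = 1.0 - 2.0 * t
    c = max(-1.0, min(1.0, c))
    return (math.acos(c) - c * math.sqrt(1.0 - c * c)) / math.pi


def _eyelid_cut_y(frac: float, pupil_y: float, half_height: float) -> float:
    """Full-frame y of the eyelid edge occluding ``frac`` of the pupil."""
    if frac <= 0:
        return pupil_y - half_height - 8.0  # well above the pupil
    if frac >= 1:
        return pupil_y + half_height + 8.0
    t = brentq(lambda t: _segment_fraction(t) - frac, 0.0, 1.0, xtol=1e-9)
    return pupil_y - half_height + 2.0 * half_height * t


def render_region(truth: EyeFeatures, cfg: RenderConfig,
                  rng: Optional[np.random.Generator] = None,
                  appearance: Optional[Appearance] = None,
                  crop_offset: Optional[Sequence[float]] = None,
                  leds_on: Optional[Tuple[bool, bool]] = None,
                  subject: int = -1) -> LabeledRegion:
    """Render one eye-region crop around the true pupil center.

    ``truth`` supplies sub-pixel feature positions in full-frame px (a glint
    set to ``None`` means the matching LED is disabled).  The crop is
    centered on the pupil plus a random offset within +-crop/8 unless
    ``crop_offset`` pins it.  Deterministic given the generator state.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if truth.pupil is None:
        raise ValueError("truth must contain a pupil position")
    ap = appearance if appearance is not None else sample_appearance(cfg, rng)

    n = cfg.crop_size
    pupil = np.asarray(truth.pupil, float)
    if leds_on is None:
        leds_on = cfg.leds_on
    present = [pupil] + [np.asarray(g, float)
                         for g, on in ((truth.glint_a, leds_on[0]),
                                       (truth.glint_b, leds_on[1]))
                         if on and g is not None]
    if crop_offset is None:
        off = rng.uniform(-n / 8, n / 8, size=2)
        crop_offset = np.round(pupil + off - (n - 1) / 2.0)
        # keep every labeled feature inside the crop (the feature bounding
        # box is capped well below the crop size, so this is always feasible)
        lo = np.max([p for p in present], axis=0) - (n - 1) + 0.5
        hi = np.min([p for p in present], axis=0) - 0.5
        crop_offset = np.round(np.clip(crop_offset, lo, hi))
    crop_offset = np.asarray(crop_offset, float)

    ys = crop_offset[1] + np.arange(n)[:, None]
    xs = crop_offset[0] + np.arange(n)[None, :]

    img = np.full((n, n), ap.sclera_level, np.float32)

    # iris disk (anti-aliased, ~concentric with the pupil)
    iris_c = pupil + rng.uniform(-2, 2, size=2)
    d_iris = ap.iris_radius_px - np.hypot(xs - iris_c[0], ys - iris_c[1])
    w = np.clip(d_iris + 0.5, 0.0, 1.0)
    img = img * (1 - w) + ap.iris_level * w

    # elliptical pupil
    a = ap.pupil_radius_px
    b = ap.pupil_radius_px * ap.pupil_axis_ratio
    ca, sa = math.cos(ap.pupil_angle), math.sin(ap.pupil_angle)
    xr = (xs - pupil[0]) * ca + (ys - pupil[1]) * sa
    yr = -(xs - pupil[0]) * sa + (ys - pupil[1]) * ca
    q = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    d_pup = (1.0 - q) * math.sqrt(a * b)
    w = np.clip(d_pup + 0.5, 0.0, 1.0)
    img = img * (1 - w) + ap.pupil_level * w

    # glints: Gaussian specular spots, only for enabled LEDs
    half_h = b * abs(ca) + a * abs(sa)  # pupil vertical half-extent
    lid_y = _eyelid_cut_y(ap.occlusion_fraction, pupil[1], half_h)
    glints: Dict[str, Optional[np.ndarray]] = {"a": None, "b": None}
    occluded_glint = False
    for key, pos, on in (("a", truth.glint_a, leds_on[0]),
                         ("b", truth.glint_b, leds_on[1])):
        if not on or pos is None:
            continue
        pos = np.asarray(pos, float)
        if pos[1] < lid_y:  # hidden behind the upper eyelid
            occluded_glint = True
            continue
        r2 = (xs - pos[0]) ** 2 + (ys - pos[1]) ** 2
        img = img + ap.glint_amp * np.exp(-r2 / (2 * ap.glint_sigma_px ** 2))
        glints[key] = pos

    # upper eyelid (skin band with a soft edge), drawn above everything
    w = np.clip(lid_y - ys + 0.5, 0.0, 1.0)
    img = img * (1 - w) + ap.skin_level * w

    if ap.blur_sigma_px > 0.05:
        img = ndimage.gaussian_filter(img, ap.blur_sigma_px, mode="nearest")
    if ap.motion_blur_px > 1:
        img = ndimage.uniform_filter1d(img, ap.motion_blur_px,
                                       axis=ap.motion_axis, mode="nearest")
    if ap.noise_sd > 0:
        img = img + rng.normal(0.0, ap.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    valid = (glints["a"] is not None and glints["b"] is not None
             and not occluded_glint
             and ap.occlusion_fraction <= cfg.occlusion_invalid_fraction
             and ap.blur_sigma_px <= cfg.blur_invalid_px
             and ap.motion_blur_px <= 3)

    angles = np.sort(rng.uniform(0, 2 * math.pi, 10))
    bx = pupil[0] + a * np.cos(angles) * ca - b * np.sin(angles) * sa
    by = pupil[1] + a * np.cos(angles) * sa + b * np.sin(angles) * ca
    boundary = np.stack([bx, by], axis=1)

    return LabeledRegion(
        image=img, crop_offset=crop_offset, scale=1.0,
        label_class="valid" if valid else "invalid",
        pupil=pupil, glint_a=glints["a"], glint_b=glints["b"],
        boundary_points=boundary, subject=subject)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """Labeled eye-region crops with a subject-disjoint train/val split."""

    samples: List[LabeledRegion]
    train_subjects: List[int]
    val_subjects: List[int]
    n_base_regions: int

    def subset(self, split: str, valid_only: bool = False) -> List[LabeledRegion]:
        subjects = set(self.train_subjects if split == "train" else self.val_subjects)
        out = [s for s in self.samples if s.subject in subjects]
        if valid_only:
            out = [s for s in out if s.valid]
        return out

    @property
    def valid_fraction(self) -> float:
        base = self.samples[:: max(1, len(self.samples) // self.n_base_regions)]
        n_valid = sum(s.valid for s in self.samples)
        return n_valid / len(self.samples)

    def write_manifest(self, directory: str | Path, write_images: bool = False) -> None:
        """JSON-lines labels (+ optional PNGs) and a CSV manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        with open(directory / "labels.jsonl", "w") as fh:
            for i, s in enumerate(self.samples):
                rec = {
                    "index": i, "subject": s.subject, "class": s.label_class,
                    "crop_offset": list(map(float, s.crop_offset)),
                    "scale": s.scale,
                    "pupil": None if s.pupil is None else list(map(float, s.pupil)),
                    "glint_a": None if s.glint_a is None else list(map(float, s.glint_a)),
                    "glint_b": None if s.glint_b is None else list(map(float, s.glint_b)),
                }
                fh.write(json.dumps(rec) + "\n")
                rows.append((i, s.subject, s.label_class,
                             "train" if s.subject in set(self.train_subjects) else "val"))
                if write_images:
                    from PIL import Image
                    Image.fromarray((s.image * 255).astype(np.uint8)).save(
                        directory / f"region_{i:06d}.png")
        import pandas as pd
        pd.DataFrame(rows, columns=["index", "subject", "class", "split"]).to_csv(
            directory / "manifest.csv", index=False)


def _led_disabled_frames(n_frames: int, rng: np.random.Generator) -> Dict[int, Tuple[bool, bool]]:
    """Choose the frames captured with one or both LEDs disabled (6 of 20)."""
    n_off = max(1, round(n_frames * 6 / 20))
    idx = rng.choice(n_frames, size=n_off, replace=False)
    out = {}
    for i in idx:
        mode = rng.integers(0, 3)  # which LED(s) to disable, chosen at random
        out[int(i)] = ((False, True), (True, False), (False, False))[mode]
    return out


def generate_dataset(n_subjects: int, frames_per_subject: int,
                     cfg: Optional[RenderConfig] = None,
                     dev: Optional[DeviceGeometry] = None,
                     params: Optional[EyeParams] = None,
                     n_aug: int = 10,
                     p_blink: float = 0.13,
                     p_heavy_blur: float = 0.05,
                     val_fraction: float = 0.2,
                     max_feature_box_px: float = 58.0,
                     seed: int = 0) -> SyntheticDataset:
    """Generate a subject-disjoint synthetic eye-region dataset.

    Each frame produces two eye regions (left and right eye fixating the
    same screen target) whose feature positions come from the 3D forward
    model at a random device pose, and each region yields ``n_aug`` crops
    at random offsets near the pupil.  A random ~6/20 of each subject's
    frames are captured with one or both LEDs disabled; blinks and heavy
    motion blur supply natural invalid regions.

    ``max_feature_box_px`` caps the pupil-centered bounding box holding the
    whole pupil and both glints: poses/targets whose box would exceed it
    are resampled, emulating the envelope observed in real handheld
    collections (extreme far-corner fixations at the closest distances are
    rare in practice).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for a subject-disjoint split")
    cfg = cfg if cfg is not None else RenderConfig()
    dev = dev if dev is not None else DeviceGeometry()
    params = params if params is not None else EyeParams()
    rng = np.random.default_rng(seed)

    f_px = dev.focal_length
    samples: List[LabeledRegion] = []
    n_base = 0
    for subj in range(n_subjects):
        srng = np.random.default_rng(rng.integers(2 ** 31))
        pupil_mm = srng.uniform(1.0, 2.0)
        iris_mm = srng.uniform(5.5, 6.5)
        eye_sep = srng.uniform(58.0, 66.0)
        led_off = _led_disabled_frames(frames_per_subject, srng)
        for frame in range(frames_per_subject):
            z = srng.uniform(200.0, 400.0)
            # the face roughly faces the camera: angular offsets, not mm
            cx = z * math.tan(math.radians(srng.uniform(-2.0, 2.0)))
            cy = z * math.tan(math.radians(srng.uniform(6.0, 10.5)))
            leds_on = led_off.get(frame, (True, True))
            for attempt in range(12):
                target = np.array([srng.uniform(8, dev.screen_size[0] - 8),
                                   srng.uniform(8, dev.screen_size[1] - 8)])
                t3d = dev.screen_to_camera(target)
                truths = []
                box = 0.0
                for side in (-1, 1):
                    c = np.array([cx + side * eye_sep / 2, cy, z])
                    v = t3d - c
                    v = v / np.linalg.norm(v)
                    eye = EyeState(c, optic_axis_from_visual(v, params))
                    truth = forward_features(eye, params, dev, leds_on=leds_on)
                    truths.append(truth)
                    if truth.pupil is None:
                        continue
                    half = pupil_mm * f_px / z + 1.0
                    for g in (truth.glint_a, truth.glint_b):
                        if g is not None:
                            half = max(half, abs(g[0] - truth.pupil[0]),
                                       abs(g[1] - truth.pupil[1]))
                    box = max(box, 2 * half + 2)
                if box <= max_feature_box_px:
                    break
            for truth in truths:
                if truth.pupil is None:
                    continue
                n_base += 1
                blink = srng.uniform() < p_blink
                heavy = srng.uniform() < p_heavy_blur
                ap = sample_appearance(
                    cfg, srng,
                    pupil_radius_px=np.clip(pupil_mm * f_px / z, *cfg.pupil_radius_px),
                    iris_radius_px=np.clip(iris_mm * f_px / z, *cfg.iris_radius_px),
                    blink=blink, heavy_blur=heavy)
                for _ in range(n_aug):
                    samples.append(render_region(
                        truth, cfg, rng=srng, appearance=ap,
                        leds_on=leds_on, subject=subj))

    order = rng.permutation(n_subjects)
    n_val = max(1, round(n_subjects * val_fraction))
    val_subjects = sorted(int(s) for s in order[:n_val])
    train_subjects = sorted(int(s) for s in order[n_val:])
    return SyntheticDataset(samples=samples, train_subjects=train_subjects,
                            val_subjects=val_subjects, n_base_regions=n_base)


# ---------------------------------------------------------------------------
# labeling-noise models
# ---------------------------------------------------------------------------


def quantization_error_model(n_samples: int, seed: int = 0,
                             step: float = 1.0) -> Tuple[float, float]:
    """Single-click labeling quantization error model.

    Clicks round a continuously varying feature position to the nearest
    pixel on each axis, so per-axis errors are ~U(-step/2, step/2) with
    mean absolute error step/4 (0.25 px at unit step).  Returns the Monte
    Carlo per-axis mean absolute error (averaged over x and y) and the
    quadrature combination of the two per-axis means
    (sqrt(mx^2 + my^2) ~ 0.354 px).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, 1000.0, size=(n_samples, 2))
    if step <= 0:
        return 0.0, 0.0
    err = np.round(pos / step) * step - pos
    per_axis = np.mean(np.abs(err), axis=0)
    combined = float(np.hypot(per_axis[0], per_axis[1]))
    return float(per_axis.mean()), combined


def fit_pupil_ellipse(boundary_points: np.ndarray) -> np.ndarray:
    """Least-squares ellipse fit to clicked pupil-iris boundary points;
    returns the fitted center (the ground-truth pupil labeling procedure)."""
    pts = np.asarray(boundary_points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need at least 5 boundary points")
    from skimage.measure import EllipseModel

    model = EllipseModel.from_estimate(pts)
    if not model or not np.all(np.isfinite(model.center)):
        raise ValueError("degenerate boundary points: ellipse fit failed")
    return np.asarray(model.center, float)
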