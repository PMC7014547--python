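"""3D spherical-cornea gaze geometry.

Forward and inverse model linking the pose of an eye and four
subject-specific parameters to image-plane feature positions (pupil center
and two corneal reflections) and to the point-of-gaze (PoG) on the device
screen.

Conventions
-----------
* Camera frame: right-handed, origin at the camera nodal point, ``x`` to the
  right, ``y`` down, ``z`` from the camera toward the user (all mm).
* Image: ideal pinhole, zero distortion.  Pixel coordinates are 0-based with
  the origin at the top-left pixel center, continuous at sub-pixel
  resolution: ``u = f * X/Z + cx``.
* The screen lies in a plane given by an origin point and two orthonormal
  in-plane axes; PoG is reported in mm along those axes.

The glint (corneal reflection) is the virtual image of an IR LED formed by
specular reflection off the spherical front corneal surface; it is solved in
the plane containing the LED, the camera nodal point and the center of
corneal curvature by 1-D bisection on the reflection-law residual.  The
pupil center is imaged either through refraction at the corneal surface
(effective aqueous index 1.3375, the standard keratometric value) or, in a
flagged simplified mode, by direct projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "EyeParams",
    "DeviceGeometry",
    "EyeState",
    "EyeFeatures",
    "PoG",
    "GeometryError",
    "NoSolutionError",
    "IllConditionedError",
    "ParallelRayError",
    "glint_image_position",
    "pupil_image_position",
    "forward_features",
    "reconstruct_eye_state",
    "visual_axis",
    "optic_axis_from_visual",
    "intersect_screen",
    "bias_deg",
    "AQUEOUS_INDEX",
]

AQUEOUS_INDEX = 1.3375  # effective corneal/aqueous refractive index


class GeometryError(RuntimeError):
    """Base class for geometric failure modes."""


class NoSolutionError(GeometryError):
    """No physically meaningful solution (eye behind camera, occluded...)."""


class IllConditionedError(GeometryError):
    """The inverse problem is numerically degenerate (e.g. coincident glints)."""


class ParallelRayError(GeometryError):
    """Gaze ray parallel to the screen plane."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class EyeParams:
    """Subject-specific eye geometry estimated by calibration.

    R       -- corneal radius of curvature (mm)
    K       -- distance from the center of corneal curvature to the pupil
               center (mm)
    alpha_h -- horizontal offset angle between optical and visual axis (deg)
    alpha_v -- vertical offset angle between optical and visual axis (deg)
    """

    R: float = 7.8
    K: float = 4.2
    alpha_h: float = 5.0
    alpha_v: float = 1.5

    def __post_init__(self) -> None:
        if not (self.R > 0 and self.K > 0):
            raise ValueError("R and K must be positive")
        if not (abs(self.alpha_h) < 15 and abs(self.alpha_v) < 15):
            raise ValueError("axis offset angles must satisfy |alpha| < 15 deg")

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.K, self.alpha_h, self.alpha_v], float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "EyeParams":
        return cls(float(a[0]), float(a[1]), float(a[2]), float(a[3]))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


@dataclass
class DeviceGeometry:
    """Camera intrinsics, IR LED positions and screen pose (camera frame).

    The default models a 5-inch prototype handset: 4K front camera with a
    75 degree horizontal field of view, a 115.2 x 64.8 mm active display
    area below the camera, and two IR LEDs near the top-right and
    bottom-left corners of the display.
    """

    focal_length: float = 1920.0 / math.tan(math.radians(37.5))
    principal_point: Tuple[float, float] = (1919.5, 1079.5)
    image_size: Tuple[int, int] = (3840, 2160)
    pixel_pitch: float = 0.0008  # mm per px on sensor (informational)
    led_a: Tuple[float, float, float] = (57.6, 8.0, 0.0)      # top-right
    led_b: Tuple[float, float, float] = (-57.6, 72.8, 0.0)    # bottom-left
    screen_origin: Tuple[float, float, float] = (-57.6, 8.0, 0.0)
    screen_x_axis: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    screen_y_axis: Tuple[float, float, float] = (0.0, 1.0, 0.0)
    screen_size: Tuple[float, float] = (115.2, 64.8)
    fov: float = 75.0

    def __post_init__(self) -> None:
        sx = np.asarray(self.screen_x_axis, float)
        sy = np.asarray(self.screen_y_axis, float)
        if abs(np.linalg.norm(sx) - 1) > 1e-9 or abs(np.linalg.norm(sy) - 1) > 1e-9:
            raise ValueError("screen axes must be unit vectors")
        if abs(float(sx @ sy)) > 1e-9:
            raise ValueError("screen axes must be orthogonal")

    # -- convenience -------------------------------------------------------
    def project(self, p: np.ndarray) -> np.ndarray:
        """Pinhole projection of a 3D camera-frame point (mm) to pixels."""
        p = np.asarray(p, float)
        if p[2] <= 0:
            raise NoSolutionError("point not in front of the camera")
        f = self.focal_length
        cx, cy = self.principal_point
        return np.array([f * p[0] / p[2] + cx, f * p[1] / p[2] + cy])

    def back_project(self, px: np.ndarray) -> np.ndarray:
        """Unit direction of the camera ray through an image point."""
        u, v = np.asarray(px, float)
        cx, cy = self.principal_point
        f = self.focal_length
        return _unit(np.array([(u - cx) / f, (v - cy) / f, 1.0]))

    def in_frame(self, px: np.ndarray) -> bool:
        u, v = px
        w, h = self.image_size
        return 0 <= u <= w - 1 and 0 <= v <= h - 1

    def screen_to_camera(self, pog_mm: np.ndarray) -> np.ndarray:
        o = np.asarray(self.screen_origin, float)
        return (o + pog_mm[0] * np.asarray(self.screen_x_axis, float)
                + pog_mm[1] * np.asarray(self.screen_y_axis, float))

    @property
    def screen_center_mm(self) -> np.ndarray:
        return np.asarray(self.screen_size, float) / 2.0


@dataclass
class EyeState:
    """Pose of one eye: center of corneal curvature and optic-axis direction."""

    cornea_center: np.ndarray
    optic_axis: np.ndarray

    def __post_init__(self) -> None:
        self.cornea_center = np.asarray(self.cornea_center, float)
        self.optic_axis = _unit(np.asarray(self.optic_axis, float))


@dataclass
class EyeFeatures:
    """Sub-pixel image features of one eye region (full-frame pixels)."""

    pupil: Optional[np.ndarray]
    glint_a: Optional[np.ndarray]
    glint_b: Optional[np.ndarray]
    valid: bool

    def with_noise(self, sd_px: float, rng: np.random.Generator) -> "EyeFeatures":
        """A copy with isotropic Gaussian noise added to every feature."""

        def nz(p):
            return None if p is None else np.asarray(p, float) + rng.normal(0, sd_px, 2)

        return EyeFeatures(nz(self.pupil), nz(self.glint_a), nz(self.glint_b), self.valid)


@dataclass
class PoG:
    """Point-of-gaze on the screen plane (mm; optionally display px)."""

    screen_mm: np.ndarray
    screen_px: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def _plane_basis(c: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Orthonormal in-plane basis (ex toward a) of the plane through c, a, b.

    Returns (ex, ey) or raises ValueError when the three points are
    (near-)collinear; callers handle that case by axial symmetry.
    """
    w1 = a - c
    w2 = b - c
    n = np.cross(w1, w2)
    if np.linalg.norm(n) < 1e-9 * np.linalg.norm(w1) * np.linalg.norm(w2):
        raise ValueError("collinear")
    ex = _unit(w1)
    ey = _unit(w2 - (w2 @ ex) * ex)
    return ex, ey


def glint_image_position(led: Sequence[float], eye: EyeState, params: EyeParams,
                         dev: DeviceGeometry) -> np.ndarray:
    """Image position of the corneal reflection of one LED.

    Solves, in the plane containing the LED, the camera nodal point and the
    cornea center, for the point on the corneal sphere where the LED ray
    reflects into the nodal point (law of reflection), then projects that
    point.  Bisection on the reflection-law residual to 1e-12 rad.
    """
    c = np.asarray(eye.cornea_center, float)
    led = np.asarray(led, float)
    R = params.R
    if c[2] <= 0:
        raise NoSolutionError("eye behind the camera")
    o = np.zeros(3)  # nodal point
    try:
        ex, ey = _plane_basis(c, o, led)
    except ValueError:
        # LED on the camera-cornea axis: reflection point at the near pole
        p = c + R * _unit(o - c)
        return dev.project(p)

    o2 = np.array([(o - c) @ ex, (o - c) @ ey])
    l2 = np.array([(led - c) @ ex, (led - c) @ ey])

    def residual(theta: float) -> float:
        s = R * np.array([math.cos(theta), math.sin(theta)])
        n2 = np.array([math.cos(theta), math.sin(theta)])
        vi = o2 - s
        vl = l2 - s
        vi = vi / np.linalg.norm(vi)
        vl = vl / np.linalg.norm(vl)
        bis = vi + vl
        return n2[0] * bis[1] - n2[1] * bis[0]

    theta_l = math.atan2(l2[1], l2[0])
    lo, hi = 0.0, theta_l
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo == 0.0:
        theta = lo
    elif f_hi == 0.0:
        theta = hi
    else:
        if f_lo * f_hi > 0:
            raise NoSolutionError("no reflection point between camera and LED poles")
        while abs(hi - lo) > 1e-12:
            mid = 0.5 * (lo + hi)
            f_mid = residual(mid)
            if f_mid == 0.0:
                lo = hi = mid
            elif f_lo * f_mid <= 0:
                hi, f_hi = mid, f_mid
            else:
                lo, f_lo = mid, f_mid
        theta = 0.5 * (lo + hi)

    p = c + R * (math.cos(theta) * ex + math.sin(theta) * ey)
    if (p - o) @ (p - c) >= 0:
        raise NoSolutionError("reflection point on the occluded hemisphere")
    return dev.project(p)


def _refract(d: np.ndarray, m: np.ndarray, n1: float, n2: float) -> np.ndarray:
    """Snell refraction of unit direction ``d`` at a surface with unit normal
    ``m`` (oriented against ``d``); returns the refracted unit direction."""
    eta = n1 / n2
    cos_i = -float(m @ d)
    sin2_t = eta * eta * (1.0 - cos_i * cos_i)
    if sin2_t > 1.0:
        raise NoSolutionError("total internal reflection")
    return eta * d + (eta * cos_i - math.sqrt(1.0 - sin2_t)) * m


def pupil_image_position(eye: EyeState, params: EyeParams, dev: DeviceGeometry,
                         refraction: bool = True) -> np.ndarray:
    """Image position of the pupil center.

    The pupil center sits a distance ``K`` from the cornea center along the
    optic axis.  With ``refraction=True`` (default) it is imaged through the
    spherical corneal surface with effective index 1.3375; with
    ``refraction=False`` it is projected directly (a flagged simplified mode
    used for unit tests and fast paths).
    """
    c = np.asarray(eye.cornea_center, float)
    p = c + params.K * eye.optic_axis
    if not refraction:
        return dev.project(p)

    R = params.R
    o = np.zeros(3)
    try:
        ex, ey = _plane_basis(c, o, p)
    except ValueError:
        # pupil on the camera-cornea axis: by symmetry the refraction point
        # is the near pole and the image coincides with the axial projection
        s = c + R * _unit(o - c)
        return dev.project(s)

    o2 = np.array([(o - c) @ ex, (o - c) @ ey])
    q2 = np.array([(p - c) @ ex, (p - c) @ ey])

    def residual2(theta: float) -> float:
        s = R * np.array([math.cos(theta), math.sin(theta)])
        m = np.array([math.cos(theta), math.sin(theta)])
        d = s - o2
        d = d / np.linalg.norm(d)
        m_in = m if (m @ d) < 0 else -m
        eta = 1.0 / AQUEOUS_INDEX
        cos_i = -float(m_in @ d)
        sin2_t = eta * eta * (1.0 - cos_i * cos_i)
        d2 = eta * d + (eta * cos_i - math.sqrt(max(0.0, 1.0 - sin2_t))) * m_in
        w = q2 - s
        return d2[0] * w[1] - d2[1] * w[0]

    theta_q = math.atan2(q2[1], q2[0])
    # scan a bracket between the camera pole (theta=0) and past the pupil
    lo_s, hi_s = min(0.0, theta_q) - 0.3, max(0.0, theta_q) + 0.3
    grid = np.linspace(lo_s, hi_s, 241)
    vals = [residual2(t) for t in grid]
    bracket = None
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            bracket = (grid[i], grid[i])
            break
        if vals[i] * vals[i + 1] < 0:
            bracket = (grid[i], grid[i + 1])
            break
    if bracket is None:
        raise NoSolutionError("no refraction point found")
    from scipy.optimize import brentq

    if bracket[0] == bracket[1]:
        theta = bracket[0]
    else:
        theta = brentq(residual2, bracket[0], bracket[1], xtol=1e-13)
    s = c + R * (math.cos(theta) * ex + math.sin(theta) * ey)
    if (s - o) @ (s - c) >= 0:
        raise NoSolutionError("refraction point occluded")
    return dev.project(s)


def forward_features(eye: EyeState, params: EyeParams, dev: DeviceGeometry,
                     leds_on: Tuple[bool, bool] = (True, True),
                     refraction: bool = True) -> EyeFeatures:
    """Project an eye state to image features; composition of the two
    projections.  Glints are present only for enabled LEDs; the region is
    valid only when both LEDs are on and every feature lies in the frame."""
    try:
        pupil = pupil_image_position(eye, params, dev, refraction=refraction)
    except GeometryError:
        return EyeFeatures(None, None, None, False)
    glints = []
    for led, on in ((dev.led_a, leds_on[0]), (dev.led_b, leds_on[1])):
        if not on:
            glints.append(None)
            continue
        try:
            glints.append(glint_image_position(led, eye, params, dev))
        except GeometryError:
            glints.append(None)
    ga, gb = glints
    valid = (leds_on[0] and leds_on[1] and ga is not None and gb is not None
             and dev.in_frame(pupil) and dev.in_frame(ga) and dev.in_frame(gb))
    return EyeFeatures(pupil, ga, gb, bool(valid))


# ---------------------------------------------------------------------------
# inverse model
# ---------------------------------------------------------------------------


def _cornea_curve(t: np.ndarray, d: np.ndarray, led: np.ndarray, R: float) -> np.ndarray:
    """Locus of cornea centers consistent with one glint.

    For a candidate distance ``t`` of the reflection point along the
    back-projected glint ray ``d``, the outward surface normal bisects the
    directions to the camera and to the LED, so the cornea center is
    ``P - R * n``.  Vectorized over ``t`` (shape (...,)).
    """
    t = np.asarray(t, float)[..., None]
    P = t * d  # (...,3)
    vi = -d / np.linalg.norm(d)  # toward camera (constant)
    vl = led - P
    vl = vl / np.linalg.norm(vl, axis=-1, keepdims=True)
    n = vi + vl
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    return P - R * n


def _recover_cornea(f: EyeFeatures, params: EyeParams, dev: DeviceGeometry,
                    t0: float = 300.0) -> np.ndarray:
    """Cornea center from the two glints given R (Gauss-Newton on the two
    reflection-point distances; least-squares intersection of the curves)."""
    ga, gb = np.asarray(f.glint_a, float), np.asarray(f.glint_b, float)
    if np.linalg.norm(ga - gb) < 0.25:
        raise IllConditionedError("glints coincident: cornea center unobservable")
    da = dev.back_project(ga)
    db = dev.back_project(gb)
    la = np.asarray(dev.led_a, float)
    lb = np.asarray(dev.led_b, float)
    R = params.R
    x = np.array([t0, t0], float)
    eps = 1e-5
    for _ in range(60):
        Fa = _cornea_curve(x[0], da, la, R)
        Fb = _cornea_curve(x[1], db, lb, R)
        r = Fa - Fb
        Ja = (_cornea_curve(x[0] + eps, da, la, R) - Fa) / eps
        Jb = -(_cornea_curve(x[1] + eps, db, lb, R) - Fb) / eps
        J = np.stack([Ja, Jb], axis=1)  # (3,2)
        JtJ = J.T @ J
        if np.linalg.cond(JtJ) > 1e12:
            raise IllConditionedError("glint constraints near-parallel")
        step = np.linalg.solve(JtJ, -J.T @ r)
        x = x + step
        if np.linalg.norm(step) < 1e-10:
            break
    Fa = _cornea_curve(x[0], da, la, R)
    Fb = _cornea_curve(x[1], db, lb, R)
    if np.linalg.norm(Fa - Fb) > 1.0:
        raise IllConditionedError("glint constraints do not intersect")
    return 0.5 * (Fa + Fb)


def _recover_axis(pupil_px: np.ndarray, c: np.ndarray, params: EyeParams,
                  dev: DeviceGeometry, refraction: bool = True) -> np.ndarray:
    """Optic axis from the pupil image given the cornea center (closed form).

    The camera ray through the pupil image is intersected with the corneal
    sphere; with refraction the ray is bent at that surface point and
    intersected with the sphere of radius K about the cornea center, giving
    the pupil center and hence the axis.  Without refraction the ray is
    intersected with the K-sphere directly.
    """
    d = dev.back_project(pupil_px)
    K, R = params.K, params.R

    def ray_sphere(center: np.ndarray, radius: float, origin: np.ndarray,
                   direction: np.ndarray) -> float:
        oc = origin - center
        b = float(oc @ direction)
        disc = b * b - float(oc @ oc) + radius * radius
        if disc < 0:
            raise NoSolutionError("ray misses the sphere")
        return -b - math.sqrt(disc)  # near intersection

    if not refraction:
        t = ray_sphere(c, K, np.zeros(3), d)
        p = t * d
    else:
        t = ray_sphere(c, R, np.zeros(3), d)
        s = t * d
        m = (s - c) / R  # outward normal, against the incident ray
        d2 = _refract(d, -m if (m @ d) > 0 else m, 1.0, AQUEOUS_INDEX)
        u = ray_sphere(c, K, s, d2)
        p = s + u * d2
    return _unit(p - c)


def reconstruct_eye_state(f: EyeFeatures, params: EyeParams, dev: DeviceGeometry,
                          refraction: bool = True, t0: float = 300.0) -> EyeState:
    """Invert the forward model: eye pose from valid image features."""
    if not f.valid or f.pupil is None or f.glint_a is None or f.glint_b is None:
        raise ValueError("reconstruction requires valid features with both glints")
    c = _recover_cornea(f, params, dev, t0=t0)
    w = _recover_axis(np.asarray(f.pupil, float), c, params, dev, refraction=refraction)
    return EyeState(c, w)


# ---------------------------------------------------------------------------
# visual axis and screen intersection
# ---------------------------------------------------------------------------


def _dir_to_angles(v: np.ndarray) -> Tuple[float, float]:
    """(azimuth, elevation) of a gaze direction, forward being -z.

    Azimuth is positive toward +x, elevation positive upward (-y; the camera
    frame has y down).
    """
    az = math.atan2(v[0], -v[2])
    el = math.asin(max(-1.0, min(1.0, -v[1])))
    return az, el


def _angles_to_dir(az: float, el: float) -> np.ndarray:
    return np.array([math.cos(el) * math.sin(az), -math.sin(el),
                     -math.cos(el) * math.cos(az)])


def visual_axis(eye: EyeState, params: EyeParams) -> np.ndarray:
    """Rotate the optic axis by the subject's axis-offset (kappa) angles.

    Convention: the horizontal offset is applied first as an azimuth shift
    about the eye's vertical axis, then the vertical offset as an elevation
    shift about the horizontal axis of the rotated frame.  In angle space
    this is simple addition, so applying (a_h, a_v) then (-a_h, -a_v)
    returns the optic axis exactly.
    """
    az, el = _dir_to_angles(eye.optic_axis)
    return _angles_to_dir(az + math.radians(params.alpha_h),
                          el + math.radians(params.alpha_v))


def optic_axis_from_visual(v: np.ndarray, params: EyeParams) -> np.ndarray:
    """Inverse of :func:`visual_axis` (used when synthesizing fixating eyes)."""
    az, el = _dir_to_angles(np.asarray(v, float))
    return _angles_to_dir(az - math.radians(params.alpha_h),
                          el - math.radians(params.alpha_v))


def intersect_screen(eye: EyeState, v: np.ndarray, dev: DeviceGeometry) -> PoG:
    """Intersect the gaze ray from the cornea center with the screen plane."""
    v = np.asarray(v, float)
    sx = np.asarray(dev.screen_x_axis, float)
    sy = np.asarray(dev.screen_y_axis, float)
    o = np.asarray(dev.screen_origin, float)
    n = np.cross(sx, sy)
    denom = float(v @ n)
    if abs(denom) < 1e-12:
        raise ParallelRayError("gaze ray parallel to the screen plane")
    c = np.asarray(eye.cornea_center, float)
    t = float((o - c) @ n) / denom
    p = c + t * v
    rel = p - o
    return PoG(screen_mm=np.array([float(rel @ sx), float(rel @ sy)]))


def bias_deg(pog_err_mm: float, distance_mm: float) -> float:
    """Gaze bias in visual degrees from a screen-plane error at a distance."""
    if distance_mm <= 0:
        raise ValueError("distance must be positive")
    return math.degrees(math.atan(pog_err_mm / distance_mm))


# ---------------------------------------------------------------------------
# vectorized inverse pipeline (used by calibration and the evaluation
# harnesses, where thousands of feature sets are inverted per objective
# evaluation)
# ---------------------------------------------------------------------------


def _back_project_batch(px: np.ndarray, dev: DeviceGeometry) -> np.ndarray:
    cx, cy = dev.principal_point
    f = dev.focal_length
    d = np.stack([(px[:, 0] - cx) / f, (px[:, 1] - cy) / f,
                  np.ones(len(px))], axis=1)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def _cornea_curve_batch(t: np.ndarray, d: np.ndarray, led: np.ndarray,
                        R: float) -> np.ndarray:
    P = t[:, None] * d
    vl = led[None, :] - P
    vl = vl / np.linalg.norm(vl, axis=1, keepdims=True)
    n = -d + vl
    n = n / np.linalg.norm(n, axis=1, keepdims=True)
    return P - R * n


def _recover_cornea_batch(ga: np.ndarray, gb: np.ndarray, params: EyeParams,
                          dev: DeviceGeometry, t0: float = 300.0) -> np.ndarray:
    """Vectorized Gauss-Newton intersection of the two glint loci; returns
    (N, 3) cornea centers with NaN rows where the solve degenerates."""
    da = _back_project_batch(ga, dev)
    db = _back_project_batch(gb, dev)
    la = np.asarray(dev.led_a, float)
    lb = np.asarray(dev.led_b, float)
    R = params.R
    n = len(ga)
    x = np.full((n, 2), t0)
    eps = 1e-5
    bad = np.linalg.norm(ga - gb, axis=1) < 0.25
    for _ in range(60):
        Fa = _cornea_curve_batch(x[:, 0], da, la, R)
        Fb = _cornea_curve_batch(x[:, 1], db, lb, R)
        r = Fa - Fb
        Ja = (_cornea_curve_batch(x[:, 0] + eps, da, la, R) - Fa) / eps
        Jb = -(_cornea_curve_batch(x[:, 1] + eps, db, lb, R) - Fb) / eps
        # per-sample 2x2 normal equations, closed form
        a11 = (Ja * Ja).sum(1)
        a12 = (Ja * Jb).sum(1)
        a22 = (Jb * Jb).sum(1)
        b1 = -(Ja * r).sum(1)
        b2 = -(Jb * r).sum(1)
        det = a11 * a22 - a12 * a12
        bad |= np.abs(det) < 1e-12
        det = np.where(bad, 1.0, det)
        s1 = (a22 * b1 - a12 * b2) / det
        s2 = (a11 * b2 - a12 * b1) / det
        x[:, 0] += np.where(bad, 0.0, s1)
        x[:, 1] += np.where(bad, 0.0, s2)
        if max(np.abs(s1).max(initial=0), np.abs(s2).max(initial=0)) < 1e-10:
            break
    Fa = _cornea_curve_batch(x[:, 0], da, la, R)
    Fb = _cornea_curve_batch(x[:, 1], db, lb, R)
    bad |= np.linalg.norm(Fa - Fb, axis=1) > 1.0
    c = 0.5 * (Fa + Fb)
    c[bad] = np.nan
    return c


def _recover_axis_batch(pupil: np.ndarray, c: np.ndarray, params: EyeParams,
                        dev: DeviceGeometry, refraction: bool = True) -> np.ndarray:
    d = _back_project_batch(pupil, dev)
    K, R = params.K, params.R

    def near_root(center, radius, origin, direction):
        oc = origin - center
        b = (oc * direction).sum(1)
        disc = b * b - (oc * oc).sum(1) + radius * radius
        t = -b - np.sqrt(np.maximum(disc, 0.0))
        t[disc < 0] = np.nan
        return t

    zero = np.zeros_like(c)
    if not refraction:
        t = near_root(c, K, zero, d)
        p = t[:, None] * d
    else:
        t = near_root(c, R, zero, d)
        s = t[:, None] * d
        m = (s - c) / R
        eta = 1.0 / AQUEOUS_INDEX
        cos_i = -(m * d).sum(1)
        flip = cos_i < 0
        m[flip] *= -1.0
        cos_i = np.abs(cos_i)
        sin2_t = eta * eta * (1.0 - cos_i * cos_i)
        d2 = eta * d + (eta * cos_i - np.sqrt(np.maximum(1 - sin2_t, 0.0)))[:, None] * m
        u = near_root(c, K, s, d2)
        p = s + u[:, None] * d2
    w = p - c
    return w / np.linalg.norm(w, axis=1, keepdims=True)


def estimate_pog_batch(pupil: np.ndarray, glint_a: np.ndarray,
                       glint_b: np.ndarray, params: EyeParams,
                       dev: DeviceGeometry, refraction: bool = True
                       ) -> np.ndarray:
    """PoG (N, 2) screen mm for N feature sets; NaN rows on degeneracy.

    Vectorized composition of cornea recovery, axis recovery, the
    optical-to-visual-axis rotation and the screen intersection; agrees
    with the scalar pipeline to numerical precision.
    """
    pupil = np.atleast_2d(np.asarray(pupil, float))
    ga = np.atleast_2d(np.asarray(glint_a, float))
    gb = np.atleast_2d(np.asarray(glint_b, float))
    c = _recover_cornea_batch(ga, gb, params, dev)
    w = _recover_axis_batch(pupil, c, params, dev, refraction=refraction)
    # visual axis via azimuth/elevation shifts
    az = np.arctan2(w[:, 0], -w[:, 2]) + math.radians(params.alpha_h)
    el = np.arcsin(np.clip(-w[:, 1], -1, 1)) + math.radians(params.alpha_v)
    v = np.stack([np.cos(el) * np.sin(az), -np.sin(el),
                  -np.cos(el) * np.cos(az)], axis=1)
    sx = np.asarray(dev.screen_x_axis, float)
    sy = np.asarray(dev.screen_y_axis, float)
    o = np.asarray(dev.screen_origin, float)
    nrm = np.cross(sx, sy)
    denom = v @ nrm
    denom = np.where(np.abs(denom) < 1e-12, np.nan, denom)
    t = ((o - c) @ nrm) / denom
    p = c + t[:, None] * v
    rel = p - o
    return np.stack([rel @ sx, rel @ sy], axis=1)
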