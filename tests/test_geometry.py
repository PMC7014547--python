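"""Forward and inverse 3D eye-model geometry."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from irgaze.geometry import (AQUEOUS_INDEX, DeviceGeometry, EyeParams,
                             EyeFeatures, EyeState, IllConditionedError,
                             NoSolutionError, bias_deg, estimate_pog_batch,
                             forward_features, glint_image_position,
                             intersect_screen, optic_axis_from_visual,
                             pupil_image_position, reconstruct_eye_state,
                             visual_axis)
from irgaze.calibration import estimate_pog

from conftest import random_eye_state


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def _sphere_point(c, R, ang):
    th, ph = ang
    return c + R * np.array([math.sin(th) * math.cos(ph),
                             math.sin(th) * math.sin(ph),
                             math.cos(th)])


def glint_oracle(led, eye, params, dev):
    """Dense sampling + local refinement of the reflection-law residual on
    the corneal sphere, independent of the in-plane bisection solver."""
    c, R = eye.cornea_center, params.R
    led = np.asarray(led, float)

    def residual(ang):
        p = _sphere_point(c, R, ang)
        n = (p - c) / R
        vi = -p / np.linalg.norm(p)          # toward the camera at the origin
        vl = led - p
        vl = vl / np.linalg.norm(vl)
        bis = vi + vl
        bis = bis / np.linalg.norm(bis)
        return float(np.linalg.norm(np.cross(n, bis))) + max(0.0, -n @ vi)

    # coarse grid over the camera-facing hemisphere, then refinement
    best, best_ang = np.inf, None
    for th in np.linspace(2.4, math.pi, 60):       # z-facing pole is th=pi
        for ph in np.linspace(-math.pi, math.pi, 90, endpoint=False):
            r = residual((th, ph))
            if r < best:
                best, best_ang = r, (th, ph)
    ref = minimize(residual, best_ang, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-16})
    return dev.project(_sphere_point(c, R, ref.x))


def pupil_refraction_oracle(eye, params, dev):
    """Ray-trace: refract camera rays at densely sampled corneal surface
    points (Snell) and pick the surface point whose refracted ray passes
    through the pupil center."""
    c, R, K = eye.cornea_center, params.R, params.K
    p_true = c + K * eye.optic_axis

    def miss(ang):
        s = _sphere_point(c, R, ang)
        d = s / np.linalg.norm(s)            # camera ray toward the surface
        m = (s - c) / R
        if m @ d > 0:
            return 1e3
        eta = 1.0 / AQUEOUS_INDEX
        cos_i = -(m @ d)
        sin2 = eta ** 2 * (1 - cos_i ** 2)
        d2 = eta * d + (eta * cos_i - math.sqrt(1 - sin2)) * m
        w = p_true - s
        return float(np.linalg.norm(np.cross(d2, w)))

    best, best_ang = np.inf, None
    for th in np.linspace(2.6, math.pi, 80):
        for ph in np.linspace(-math.pi, math.pi, 120, endpoint=False):
            r = miss((th, ph))
            if r < best:
                best, best_ang = r, (th, ph)
    ref = minimize(miss, best_ang, method="Nelder-Mead",
                   options={"xatol": 1e-13, "fatol": 1e-18})
    return dev.project(_sphere_point(c, R, ref.x))


# ---------------------------------------------------------------------------
# glints
# ---------------------------------------------------------------------------

class TestGlint:
    def test_coaxial_led_projects_to_principal_point(self, dev, params):
        eye = EyeState(np.array([0.0, 0.0, 300.0]), np.array([0.0, 0.0, -1.0]))
        g = glint_image_position((0.0, 0.0, 0.0), eye, params, dev)
        assert np.allclose(g, dev.principal_point, atol=1e-9)

    def test_mirror_symmetric_leds_give_mirror_symmetric_glints(self, params):
        dev = DeviceGeometry(led_a=(40.0, 0.0, 0.0), led_b=(-40.0, 0.0, 0.0))
        eye = EyeState(np.array([0.0, 0.0, 300.0]), np.array([0.0, 0.0, -1.0]))
        ga = glint_image_position(dev.led_a, eye, params, dev)
        gb = glint_image_position(dev.led_b, eye, params, dev)
        cx = dev.principal_point[0]
        assert ga[1] == pytest.approx(gb[1], abs=1e-9)
        assert ga[0] - cx == pytest.approx(-(gb[0] - cx), abs=1e-9)

    def test_matches_dense_sampling_oracle(self, dev, params):
        rng = np.random.default_rng(0)
        for _ in range(5):
            eye, _ = random_eye_state(rng, dev, params)
            for led in (dev.led_a, dev.led_b):
                g = glint_image_position(led, eye, params, dev)
                go = glint_oracle(led, eye, params, dev)
                assert np.linalg.norm(g - go) < 0.01

    def test_reflection_law_residual_at_solution(self, dev, params):
        # solved surface point satisfies angle(in)=angle(out) to < 1e-9 rad
        rng = np.random.default_rng(1)
        for _ in range(20):
            eye, _ = random_eye_state(rng, dev, params)
            g = glint_image_position(dev.led_a, eye, params, dev)
            d = dev.back_project(g)
            # intersect the ray with the sphere to recover the surface point
            c, R = eye.cornea_center, params.R
            b = -(d @ c)
            t = -b - math.sqrt(b * b - c @ c + R * R)
            p = t * d
            n = (p - c) / R
            vi = -p / np.linalg.norm(p)
            vl = np.asarray(dev.led_a) - p
            vl /= np.linalg.norm(vl)
            assert abs(math.acos(np.clip(n @ vi, -1, 1))
                       - math.acos(np.clip(n @ vl, -1, 1))) < 1e-9

    def test_eye_behind_camera_rejected(self, dev, params):
        eye = EyeState(np.array([0.0, 0.0, -300.0]), np.array([0.0, 0.0, 1.0]))
        with pytest.raises(NoSolutionError):
            glint_image_position(dev.led_a, eye, params, dev)


# ---------------------------------------------------------------------------
# pupil projection
# ---------------------------------------------------------------------------

class TestPupilImage:
    def test_axial_gaze_lies_on_center_line(self, dev, params):
        c = np.array([10.0, 30.0, 300.0])
        eye = EyeState(c, -c / np.linalg.norm(c))  # aimed at the nodal point
        p_img = pupil_image_position(eye, params, dev, refraction=False)
        c_img = dev.project(c)
        pp = np.asarray(dev.principal_point)
        # collinear: pupil image on the ray principal point -> cornea image
        v1 = c_img - pp
        v2 = p_img - pp
        assert abs(v1[0] * v2[1] - v1[1] * v2[0]) < 1e-6

    def test_zero_K_degenerates_to_cornea_projection(self, dev):
        par = EyeParams(K=1e-12)
        c = np.array([5.0, 25.0, 280.0])
        eye = EyeState(c, np.array([0.1, -0.1, -0.98]) / np.linalg.norm([0.1, -0.1, 0.98]))
        p_img = pupil_image_position(eye, par, dev, refraction=False)
        assert np.allclose(p_img, dev.project(c), atol=1e-6)

    def test_refraction_matches_ray_trace_oracle(self, dev, params):
        rng = np.random.default_rng(2)
        for _ in range(4):
            eye, _ = random_eye_state(rng, dev, params)
            p = pupil_image_position(eye, params, dev, refraction=True)
            po = pupil_refraction_oracle(eye, params, dev)
            assert np.linalg.norm(p - po) < 0.05

    def test_refraction_shifts_the_image(self, dev, params):
        rng = np.random.default_rng(3)
        eye, _ = random_eye_state(rng, dev, params)
        with_r = pupil_image_position(eye, params, dev, refraction=True)
        without = pupil_image_position(eye, params, dev, refraction=False)
        assert 0.01 < np.linalg.norm(with_r - without) < 20.0


# ---------------------------------------------------------------------------
# forward features and reconstruction
# ---------------------------------------------------------------------------

class TestForwardInverse:
    def test_forward_features_validity_and_led_gating(self, dev, params):
        rng = np.random.default_rng(4)
        eye, _ = random_eye_state(rng, dev, params)
        f = forward_features(eye, params, dev)
        assert f.valid and f.glint_a is not None and f.glint_b is not None
        f2 = forward_features(eye, params, dev, leds_on=(True, False))
        assert not f2.valid and f2.glint_b is None and f2.glint_a is not None

    def test_round_trip_recovers_eye_state(self, dev, params):
        rng = np.random.default_rng(5)
        for _ in range(10):
            eye, _ = random_eye_state(rng, dev, params)
            f = forward_features(eye, params, dev)
            st = reconstruct_eye_state(f, params, dev)
            assert np.linalg.norm(st.cornea_center - eye.cornea_center) < 1e-3
            ang = math.acos(np.clip(st.optic_axis @ eye.optic_axis, -1, 1))
            assert ang < 1e-5

    def test_round_trip_pog_under_0p01_mm(self, dev, params):
        rng = np.random.default_rng(6)
        for _ in range(10):
            eye, target = random_eye_state(rng, dev, params)
            f = forward_features(eye, params, dev)
            pog = estimate_pog(f, params, dev)
            assert np.linalg.norm(pog.screen_mm - target) < 0.01

    def test_coincident_glints_ill_conditioned(self, dev, params):
        f = EyeFeatures(pupil=np.array([1900.0, 1300.0]),
                        glint_a=np.array([1910.0, 1310.0]),
                        glint_b=np.array([1910.0, 1310.0]), valid=True)
        with pytest.raises(IllConditionedError):
            reconstruct_eye_state(f, params, dev)

    def test_reconstruction_is_continuous_under_perturbation(self, dev, params):
        rng = np.random.default_rng(7)
        for _ in range(8):
            eye, _ = random_eye_state(rng, dev, params)
            f = forward_features(eye, params, dev)
            st0 = reconstruct_eye_state(f, params, dev)
            for _ in range(4):
                g = f.with_noise(0.5, rng)
                st = reconstruct_eye_state(g, params, dev)
                ang = math.acos(np.clip(st.optic_axis @ st0.optic_axis, -1, 1))
                assert ang < 0.05  # rad; smooth response, no branch jumps

    def test_batch_pipeline_matches_scalar(self, dev, params):
        rng = np.random.default_rng(8)
        feats, targets = [], []
        for _ in range(6):
            eye, t = random_eye_state(rng, dev, params)
            feats.append(forward_features(eye, params, dev))
            targets.append(t)
        pb = estimate_pog_batch(np.array([f.pupil for f in feats]),
                                np.array([f.glint_a for f in feats]),
                                np.array([f.glint_b for f in feats]),
                                params, dev)
        for f, row in zip(feats, pb):
            assert np.allclose(estimate_pog(f, params, dev).screen_mm, row,
                               atol=1e-6)


# ---------------------------------------------------------------------------
# visual axis, screen, bias
# ---------------------------------------------------------------------------

class TestVisualAxis:
    def test_zero_offsets_identity(self):
        par = EyeParams(alpha_h=1e-12, alpha_v=1e-12)
        w = np.array([0.1, -0.2, -0.97])
        w /= np.linalg.norm(w)
        eye = EyeState(np.array([0, 0, 300.0]), w)
        assert np.allclose(visual_axis(eye, par), w, atol=1e-9)

    def test_offsets_invert_exactly(self):
        par = EyeParams(alpha_h=5.0, alpha_v=1.5)
        neg = EyeParams(alpha_h=-5.0, alpha_v=-1.5)
        rng = np.random.default_rng(9)
        for _ in range(20):
            w = rng.normal(size=3)
            w[2] = -abs(w[2]) - 1.0
            w /= np.linalg.norm(w)
            c = np.array([0, 0, 300.0])
            v = visual_axis(EyeState(c, w), par)
            back = visual_axis(EyeState(c, v), neg)
            assert np.linalg.norm(back - w) < 1e-12

    def test_five_degree_offset_makes_five_degrees(self):
        par = EyeParams(alpha_h=5.0, alpha_v=1e-12)
        eye = EyeState(np.array([0, 0, 300.0]), np.array([0.0, 0.0, -1.0]))
        v = visual_axis(eye, par)
        ang = math.degrees(math.acos(np.clip(v @ np.array([0, 0, -1.0]), -1, 1)))
        assert ang == pytest.approx(5.0, abs=1e-9)

    def test_optic_axis_from_visual_inverts(self, params):
        rng = np.random.default_rng(10)
        for _ in range(10):
            w = rng.normal(size=3)
            w[2] = -abs(w[2]) - 1.0
            w /= np.linalg.norm(w)
            v = visual_axis(EyeState(np.zeros(3) + [0, 0, 300], w), params)
            assert np.allclose(optic_axis_from_visual(v, params), w, atol=1e-12)


class TestScreenAndBias:
    def test_normal_ray_hits_screen_center(self, dev):
        center = dev.screen_to_camera(dev.screen_center_mm)
        c = center + np.array([0.0, 0.0, 300.0])
        pog = intersect_screen(EyeState(c, [0, 0, -1.0]), np.array([0, 0, -1.0]), dev)
        assert np.allclose(pog.screen_mm, dev.screen_center_mm, atol=1e-9)

    def test_translation_parallel_to_screen_translates_pog(self, dev):
        c = np.array([0.0, 30.0, 300.0])
        v = np.array([0.0, 0.0, -1.0])
        p0 = intersect_screen(EyeState(c, v), v, dev).screen_mm
        d = np.array([7.0, -3.0])
        c2 = c + np.array([d[0], d[1], 0.0])
        p1 = intersect_screen(EyeState(c2, v), v, dev).screen_mm
        assert np.allclose(p1 - p0, d, atol=1e-9)

    def test_general_ray_matches_closed_form(self, dev, params):
        rng = np.random.default_rng(11)
        for _ in range(10):
            eye, _ = random_eye_state(rng, dev, params)
            v = visual_axis(eye, params)
            pog = intersect_screen(eye, v, dev)
            # closed form for the z=0 plane with axis-aligned screen axes
            t = -eye.cornea_center[2] / v[2]
            hit = eye.cornea_center + t * v
            expect = hit[:2] - np.asarray(dev.screen_origin[:2])
            assert np.allclose(pog.screen_mm, expect, atol=1e-9)

    def test_bias_deg_values_and_monotonicity(self):
        assert bias_deg(0.0, 300.0) == 0.0
        assert bias_deg(5.236, 300.0) == pytest.approx(1.0, abs=1e-3)
        assert bias_deg(6.0, 300.0) > bias_deg(5.0, 300.0)
        assert bias_deg(5.0, 400.0) < bias_deg(5.0, 300.0)
        with pytest.raises(ValueError):
            bias_deg(1.0, 0.0)


class TestMotionInvariance:
    def test_pog_bias_flat_over_distance_without_recalibration(self, dev, params):
        rng = np.random.default_rng(12)
        biases = []
        for z in (200, 250, 300, 350, 400):
            errs = []
            for _ in range(5):
                eye, target = random_eye_state(rng, dev, params, z=float(z))
                f = forward_features(eye, params, dev)
                pog = estimate_pog(f, params, dev)
                errs.append(np.linalg.norm(pog.screen_mm - target))
            biases.append(bias_deg(float(np.mean(errs)), z))
        assert max(biases) - min(biases) < 0.05
        assert max(biases) < 0.05
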