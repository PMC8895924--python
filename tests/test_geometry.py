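import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from femurmetrics.errors import CollinearityError, DegeneracyError
from femurmetrics.geometry import (
    angle_between,
    circumradius,
    fit_line,
    fit_sphere,
    max_deviation_point,
    mirror_x,
    projected_angle,
    rotate_about,
    skew_distance,
)
from femurmetrics.model import Axis


def random_axis(rng, span=100.0):
    d = rng.normal(size=3)
    return Axis(point=rng.uniform(-span, span, 3), direction=d / np.linalg.norm(d))


def brute_force_line_distance(a, b, half_range=300.0, n=500, refine=3):
    """Multi-resolution grid minimization of |a(s) - b(t)| (independent oracle)."""
    s_lo = t_lo = -half_range
    s_hi = t_hi = half_range
    best = np.inf
    for _ in range(refine):
        s = np.linspace(s_lo, s_hi, n)
        t = np.linspace(t_lo, t_hi, n)
        pa = a.point[None, :] + s[:, None] * a.direction[None, :]
        pb = b.point[None, :] + t[:, None] * b.direction[None, :]
        d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
        idx = np.unravel_index(np.argmin(d2), d2.shape)
        best = float(np.sqrt(d2[idx]))
        ds = (s_hi - s_lo) / (n - 1)
        dt = (t_hi - t_lo) / (n - 1)
        s_lo, s_hi = s[idx[0]] - 2 * ds, s[idx[0]] + 2 * ds
        t_lo, t_hi = t[idx[1]] - 2 * dt, t[idx[1]] + 2 * dt
    return best


class TestFitSphere:
    def test_octahedron_unit_sphere(self):
        pts = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        fit = fit_sphere(pts)
        np.testing.assert_allclose(fit.center, [0, 0, 0], atol=1e-12)
        assert fit.radius == pytest.approx(1.0, abs=1e-12)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_recovers_constructed_sphere(self, rng):
        center = np.array([3.0, -2.0, 7.0])
        dirs = rng.normal(size=(20, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        fit = fit_sphere(center + 23.0 * dirs)
        np.testing.assert_allclose(fit.center, center, atol=1e-9)
        assert fit.radius == pytest.approx(23.0, abs=1e-9)

    def test_jittered_sphere_monte_carlo(self, rng):
        # 100 reps: radius within 0.5 of truth and rms_residual ~ sigma
        sigma, radius = 0.5, 23.0
        rms_values = []
        for _ in range(100):
            dirs = rng.normal(size=(50, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            pts = radius * dirs + rng.normal(0, sigma, (50, 3))
            fit = fit_sphere(pts)
            assert abs(fit.radius - radius) < 0.5
            rms_values.append(fit.rms_residual)
        assert np.mean(rms_values) == pytest.approx(sigma, abs=0.15)

    def test_coplanar_points_degenerate(self):
        pts = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0), (2, 1, 0), (1, 2, 0)]
        with pytest.raises(DegeneracyError):
            fit_sphere(pts)

    def test_too_few_points(self):
        with pytest.raises(DegeneracyError):
            fit_sphere([(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)])


class TestFitLine:
    def test_collinear_z_axis(self):
        # ordered proximal (z high) first ... distal last -> direction (0,0,1)
        pts = [(0, 0, 10), (0, 0, 5), (0, 0, 1), (0, 0, -4)]
        axis = fit_line(pts)
        np.testing.assert_allclose(axis.direction, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(np.cross(axis.point - np.array([0, 0, 1.0]), axis.direction), 0, atol=1e-12)

    def test_two_points(self):
        axis = fit_line([(1, 1, 1), (4, 5, 1)])
        expected = np.array([-3.0, -4.0, 0.0]) / 5.0
        np.testing.assert_allclose(axis.direction, expected, atol=1e-12)

    def test_arc_direction_matches_dense_oracle(self):
        # principal direction of a symmetric circular-arc segment
        R, theta_max = 1000.0, 0.4
        theta = np.linspace(0, theta_max, 21)
        pts = np.column_stack([np.zeros_like(theta), R * np.cos(theta) - R, -R * np.sin(theta)])
        axis = fit_line(pts)
        dense = np.linspace(0, theta_max, 100_000)
        dpts = np.column_stack([np.zeros_like(dense), R * np.cos(dense) - R, -R * np.sin(dense)])
        q = dpts - dpts.mean(axis=0)
        w, v = np.linalg.eigh(q.T @ q)
        oracle = v[:, np.argmax(w)]
        assert abs(abs(float(axis.direction @ oracle)) - 1.0) < 1e-9

    def test_identical_points_degenerate(self):
        with pytest.raises(DegeneracyError):
            fit_line([(1, 2, 3)] * 5)

    def test_noise_free_residual_zero(self, rng):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        p0 = rng.normal(size=3)
        pts = p0 + np.linspace(10, -10, 7)[:, None] * d
        axis = fit_line(pts)
        resid = np.linalg.norm(np.cross(pts - axis.point, axis.direction), axis=1)
        assert resid.max() < 1e-9


class TestSkewDistance:
    def test_known_offset(self):
        a = Axis(point=[0, 0, 0], direction=[1, 0, 0])
        b = Axis(point=[0, 0, 5], direction=[0, 1, 0])
        res = skew_distance(a, b)
        assert res.distance == pytest.approx(5.0, abs=1e-12)
        np.testing.assert_allclose(res.point_on_line1, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(res.point_on_line2, [0, 0, 5], atol=1e-12)
        assert not res.parallel_flag

    def test_intersecting_lines(self):
        a = Axis(point=[0, 0, 0], direction=[1, 0, 0])
        b = Axis(point=[3, -3, 0], direction=[0, 1, 0])
        assert skew_distance(a, b).distance == pytest.approx(0.0, abs=1e-12)

    def test_parallel_lines(self):
        a = Axis(point=[0, 0, 0], direction=[1, 0, 0])
        b = Axis(point=[7, 0, 3], direction=[1, 0, 0])
        res = skew_distance(a, b)
        assert res.parallel_flag
        assert res.distance == pytest.approx(3.0, abs=1e-12)

    def test_matches_brute_force_grid(self, rng):
        for _ in range(10):
            a, b = random_axis(rng), random_axis(rng)
            res = skew_distance(a, b)
            oracle = brute_force_line_distance(a, b)
            assert res.distance == pytest.approx(oracle, abs=1e-3)

    def test_closest_points_span_distance(self, rng):
        for _ in range(20):
            a, b = random_axis(rng), random_axis(rng)
            res = skew_distance(a, b)
            gap = np.linalg.norm(res.point_on_line1 - res.point_on_line2)
            assert gap == pytest.approx(res.distance, abs=1e-9)

    def test_symmetric_and_rigid_invariant(self, rng):
        for _ in range(20):
            a, b = random_axis(rng), random_axis(rng)
            assert skew_distance(a, b).distance == pytest.approx(skew_distance(b, a).distance, abs=1e-9)
            # random rigid transform applied to both axes
            q = rng.normal(size=3)
            q /= np.linalg.norm(q)
            ang = rng.uniform(0, 2 * np.pi)
            t = rng.uniform(-50, 50, 3)
            ta = Axis(point=rotate_about(a.point, q, ang) + t, direction=rotate_about(a.direction, q, ang))
            tb = Axis(point=rotate_about(b.point, q, ang) + t, direction=rotate_about(b.direction, q, ang))
            assert skew_distance(ta, tb).distance == pytest.approx(skew_distance(a, b).distance, abs=1e-9)


class TestAngleBetween:
    def test_orthogonal(self):
        assert angle_between((1, 0, 0), (0, 1, 0)) == pytest.approx(90.0, abs=1e-12)

    def test_identical(self):
        assert angle_between((1, 0, 0), (1, 0, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_antiparallel_clamped(self):
        assert angle_between((1, 0, 0), (-1, 1e-9, 0)) == pytest.approx(180.0, abs=1e-6)

    def test_zero_vector_raises(self):
        with pytest.raises(DegeneracyError):
            angle_between((0, 0, 0), (1, 0, 0))


class TestProjectedAngle:
    def test_out_of_plane_component_ignored(self):
        u = (np.cos(np.radians(20)), np.sin(np.radians(20)), 0.5)
        ang = projected_angle(u, (1, 0, 0), (0, 0, 1), (0, 0, 1))
        assert ang == pytest.approx(20.0, abs=1e-9)

    def test_same_vector_zero(self):
        assert projected_angle((1, 2, 0.3), (1, 2, 0.3), (0, 0, 1), (0, 0, 1)) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_matrix_oracle(self, rng):
        # construct u by rotating v about the normal by a known angle
        for _ in range(50):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            v = rng.normal(size=3)
            theta = rng.uniform(-179.0, 179.0)
            u = rotate_about(v, n, np.radians(theta)) + rng.uniform(-2, 2) * n
            if np.linalg.norm(v - (v @ n) * n) < 1e-6:
                continue
            assert projected_angle(u, v, n, n) == pytest.approx(theta, abs=1e-9)

    def test_antisymmetry(self, rng):
        for _ in range(20):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            u, v = rng.normal(size=3), rng.normal(size=3)
            assert projected_angle(u, v, n, n) == pytest.approx(-projected_angle(v, u, n, n), abs=1e-9)

    def test_degenerate_projection(self):
        with pytest.raises(DegeneracyError):
            projected_angle((0, 0, 1), (1, 0, 0), (0, 0, 1), (0, 0, 1))


class TestCircumradius:
    def test_simple_triangle(self):
        res = circumradius((0, 0, 0), (2, 0, 0), (1, 1, 0))
        assert res.radius == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(res.center, [1, 0, 0], atol=1e-12)

    def test_equilateral_side_one(self):
        res = circumradius((0, 0, 0), (1, 0, 0), (0.5, np.sqrt(3) / 2, 0))
        assert res.radius == pytest.approx(1 / np.sqrt(3), abs=1e-12)

    def test_arc_samples_radius_1200(self):
        R = 1200.0
        theta = np.array([0.0, 0.17, 0.3])
        pts = np.column_stack([np.zeros(3), R * np.cos(theta), R * np.sin(theta)])
        res = circumradius(*pts)
        assert res.radius == pytest.approx(R, rel=1e-9)

    def test_center_equidistant(self, rng):
        for _ in range(20):
            pts = rng.uniform(-50, 50, (3, 3))
            try:
                res = circumradius(*pts)
            except CollinearityError:
                continue
            for p in pts:
                assert np.linalg.norm(p - res.center) == pytest.approx(res.radius, abs=1e-9)

    def test_collinear_raises(self):
        with pytest.raises(CollinearityError):
            circumradius((0, 0, 0), (1, 0, 0), (2, 0, 0))

    @settings(max_examples=50, deadline=None)
    @given(
        radius=st.floats(10.0, 5000.0),
        angles=st.tuples(st.floats(0, 6.0), st.floats(0, 6.0), st.floats(0, 6.0)),
    )
    def test_any_three_circle_points(self, radius, angles):
        a = np.sort(np.asarray(angles))
        if a[1] - a[0] < 1e-3 or a[2] - a[1] < 1e-3:
            return
        pts = np.column_stack([radius * np.cos(a), radius * np.sin(a), np.full(3, 2.0)])
        res = circumradius(*pts)
        assert res.radius == pytest.approx(radius, rel=1e-6)


class TestMaxDeviationPoint:
    def test_semicircle_apex(self):
        theta = np.linspace(0, np.pi, 31)
        pts = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        res = max_deviation_point(pts, (1, 0, 0), (-1, 0, 0))
        assert res.deviation == pytest.approx(1.0, abs=1e-12)
        assert res.index == 15

    def test_all_on_chord_tie_break(self):
        pts = np.column_stack([np.linspace(0, 10, 11), np.zeros(11), np.zeros(11)])
        res = max_deviation_point(pts, (0, 0, 0), (10, 0, 0))
        assert res.deviation == pytest.approx(0.0, abs=1e-12)
        assert res.index == 0

    def test_sagitta_closed_form(self):
        R, theta_arc = 900.0, 0.5
        theta = np.linspace(0, theta_arc, 2001)
        pts = np.column_stack([np.zeros_like(theta), R * np.cos(theta), R * np.sin(theta)])
        res = max_deviation_point(pts, pts[0], pts[-1])
        sagitta = R * (1 - np.cos(theta_arc / 2))
        assert res.deviation == pytest.approx(sagitta, abs=1e-4)


class TestMirrorX:
    def test_double_mirror_identity(self, clean_specimen):
        twice = mirror_x(mirror_x(clean_specimen))
        assert twice.side == clean_specimen.side
        for name, arr in clean_specimen.landmark_groups().items():
            np.testing.assert_allclose(getattr(twice, name), getattr(clean_specimen, name), atol=0)

    def test_side_flip_and_x_negation(self, clean_specimen):
        mirrored = mirror_x(clean_specimen)
        assert {clean_specimen.side, mirrored.side} == {"L", "R"}
        np.testing.assert_allclose(mirrored.gt_tip[0], -clean_specimen.gt_tip[0], atol=0)
        np.testing.assert_allclose(mirrored.gt_tip[1:], clean_specimen.gt_tip[1:], atol=0)
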