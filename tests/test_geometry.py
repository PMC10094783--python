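"""Unit and property tests for the geometric primitives and fitters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares, minimize
from scipy.spatial.transform import Rotation

from scapulometry.geometry import (
    DegenerateGeometryError,
    Plane,
    Sphere,
    fit_line_least_squares,
    fit_plane_least_squares,
    fit_sphere,
    fit_sphere_detailed,
    project_onto_plane,
    signed_angle_in_plane,
    spherical_cap_volume_fraction,
)


def angle_between_deg(u, v):
    u = np.asarray(u, float) / np.linalg.norm(u)
    v = np.asarray(v, float) / np.linalg.norm(v)
    return np.degrees(np.arccos(np.clip(abs(u @ v), 0.0, 1.0)))


def random_rigid_motion(rng):
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.uniform(-100, 100, 3)


# ---------------------------------------------------------------- plane


class TestFitPlane:
    def test_exact_three_points(self):
        plane = fit_plane_least_squares([(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        assert angle_between_deg(plane.normal, [0, 0, 1]) < 1e-9

    def test_noiseless_cloud_exact_recovery(self, rng):
        pts = np.column_stack(
            [rng.uniform(-50, 50, 200), rng.uniform(-50, 50, 200), np.full(200, 2.0)]
        )
        plane = fit_plane_least_squares(pts)
        assert angle_between_deg(plane.normal, [0, 0, 1]) < 1e-9
        assert abs(plane.signed_distance([0.0, 0.0, 2.0])) < 1e-9
        assert np.abs(plane.signed_distance(pts)).max() < 1e-9

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_tilted_plane_recovery_and_oracle(self, seed):
        """Noisy fits stay within 0.5 deg of truth and at the optimum an
        independently coded minimizer finds."""
        rng = np.random.default_rng(seed)
        true_normal = np.array([0.2, -0.1, 0.97])
        true_normal /= np.linalg.norm(true_normal)
        basis = np.linalg.svd(np.eye(3) - np.outer(true_normal, true_normal))[0][:, :2]
        uv = rng.uniform(-40, 40, (500, 2))
        pts = uv @ basis.T + 7.0 * true_normal + rng.normal(0, 0.3, (500, 3))
        plane = fit_plane_least_squares(pts)
        assert angle_between_deg(plane.normal, true_normal) < 0.5

        centered = pts - pts.mean(axis=0)

        def ssq(angles):
            th, ph = angles
            n = np.array(
                [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
            )
            return float(((centered @ n) ** 2).sum())

        th0 = np.arccos(true_normal[2])
        ph0 = np.arctan2(true_normal[1], true_normal[0])
        res = minimize(ssq, [th0, ph0], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14})
        oracle_n = np.array(
            [
                np.sin(res.x[0]) * np.cos(res.x[1]),
                np.sin(res.x[0]) * np.sin(res.x[1]),
                np.cos(res.x[0]),
            ]
        )
        assert angle_between_deg(plane.normal, oracle_n) < 1e-3
        assert ssq([th0, ph0]) >= float(((centered @ plane.normal) ** 2).sum()) - 1e-9

    @pytest.mark.parametrize(
        "points",
        [
            [(0, 0, 0), (1, 0, 0)],
            [(0, 0, 0), (1, 1, 1), (2, 2, 2), (3, 3, 3)],
            [(5, 5, 5)] * 4,
        ],
    )
    def test_degenerate_inputs_raise(self, points):
        with pytest.raises(DegenerateGeometryError):
            fit_plane_least_squares(points)

    def test_rigid_motion_equivariance(self, rng):
        pts = rng.uniform(-30, 30, (120, 2)) @ np.eye(3)[:2] + rng.normal(0, 0.5, (120, 3))
        plane = fit_plane_least_squares(pts)
        rot, shift = random_rigid_motion(rng)
        moved = fit_plane_least_squares(pts @ rot.T + shift)
        assert angle_between_deg(moved.normal, rot @ plane.normal) < 1e-9
        assert abs(moved.signed_distance(rot @ plane.point + shift)) < 1e-9


# ----------------------------------------------------------------- line


def line_ssq(pts, direction):
    direction = direction / np.linalg.norm(direction)
    rel = pts - pts.mean(axis=0)
    return float((np.linalg.norm(np.cross(rel, direction), axis=1) ** 2).sum())


def grid_directions(step_deg):
    thetas = np.radians(np.arange(0.0, 90.0 + step_deg, step_deg))
    dirs = []
    for th in thetas:
        n_phi = max(1, int(round(360.0 * np.sin(th) / step_deg)))
        phis = 2 * np.pi * np.arange(n_phi) / n_phi
        dirs.append(
            np.column_stack(
                [np.sin(th) * np.cos(phis), np.sin(th) * np.sin(phis),
                 np.full(n_phi, np.cos(th))]
            )
        )
    return np.vstack(dirs)


class TestFitLine:
    def test_collinear_exact(self):
        line = fit_line_least_squares([(0, 0, 0), (1, 1, 1), (2, 2, 2)])
        assert angle_between_deg(line.direction, [1, 1, 1]) < 1e-9
        assert np.abs(line.distance([(0, 0, 0), (1, 1, 1), (2, 2, 2)])).max() < 1e-9

    def test_two_points_exact(self):
        line = fit_line_least_squares([(1, 2, 3), (4, 6, 3)])
        assert angle_between_deg(line.direction, [3, 4, 0]) < 1e-9
        assert float(line.distance([1, 2, 3])) < 1e-9

    def test_planar_arc_matches_direction_grid_oracle(self):
        """TLS direction is the argmin of summed squared point-line
        distances, verified against a brute-force direction grid."""
        theta = np.linspace(-0.4, 0.4, 15)
        pts = np.column_stack([100 * np.sin(theta), 100 * (1 - np.cos(theta)),
                               np.zeros_like(theta)])
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        pts = pts @ rot.T
        line = fit_line_least_squares(pts)
        step = 1.0
        dirs = grid_directions(step)
        ssqs = np.array([line_ssq(pts, d) for d in dirs])
        best = dirs[np.argmin(ssqs)]
        assert line_ssq(pts, line.direction) <= ssqs.min() + 1e-9
        assert angle_between_deg(line.direction, best) < step

    def test_symmetric_arc_direction_is_chord_axis(self):
        theta = np.linspace(-0.3, 0.3, 21)
        pts = np.column_stack([50 * np.sin(theta), 50 * (1 - np.cos(theta)),
                               np.zeros_like(theta)])
        line = fit_line_least_squares(pts)
        assert angle_between_deg(line.direction, [1, 0, 0]) < 1e-9

    def test_coincident_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            fit_line_least_squares([(1, 1, 1), (1, 1, 1), (1, 1, 1)])


# --------------------------------------------------------------- sphere


class TestFitSphere:
    def test_regular_tetrahedron_exact(self):
        pts = np.array(
            [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], dtype=float
        ) / np.sqrt(3)
        sphere = fit_sphere(pts)
        assert np.linalg.norm(sphere.center) < 1e-9
        assert abs(sphere.radius - 1.0) < 1e-9

    def test_noiseless_cap_exact(self, rng):
        dirs = rng.normal(size=(60, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        pts = np.array([1.0, 2.0, 3.0]) + 5.0 * dirs
        sphere = fit_sphere(pts)
        assert np.linalg.norm(sphere.center - [1, 2, 3]) < 1e-6
        assert abs(sphere.radius - 5.0) < 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_cap_radius_and_oracle(self, seed):
        """60-deg cap, sigma = 0.2 mm: radius within 2% of 12.5 mm and the
        refined fit matches an independent nonlinear solver started from
        the truth."""
        rng = np.random.default_rng(seed)
        cos_min = np.cos(np.radians(60.0))
        cosq = rng.uniform(cos_min, 1.0, 300)
        sinq = np.sqrt(1 - cosq**2)
        phi = rng.uniform(0, 2 * np.pi, 300)
        dirs = np.column_stack([sinq * np.cos(phi), sinq * np.sin(phi), cosq])
        center = np.array([4.0, -2.0, 9.0])
        pts = center + 12.5 * dirs + rng.normal(0, 0.2, (300, 3))

        detail = fit_sphere_detailed(pts)
        assert abs(detail.sphere.radius - 12.5) / 12.5 < 0.02
        assert detail.converged

        def resid(params):
            return np.linalg.norm(pts - params[:3], axis=1) - params[3]

        oracle = least_squares(resid, np.append(center, 12.5), xtol=1e-14, ftol=1e-14)
        assert np.linalg.norm(detail.sphere.center - oracle.x[:3]) < 1e-5
        assert abs(detail.sphere.radius - oracle.x[3]) < 1e-5

    @pytest.mark.parametrize("seed", range(8))
    def test_refined_never_worse_than_algebraic(self, seed):
        rng = np.random.default_rng(100 + seed)
        cosq = rng.uniform(rng.uniform(0.2, 0.9), 1.0, 80)
        sinq = np.sqrt(1 - cosq**2)
        phi = rng.uniform(0, 2 * np.pi, 80)
        dirs = np.column_stack([sinq * np.cos(phi), sinq * np.sin(phi), cosq])
        pts = rng.uniform(-5, 5, 3) + rng.uniform(5, 30) * dirs
        pts = pts + rng.normal(0, rng.uniform(0.05, 1.0), pts.shape)
        detail = fit_sphere_detailed(pts)
        assert detail.rms_residual <= detail.algebraic_rms_residual + 1e-12

    def test_coplanar_raises(self, rng):
        pts = np.column_stack(
            [rng.uniform(-10, 10, 50), rng.uniform(-10, 10, 50), np.zeros(50)]
        )
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(pts)

    def test_shallow_cap_flagged_ill_conditioned(self, rng):
        # ~10-deg total coverage: barely constrains the radius
        cosq = rng.uniform(np.cos(np.radians(5.0)), 1.0, 200)
        sinq = np.sqrt(1 - cosq**2)
        phi = rng.uniform(0, 2 * np.pi, 200)
        dirs = np.column_stack([sinq * np.cos(phi), sinq * np.sin(phi), cosq])
        pts = 12.5 * dirs + rng.normal(0, 0.01, (200, 3))
        detail = fit_sphere_detailed(pts)
        assert detail.ill_conditioned
        assert "sphere_cap_ill_conditioned" in detail.flags

    def test_rigid_motion_equivariance(self, rng):
        dirs = rng.normal(size=(100, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        pts = np.array([3.0, 1.0, -2.0]) + 8.0 * dirs + rng.normal(0, 0.2, (100, 3))
        sphere = fit_sphere(pts)
        rot, shift = random_rigid_motion(rng)
        moved = fit_sphere(pts @ rot.T + shift)
        assert np.linalg.norm(moved.center - (rot @ sphere.center + shift)) < 1e-8
        assert abs(moved.radius - sphere.radius) < 1e-8


# ------------------------------------------------------ cap volume etc.


class TestCapVolumeFraction:
    plane = Plane(np.zeros(3), np.array([0.0, 0.0, 1.0]))

    @pytest.mark.parametrize(
        "center_z,side,expected",
        [
            (0.0, 1, 0.5),
            (1.0, 1, 1.0),
            (-1.0, 1, 0.0),
            (-0.5, 1, 0.15625),
            (0.5, -1, 0.15625),
            (5.0, 1, 1.0),  # clamped far outside
        ],
    )
    def test_known_fractions(self, center_z, side, expected):
        sphere = Sphere(np.array([0.0, 0.0, center_z]), 1.0)
        frac = spherical_cap_volume_fraction(sphere, self.plane, side=side)
        assert frac == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(
        radius=st.floats(0.1, 50.0),
        d1=st.floats(-60.0, 60.0),
        d2=st.floats(-60.0, 60.0),
    )
    def test_complement_and_monotonicity(self, radius, d1, d2):
        plane = Plane(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        lo, hi = sorted([d1, d2])
        f_lo = spherical_cap_volume_fraction(Sphere([0, 0, lo], radius), plane, 1)
        f_hi = spherical_cap_volume_fraction(Sphere([0, 0, hi], radius), plane, 1)
        assert f_lo <= f_hi + 1e-12
        comp = spherical_cap_volume_fraction(Sphere([0, 0, hi], radius), plane, -1)
        assert f_hi + comp == pytest.approx(1.0, abs=1e-12)


class TestProjectionAndAngles:
    def test_projection_cases(self):
        np.testing.assert_allclose(
            project_onto_plane([1, 0, 1], [0, 0, 1]), [1, 0, 0], atol=1e-12
        )
        np.testing.assert_allclose(
            project_onto_plane([3, 4, 0], [0, 0, 1]), [3, 4, 0], atol=1e-12
        )
        proj = project_onto_plane([3, 4, 12], [0, 0, 1])
        assert np.linalg.norm(proj) == pytest.approx(5.0)

    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ([1, 0, 0], [0, 1, 0], 90.0),
            ([1, 0, 0], [1, 0, 0], 0.0),
            ([1, 0, 0], [1, -1, 0], -45.0),
            ([1, 0, 0], [-1, 0, 0], 180.0),
        ],
    )
    def test_signed_angle(self, u, v, expected):
        assert signed_angle_in_plane(u, v, [0, 0, 1]) == pytest.approx(expected)

    def test_signed_angle_antisymmetric(self):
        a = signed_angle_in_plane([1, 0.2, 3], [0.5, 1, -1], [0, 0, 1])
        b = signed_angle_in_plane([0.5, 1, -1], [1, 0.2, 3], [0, 0, 1])
        assert a == pytest.approx(-b)

    def test_zero_projection_raises(self):
        with pytest.raises(DegenerateGeometryError):
            signed_angle_in_plane([0, 0, 1], [1, 0, 0], [0, 0, 1])
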