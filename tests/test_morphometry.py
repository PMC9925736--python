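"""Body-size measurement: plane fit vs normal equations, ridge arc length,
withers detection, slice location, the polar branch rule and the closed
b-spline circumference."""

import numpy as np
import pytest

from porcimetry.errors import (
    DegenerateGeometryError,
    InsufficientCoverageError,
    InsufficientDataError,
    InvalidParameterError,
    WithersNotFoundError,
)
from porcimetry.geometry import RigidTransform
from porcimetry.morphometry import (
    MorphometryResult,
    PolarSlice,
    abdominal_circumference,
    body_length,
    body_width,
    fit_closed_curve,
    fit_longitudinal_plane,
    locate_abdominal_slice,
    measure_pig,
    orient_pig_cloud,
    to_polar,
    withers_height,
)


def ellipse_radius(theta, a, b):
    """Central polar radius of the ellipse |y/a|² + |z/b|² = 1."""
    return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


class TestLongitudinalPlane:
    def test_exact_plane_recovered_with_zero_residual(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(-1, 1, size=(50, 2))
        pts = np.column_stack([xy, 2 * xy[:, 0] + 3 * xy[:, 1] + 1])
        fit = fit_longitudinal_plane(pts)
        np.testing.assert_allclose([fit.a0, fit.a1, fit.a2], [2, 3, 1], atol=1e-10)
        assert fit.residual < 1e-18

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_normal_equations_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(30, 3))
        fit = fit_longitudinal_plane(pts)
        a = np.column_stack([pts[:, 0], pts[:, 1], np.ones(30)])
        coef = np.linalg.solve(a.T @ a, a.T @ pts[:, 2])
        np.testing.assert_allclose([fit.a0, fit.a1, fit.a2], coef, atol=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], dtype=float)
        with pytest.raises(DegenerateGeometryError):
            fit_longitudinal_plane(pts)


class TestBodyLength:
    def test_straight_horizontal_ridge_exact(self):
        x = np.linspace(0, 1.2, 2000)
        ridge = np.column_stack([x, np.zeros_like(x), np.full_like(x, 0.5)])
        assert abs(body_length(ridge) - 1.2) < 1e-6

    def test_semicircular_ridge_arc(self):
        r = 0.5
        phi = np.linspace(0, np.pi, 5000)
        ridge = np.column_stack([r * np.cos(phi), np.zeros_like(phi), r * np.sin(phi)])
        assert abs(body_length(ridge) - np.pi * r) / (np.pi * r) < 0.005

    def test_synthetic_pig_within_two_percent(self, dense_pig):
        pts, gt = dense_pig
        oriented, _ = orient_pig_cloud(pts)
        assert abs(body_length(oriented) - gt.length) / gt.length < 0.02

    def test_sparse_cloud_rejected(self):
        with pytest.raises(InsufficientDataError):
            body_length(np.random.default_rng(0).normal(size=(100, 3)))


class TestWithersHeight:
    @staticmethod
    def two_bump_surface(head=0.9, withers=0.75):
        x = np.linspace(0, 1.2, 30_000)
        z = 0.5 + (head - 0.5) * np.exp(-0.5 * ((x - 0.15) / 0.05) ** 2)
        z += (withers - 0.5) * np.exp(-0.5 * ((x - 0.5) / 0.08) ** 2)
        y = np.random.default_rng(0).uniform(-0.1, 0.1, x.size)
        return np.column_stack([x, y, z])

    def test_constructed_two_bump_profile(self):
        cloud = self.two_bump_surface()
        assert abs(withers_height(cloud) - 0.75) < 0.03  # binning tolerance

    def test_single_bump_rejected(self, dense_cylinder_pig):
        pts, _ = dense_cylinder_pig
        with pytest.raises(WithersNotFoundError):
            withers_height(pts)

    def test_synthetic_pig_within_two_percent(self, dense_pig):
        pts, gt = dense_pig
        oriented, _ = orient_pig_cloud(pts)
        assert abs(withers_height(oriented) - gt.height) / gt.height < 0.02

    def test_anterior_detected_from_either_end(self):
        cloud = self.two_bump_surface()
        flipped = cloud.copy()
        flipped[:, 0] = 1.2 - flipped[:, 0]
        assert abs(withers_height(flipped) - withers_height(cloud)) < 1e-9


class TestAbdominalSlice:
    @staticmethod
    def bulged_cylinder(bulge_at=0.6, n=60_000):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1.2, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        r = 0.25 + 0.05 * np.exp(-0.5 * ((x - bulge_at) / 0.1) ** 2)
        return np.column_stack([x, r * np.cos(phi), 0.5 + r * np.sin(phi)])

    def test_bulge_located_at_midpoint(self):
        cloud = self.bulged_cylinder(bulge_at=0.6)
        _, pos = locate_abdominal_slice(cloud)
        assert abs(pos - 0.6) < 0.03

    def test_returned_position_maximizes_lateral_extent(self, dense_pig):
        pts, _ = dense_pig
        oriented, _ = orient_pig_cloud(pts)
        slice_pts, pos = locate_abdominal_slice(oriented)
        width_here = body_width(slice_pts)
        # exhaustive scan: no other slab is wider (beyond binning jitter)
        for x0 in np.linspace(oriented[:, 0].min() + 0.2, oriented[:, 0].max() - 0.2, 25):
            slab = oriented[np.abs(oriented[:, 0] - x0) <= 0.01]
            if len(slab) > 10:
                assert body_width(slab) <= width_here + 0.01

    def test_width_of_circle_slice(self):
        phi = np.linspace(0, 2 * np.pi, 501)  # includes both y = ±0.3 points
        slab = np.column_stack([np.zeros_like(phi), 0.3 * np.cos(phi), 0.3 * np.sin(phi)])
        assert abs(body_width(slab) - 0.6) < 1e-9

    def test_width_of_two_points(self):
        assert body_width(np.array([[0, -0.25, 0], [0, 0.25, 0]])) == pytest.approx(0.5)

    def test_empty_inputs_rejected(self):
        with pytest.raises(InsufficientDataError):
            body_width(np.empty((0, 3)))
        with pytest.raises(InsufficientDataError):
            locate_abdominal_slice(np.zeros((5, 3)))


class TestToPolar:
    def test_branch_rule_pinned_values(self):
        # slice centered at the origin pole by symmetric construction
        pts = np.array(
            [[0, 0.0, 1.0], [0, 1.0, 1.0], [0, -1.0, 1.0],
             [0, 0.0, -1.0], [0, 1.0, -1.0], [0, -1.0, -1.0]]
        )
        p = to_polar(pts)
        np.testing.assert_allclose(p.pole, [0.0, 0.0], atol=1e-12)
        expected_theta = [np.pi / 2, np.pi / 4, 7 * np.pi / 4,
                          np.pi / 2, 3 * np.pi / 4, 5 * np.pi / 4]
        np.testing.assert_allclose(p.theta, expected_theta, atol=1e-12)
        np.testing.assert_allclose(
            p.rho, [1, np.sqrt(2), np.sqrt(2), 1, np.sqrt(2), np.sqrt(2)], atol=1e-12
        )

    def test_pole_point_gets_zero_angle_and_radius(self):
        pts = np.array([[0, 1.0, 0.0], [0, -1.0, 0.0], [0, 0.0, 0.0]])
        p = to_polar(pts)
        assert p.rho[2] == 0.0 and p.theta[2] == 0.0

    def test_uniform_circle_covers_full_angle_range(self):
        ang = np.linspace(0, 2 * np.pi, 361)[:-1]
        pts = np.column_stack([np.zeros(360), np.cos(ang), np.sin(ang)])
        p = to_polar(pts)
        gaps = np.diff(np.sort(p.theta))
        assert np.degrees(gaps.max()) < 1.01 and np.degrees(gaps.min()) > 0.99

    def test_equals_piecewise_quadrant_oracle(self):
        """The printed branch rule equals the continuous angle in the
        (+y,+z) and (−y,−z) quadrants and the continuous angle ± π in the
        mixed-sign quadrants, wherever the tangent is defined."""
        rng = np.random.default_rng(0)
        yz = rng.normal(size=(500, 2))
        yz = yz[np.abs(yz[:, 1]) > 1e-6]  # tangent defined (z != z0)
        yz = yz - 0  # pole at origin by construction below
        pts = np.column_stack([np.zeros(len(yz)), yz])
        pts = np.vstack([pts, -pts])  # symmetric set -> centroid pole at 0
        p = to_polar(pts)
        dy, dz = pts[:, 1], pts[:, 2]
        phi = np.mod(np.arctan2(dz, dy), 2 * np.pi)
        same = (dy >= 0) == (dz > 0)
        oracle = np.where(same, phi, np.mod(phi + np.pi, 2 * np.pi))
        np.testing.assert_allclose(p.theta, oracle, atol=1e-9)


class TestClosedCurve:
    def test_constant_radius_fit(self):
        ang = np.linspace(0, 2 * np.pi, 73)[:-1]
        curve = fit_closed_curve(PolarSlice(np.zeros(2), np.full(72, 0.3), ang))
        theta = np.linspace(0, 2 * np.pi, 500)
        assert np.max(np.abs(np.asarray(curve(theta)) - 0.3)) < 1e-6

    def test_ellipse_gap_reconstruction(self):
        a, b = 0.30, 0.22
        ang = np.linspace(0, 2 * np.pi, 361)[:-1]
        gap = (ang > 1.0) & (ang < 1.0 + np.pi / 6)  # 30 degree occlusion
        curve = fit_closed_curve(
            PolarSlice(np.zeros(2), ellipse_radius(ang[~gap], a, b), ang[~gap]),
            smoothing=0.0,
        )
        probe = np.linspace(1.0, 1.0 + np.pi / 6, 100)
        rel = np.abs(np.asarray(curve(probe)) - ellipse_radius(probe, a, b))
        assert np.max(rel / ellipse_radius(probe, a, b)) < 0.02

    def test_noisy_circle_stays_within_one_centimetre(self):
        rng = np.random.default_rng(7)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 400))
        rho = 0.3 + rng.normal(0, 0.002, 400)
        curve = fit_closed_curve(PolarSlice(np.zeros(2), rho, ang))
        theta = np.linspace(0, 2 * np.pi, 2000)
        assert np.max(np.abs(np.asarray(curve(theta)) - 0.3)) < 0.01

    def test_insufficient_coverage_rejected(self):
        ang = np.linspace(0, np.pi, 50)  # only half the circle
        with pytest.raises(InsufficientCoverageError):
            fit_closed_curve(PolarSlice(np.zeros(2), np.ones(50), ang))

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_closed_curve(PolarSlice(np.zeros(2), np.ones(5), np.linspace(0, 6, 5)))


class TestCircumference:
    def test_constant_curve_gives_circle_closed_form(self):
        ang = np.linspace(0, 2 * np.pi, 73)[:-1]
        curve = fit_closed_curve(PolarSlice(np.zeros(2), np.full(72, 0.3), ang))
        c = abdominal_circumference(curve)
        assert abs(c - 2 * np.pi * 0.3) / (2 * np.pi * 0.3) < 1e-6

    def test_ellipse_matches_polygonal_oracle(self):
        a, b = 0.30, 0.22
        ang = np.linspace(0, 2 * np.pi, 721)[:-1]
        curve = fit_closed_curve(
            PolarSlice(np.zeros(2), ellipse_radius(ang, a, b), ang), smoothing=0.0
        )
        phi = np.linspace(0, 2 * np.pi, 1_000_001)
        oracle = np.sum(np.hypot(np.diff(a * np.cos(phi)), np.diff(b * np.sin(phi))))
        assert abs(abdominal_circumference(curve) - oracle) / oracle < 0.001


class TestMeasurePig:
    def test_recovers_ground_truth_within_two_percent(self, dense_pig):
        pts, gt = dense_pig
        result = measure_pig(pts)
        for key in ("length", "height", "width", "abdominal_circumference"):
            got, want = getattr(result, key), getattr(gt, key)
            assert abs(got - want) / want < 0.02, key

    def test_rotation_invariance_after_reregistration(self, dense_pig):
        pts, _ = dense_pig
        base = measure_pig(pts)
        t = RigidTransform.from_angles((0.0, 0.0, 1.3), (0.7, -0.4, 0.0))
        again = measure_pig(t.apply(pts))
        for key in ("length", "height", "width", "abdominal_circumference"):
            a, b = getattr(base, key), getattr(again, key)
            assert abs(a - b) / b < 0.005, key

    def test_noise_degrades_monotonically(self, standard_pig_params):
        from porcimetry.synthetic import generate_pig_cloud

        totals = []
        for noise in (0.0, 0.002):
            pts, gt = generate_pig_cloud(standard_pig_params, 60_000, noise, seed=5)
            r = measure_pig(pts)
            totals.append(
                sum(
                    abs(getattr(r, k) - getattr(gt, k)) / getattr(gt, k)
                    for k in ("length", "height", "width", "abdominal_circumference")
                )
            )
        assert totals[0] <= totals[1]

    def test_impossible_section_rejected(self):
        with pytest.raises(InvalidParameterError):
            MorphometryResult(
                length=1.0, height=0.6, width=1.2,
                abdominal_circumference=1.0, slice_position=0.5,
            )
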