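"""Anisotropic Gaussian field: fitting, collision index, ray integrals."""

import math

import numpy as np
import pytest

from orchardnbv import (
    ColoredPointCloud,
    GaussianField,
    GaussianObstacle,
    Ray,
    batch_occlusion,
    collision_index,
    evaluate_gaussian,
    fit_field,
    occlusion_level,
)
from orchardnbv.gaussians import SIGMA_FLOOR

from conftest import random_field, random_gaussian, random_rigid


class TestEvaluateGaussian:
    def test_center_value_is_one(self, rng):
        for _ in range(100):
            g = random_gaussian(rng)
            assert evaluate_gaussian(g, g.mu) == 1.0

    def test_isotropic_closed_form(self):
        g = GaussianObstacle(np.zeros(3), np.eye(3), np.ones(3))
        assert evaluate_gaussian(g, [1.0, 0.0, 0.0]) == pytest.approx(
            math.exp(-0.5), rel=1e-12
        )

    def test_far_point_decays(self):
        g = GaussianObstacle(np.zeros(3), np.eye(3), np.ones(3))
        assert evaluate_gaussian(g, [10.0, 0.0, 0.0]) < 1e-20

    def test_sigma_eigenvalues_match_scales(self, rng):
        g = random_gaussian(rng)
        lam = np.sort(np.linalg.eigvalsh(g.sigma))
        np.testing.assert_allclose(lam, np.sort(g.S_diag**2), atol=1e-9)

    def test_degenerate_scale_rejected(self):
        with pytest.raises(ValueError):
            GaussianObstacle(np.zeros(3), np.eye(3), np.array([0.0, 1.0, 1.0]))


class TestFitField:
    def test_symmetric_points_give_centroid_mean(self):
        c = np.array([0.012, 0.02, 0.03])
        offsets = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
        ) * 0.01
        cloud = ColoredPointCloud(c + offsets)
        field = fit_field(cloud, voxel_size=0.2, min_points=5)
        assert len(field) == 1
        np.testing.assert_allclose(field.gaussians[0].mu, c, atol=1e-12)

    def test_segment_aligns_principal_axis(self, rng):
        t = rng.uniform(-0.02, 0.02, 100)
        pts = np.zeros((100, 3))
        pts[:, 0] = t + 0.025
        pts[:, 1:] = 0.025
        field = fit_field(ColoredPointCloud(pts), voxel_size=0.05, min_points=5)
        assert len(field) == 1
        g = field.gaussians[0]
        lam = g.S_diag**2
        major = g.R[:, np.argmax(lam)]
        # independently computed sample covariance
        cov = np.cov(pts.T, ddof=1)
        w, v = np.linalg.eigh(cov)
        expected = v[:, np.argmax(w)]
        cos = abs(major @ expected)
        assert cos > math.cos(math.radians(1.0))
        assert np.sort(lam)[:2] == pytest.approx(SIGMA_FLOOR**2)

    def test_sparse_voxel_filtered(self):
        pts = np.array([[0.01, 0.01, 0.01], [0.02, 0.02, 0.02]])
        field = fit_field(ColoredPointCloud(pts), voxel_size=0.05, min_points=5)
        assert len(field) == 0

    def test_empty_cloud_empty_field(self):
        field = fit_field(ColoredPointCloud(np.zeros((0, 3))))
        assert len(field) == 0

    def test_sampling_identity_recovers_moments(self, rng):
        # points drawn from a known gaussian all landing in one big voxel
        mu = np.array([0.4, 0.4, 0.4])
        A = rng.normal(size=(3, 3)) * 0.05
        cov = A @ A.T + np.eye(3) * 1e-3
        pts = rng.multivariate_normal(mu, cov, 10_000)
        field = fit_field(ColoredPointCloud(pts), voxel_size=50.0, min_points=5)
        assert len(field) == 1
        g = field.gaussians[0]
        assert np.linalg.norm(g.mu - mu) < 0.01
        rel = np.linalg.norm(g.sigma - cov) / np.linalg.norm(cov)
        assert rel < 0.15


class TestCollisionIndex:
    def test_single_gaussian_center(self, rng):
        g = random_gaussian(rng)
        assert collision_index(GaussianField([g]), g.mu) == pytest.approx(1.0)

    def test_duplicate_gaussians_still_one(self, rng):
        g = random_gaussian(rng)
        f = GaussianField([g, GaussianObstacle(g.mu, g.R, g.S_diag)])
        assert collision_index(f, g.mu) == pytest.approx(1.0)

    def test_empty_field_is_free_space(self):
        assert collision_index(GaussianField([]), [0.0, 0.0, 0.0]) == 0.0

    def test_bounded_by_unit(self, rng):
        f = random_field(rng, 20)
        for _ in range(50):
            x = rng.uniform(-2, 2, 3)
            assert 0.0 <= collision_index(f, x) <= 1.0

    def test_invariant_under_joint_rigid_motion(self, rng):
        f = random_field(rng, 10)
        x = rng.uniform(-1, 1, 3)
        T = random_rigid(rng)
        before = collision_index(f, x)
        after = collision_index(f.transformed(T), T.apply(x))
        assert after == pytest.approx(before, rel=1e-9)


class TestOcclusionLevel:
    def test_empty_field_zero(self):
        ray = Ray([0, 0, 0], [0, 0, 2.0], 1.96)
        assert occlusion_level(GaussianField([]), ray).I == 0.0

    def test_unit_gaussian_on_ray_matches_1d_integral(self):
        g = GaussianObstacle(np.array([0, 0, 10.0]), np.eye(3), np.ones(3))
        ray = Ray([0, 0, 0.0], [0, 0, 20.0], 19.96)
        res = occlusion_level(GaussianField([g]), ray, ni=256)
        assert res.I == pytest.approx(math.sqrt(2 * math.pi), rel=0.01)

    def test_far_off_axis_gaussian_negligible(self):
        g = GaussianObstacle(np.array([10.0, 0, 10.0]), np.eye(3), np.ones(3))
        ray = Ray([0, 0, 0.0], [0, 0, 20.0], 19.96)
        assert occlusion_level(GaussianField([g]), ray, ni=256).I < 1e-10

    def test_target_fruit_gaussians_excluded(self):
        target = np.array([0.0, 0.0, 2.0])
        on_fruit = GaussianObstacle(target + [0.0, 0.0, -0.02], np.eye(3),
                                    np.full(3, SIGMA_FLOOR))
        ray = Ray.to_fruit([0, 0, 0.0], target, 0.04)
        res = occlusion_level(GaussianField([on_fruit]), ray)
        assert res.I == 0.0
        assert res.excluded_ids == (0,)

    def test_invalid_ray_rejected(self):
        with pytest.raises(ValueError):
            Ray([0, 0, 0], [0, 0, 1.0], -0.5)

    def test_quadrature_converged_at_default_ni(self, rng):
        # dense-trapezoid oracle; gaussian widths >= ~1.5 sample spacings so
        # the 64-point rule resolves every feature, and both ray endpoints
        # sit in free space so the endpoint error term vanishes
        for _ in range(20):
            base = [random_gaussian(rng, scale=1.0, s_range=(0.1, 0.3))
                    for _ in range(15)]
            f = GaussianField([
                GaussianObstacle(g.mu * [0.6, 0.6, 0.8], g.R, g.S_diag)
                for g in base
            ])
            origin = np.array([0.0, 0.0, -3.0])
            target = np.array([*rng.uniform(-0.3, 0.3, 2), 2.0])
            ray = Ray.to_fruit(origin, target, 0.04)
            coarse = occlusion_level(f, ray, ni=64).I
            dense = occlusion_level(f, ray, ni=10_000).I
            if dense > 1e-9:
                assert abs(coarse - dense) / dense < 1e-3

    def test_adding_on_ray_gaussian_increases_occlusion(self, rng):
        origin = np.array([0.0, 0.0, 0.0])
        target = np.array([0.0, 0.0, 4.0])
        ray = Ray.to_fruit(origin, target, 0.04)
        off = [
            GaussianObstacle(np.array([1.5, 1.5, z]), np.eye(3), np.full(3, 0.2))
            for z in (1.0, 2.0, 3.0)
        ]
        on = GaussianObstacle(np.array([0.0, 0.0, 2.0]), np.eye(3), np.full(3, 0.2))
        base = occlusion_level(GaussianField(off), ray).I
        more = occlusion_level(GaussianField(off + [on]), ray).I
        assert more > base


class TestBatchOcclusion:
    def test_single_ray_matches_scalar_path(self, rng):
        f = random_field(rng, 30)
        ray = Ray.to_fruit([0, 0, -3.0], [0.2, -0.1, 0.5], 0.04)
        single = occlusion_level(f, ray).I
        batch = batch_occlusion(f, [ray])[0].I
        assert batch == single

    def test_matches_looped_evaluation(self, rng):
        f = random_field(rng, 1500, scale=1.5)
        rays = [
            Ray.to_fruit(rng.uniform(-3, -2, 3), rng.uniform(-1, 1, 3), 0.04)
            for _ in range(9)
        ]
        batch = [r.I for r in batch_occlusion(f, rays)]
        loop = [occlusion_level(f, r).I for r in rays]
        np.testing.assert_allclose(batch, loop, rtol=0, atol=1e-12)

    def test_duplicated_ray_identical_results(self, rng):
        f = random_field(rng, 50)
        ray = Ray.to_fruit([0, 0, -3.0], [0, 0, 0.5], 0.04)
        res = batch_occlusion(f, [ray, ray])
        assert res[0].I == res[1].I


class TestSerialization:
    def test_field_json_round_trip(self, rng):
        f = random_field(rng, 8)
        f2 = GaussianField.from_dict(f.to_dict())
        for a, b in zip(f.gaussians, f2.gaussians):
            np.testing.assert_allclose(b.sigma, a.sigma, atol=1e-12)
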