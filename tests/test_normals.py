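"""Plane fitting, threshold calibration, minimum-reliable-scale selection."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from attiscan.normals import (
    DegenerateNeighbourhoodError,
    NoiseCalibration,
    STATUS_DEGENERATE,
    STATUS_ISOLATED,
    STATUS_MAX_SCALE,
    STATUS_REJECTED,
    ScaleConfig,
    calibrate_thresholds,
    estimate_normals,
    fit_plane,
    k_schedule,
    planar_calibration_cloud,
    select_scale,
)
from attiscan.scenes import (
    PointCloud,
    ScanConfig,
    build_scene,
    raycast,
    scan_to_points,
)


def brute_force_plane(points):
    """Independent oracle: total least squares via full SVD, no iteration."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c)
    return c, vt[-1]


def cloud_from_xyz(xyz):
    xyz = np.asarray(xyz, dtype=float)
    n = len(xyz)
    r = np.linalg.norm(xyz, axis=1)
    return PointCloud(
        xyz=xyz,
        intensity=np.full(n, 0.5),
        view_dirs=xyz / np.maximum(r[:, None], 1e-12),
        elevations_deg=np.degrees(np.arccos(np.clip(-xyz[:, 2] / np.maximum(r, 1e-12), -1, 1))),
        azimuths_deg=np.degrees(np.arctan2(xyz[:, 1], xyz[:, 0])) % 360.0,
        grid_index=np.zeros((n, 2), dtype=int),
    )


class TestFitPlane:
    def test_exact_coplanar(self):
        rng = np.random.default_rng(0)
        uv = rng.normal(size=(7, 2))
        normal = np.array([0.0, 0.0, 1.0])
        pts = np.column_stack([uv, np.full(7, -2.0)])
        fit = fit_plane(pts)
        assert fit.mean_abs_deviation == pytest.approx(0.0, abs=1e-12)
        assert abs(fit.normal @ normal) == pytest.approx(1.0, abs=1e-12)

    def test_normal_signed_toward_sensor(self):
        pts = np.column_stack([np.random.default_rng(1).normal(size=(20, 2)), np.full(20, -2.0)])
        fit = fit_plane(pts)
        # plane below the origin: sensor-facing normal points up
        assert fit.normal[2] > 0

    def test_noisy_plane_monte_carlo(self):
        # deviation ~ sigma sqrt(2/pi) for Gaussian residuals; normal
        # within 1 degree of truth at k = 100.
        rng = np.random.default_rng(2)
        sigma = 0.001
        errs, devs = [], []
        for _ in range(20):
            uv = rng.uniform(-0.5, 0.5, size=(100, 2))
            z = rng.normal(0.0, sigma, size=100) - 2.0
            fit = fit_plane(np.column_stack([uv, z]), outlier_multiple=1e9)
            errs.append(np.degrees(np.arccos(min(abs(fit.normal[2]), 1.0))))
            devs.append(fit.mean_abs_deviation)
        assert np.median(errs) < 1.0
        expected = sigma * np.sqrt(2 / np.pi)
        assert np.mean(devs) == pytest.approx(expected, rel=0.3)

    def test_collinear_errors(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.zeros(10), np.zeros(10)])
        with pytest.raises(DegenerateNeighbourhoodError):
            fit_plane(pts)

    def test_too_few_points_errors(self):
        with pytest.raises(DegenerateNeighbourhoodError):
            fit_plane(np.zeros((2, 3)))

    @pytest.mark.parametrize("aspect", [0.05, 0.1, 0.2])
    def test_elongated_strip_flagged_degenerate(self, aspect):
        rng = np.random.default_rng(3)
        pts = np.column_stack(
            [
                rng.uniform(-1, 1, 200),
                rng.uniform(-aspect, aspect, 200),
                rng.normal(0, 1e-4, 200) - 2.0,
            ]
        )
        fit = fit_plane(pts)
        assert fit.eigen_ratio < 0.3

    def test_outlier_removed_iteratively(self):
        rng = np.random.default_rng(4)
        uv = rng.uniform(-1, 1, size=(60, 2))
        z = rng.normal(0, 0.001, size=60)
        pts = np.column_stack([uv, z - 3.0])
        pts[0, 2] += 0.5  # gross outlier
        fit = fit_plane(pts)
        assert fit.inlier_count < 60
        assert abs(fit.normal[2]) > 0.9999

    def test_oracle_equivalence_noiseless(self):
        rng = np.random.default_rng(5)
        u = np.array([1.0, 0.0, 0.5])
        v = np.array([0.0, 1.0, -0.2])
        ab = rng.normal(size=(50, 2))
        pts = ab @ np.stack([u, v]) + np.array([0, 0, -4.0])
        fit = fit_plane(pts)
        _, n_oracle = brute_force_plane(pts)
        assert min(
            np.linalg.norm(fit.normal - n_oracle), np.linalg.norm(fit.normal + n_oracle)
        ) < 1e-9

    def test_oracle_equivalence_noisy_same_inliers(self):
        rng = np.random.default_rng(6)
        ab = rng.normal(size=(120, 2))
        pts = np.column_stack([ab, rng.normal(0, 0.002, 120) - 4.0])
        # huge outlier multiple: all points are inliers in both fits
        fit = fit_plane(pts, outlier_multiple=1e9)
        _, n_oracle = brute_force_plane(pts)
        assert min(
            np.linalg.norm(fit.normal - n_oracle), np.linalg.norm(fit.normal + n_oracle)
        ) < 1e-6


class TestKSchedule:
    def test_default_bounds(self):
        ks = k_schedule(ScaleConfig())
        assert ks[0] == 7 and ks[-1] == 300
        assert all(a < b for a, b in zip(ks, ks[1:]))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ScaleConfig(k_min=2)


class TestCalibration:
    def test_zero_noise_thresholds_tiny(self, scale_config):
        clouds = [
            planar_calibration_cloud(d, range_noise_m=0.0, step_arcmin=30.0, rng_seed=i)
            for i, d in enumerate((3.0, 10.0))
        ]
        cal = calibrate_thresholds(clouds, scale_config, rng_seed=0)
        assert (cal.thresholds_m < 1e-9).all()

    def test_mm_noise_gives_mm_thresholds(self, calibration):
        assert (calibration.thresholds_m > 0.0005).all()
        assert (calibration.thresholds_m < 0.005).all()

    def test_thresholds_scale_with_sigma(self, scale_config):
        def thresh(sigma):
            clouds = [
                planar_calibration_cloud(d, range_noise_m=sigma, step_arcmin=30.0, rng_seed=i)
                for i, d in enumerate((3.0, 10.0))
            ]
            return calibrate_thresholds(clouds, scale_config, rng_seed=0).thresholds_m

    # Gaussian residual scaling: doubling sigma doubles the quantile.
        ratio = thresh(0.002) / thresh(0.001)
        assert np.allclose(ratio, 2.0, atol=0.5)

    def test_monotone_in_distance(self, calibration):
        assert (np.diff(calibration.thresholds_m) >= 0).all()

    def test_lookup_clamps(self, calibration):
        lo = calibration.lookup(0.1)
        hi = calibration.lookup(1000.0)
        assert lo == calibration.thresholds_m[0]
        assert hi == calibration.thresholds_m[-1]

    def test_text_round_trip(self, calibration, tmp_path):
        p = tmp_path / "cal.txt"
        p.write_text(calibration.to_text())
        back = NoiseCalibration.from_text(p.read_text())
        np.testing.assert_allclose(back.distances_m, calibration.distances_m)
        np.testing.assert_allclose(back.thresholds_m, calibration.thresholds_m)


class TestSelectScale:
    def test_pure_plane_reaches_max_scale(self, scale_config, calibration):
        cloud = planar_calibration_cloud(10.0, range_noise_m=0.001, step_arcmin=30.0, rng_seed=1)
        # interior point: nearest to the patch center
        center_idx = int(np.argmin(np.linalg.norm(cloud.xyz - [10, 0, 0], axis=1)))
        sel = select_scale(center_idx, cloud, scale_config, calibration)
        assert sel.status == STATUS_MAX_SCALE
        assert sel.fit.k == 300

    def test_kmin_rejection_returns_k7(self, scale_config):
        # With an absurdly low threshold, k_min already rejects.
        cloud = planar_calibration_cloud(10.0, range_noise_m=0.001, step_arcmin=30.0, rng_seed=1)
        tiny = NoiseCalibration(distances_m=np.array([10.0]), thresholds_m=np.array([1e-9]))
        sel = select_scale(100, cloud, scale_config, tiny)
        assert sel.status == STATUS_REJECTED
        assert sel.selected_k == 7

    def test_crease_scene_selects_smaller_k_near_crease(self, scale_config, calibration):
        # Two planes meeting at 90 degrees: points close to the crease
        # must select smaller neighbourhoods (trend, not per-point).
        rng = np.random.default_rng(7)
        n = 4000
        # horizontal plane y in [0, 2], vertical plane z in [0, 2]; crease at y=z=0
        a = np.column_stack([rng.uniform(-2, 2, n), rng.uniform(0, 2, n), np.zeros(n)])
        b = np.column_stack([rng.uniform(-2, 2, n), np.zeros(n), rng.uniform(0, 2, n)])
        pts = np.concatenate([a, b]) + np.array([5.0, 0.0, 0.0])
        pts += rng.normal(0, 0.001, pts.shape)
        cloud = cloud_from_xyz(pts)
        dist_to_crease = np.abs(pts[:, 1]) + np.abs(pts[:, 2])
        est = estimate_normals(cloud, scale_config, calibration)
        near = dist_to_crease < 0.2
        far = dist_to_crease > 1.0
        ok = est.k > 0
        assert est.k[near & ok].mean() < est.k[far & ok].mean()

    def test_isolated_point(self, scale_config, calibration):
        cloud = cloud_from_xyz(np.random.default_rng(0).normal(size=(4, 3)) + [5, 0, 0])
        sel = select_scale(0, cloud, scale_config, calibration)
        assert sel.status == STATUS_ISOLATED

    def test_report_at_rejection_flag(self, calibration):
        rng = np.random.default_rng(8)
        n = 3000
        a = np.column_stack([rng.uniform(-2, 2, n), rng.uniform(0, 2, n), np.zeros(n)])
        b = np.column_stack([rng.uniform(-2, 2, n), np.zeros(n), rng.uniform(0, 2, n)])
        pts = np.concatenate([a, b]) + np.array([5.0, 0.0, 0.0])
        pts += rng.normal(0, 0.001, pts.shape)
        cloud = cloud_from_xyz(pts)
        idx = int(np.argmin(np.abs(pts[:, 1] - 0.3) + np.abs(pts[:, 2])))
        cfg_prev = ScaleConfig(report_at_rejection=False)
        cfg_lit = ScaleConfig(report_at_rejection=True)
        sel_prev = select_scale(idx, cloud, cfg_prev, calibration)
        sel_lit = select_scale(idx, cloud, cfg_lit, calibration)
        if sel_prev.status == STATUS_REJECTED and sel_prev.fit.k < sel_lit.selected_k:
            assert sel_lit.fit.k == sel_lit.selected_k
            assert sel_prev.fit.k < sel_lit.fit.k

    def test_mean_deviation_nondecreasing_with_interfering_plane(self, scale_config):
        # A noisy plane with a second plane beyond some radius: deviation
        # grows (statistically) with k once the far plane enters.
        rng = np.random.default_rng(9)
        n = 2500
        main = np.column_stack(
            [rng.uniform(-1, 1, n), rng.uniform(-1, 1, n), rng.normal(0, 0.001, n)]
        )
        far = np.column_stack(
            [rng.uniform(1.2, 1.6, 400), rng.uniform(-1, 1, 400),
             rng.uniform(0.0, 0.5, 400)]
        )
        pts = np.concatenate([main, far]) + np.array([5.0, 0.0, 0.0])
        tree = cKDTree(pts)
        query = pts[int(np.argmin(np.linalg.norm(pts - [5.9, 0, 0], axis=1)))]
        devs = []
        for k in k_schedule(scale_config):
            _, nbr = tree.query(query, k=k)
            devs.append(fit_plane(pts[np.atleast_1d(nbr)]).mean_abs_deviation)
        devs = np.array(devs)
        assert devs[-1] > devs[0]
        # overall non-decreasing trend (allow small wiggles)
        assert (np.diff(devs) > -0.2 * devs[:-1] - 1e-6).all()


class TestEstimateNormals:
    def test_empty_cloud(self, scale_config, calibration):
        cloud = cloud_from_xyz(np.empty((0, 3)))
        est = estimate_normals(cloud, scale_config, calibration)
        assert len(est.normals) == 0

    def test_orientation_invariant(self, scale_config, calibration):
        scan = raycast(build_scene("outdoor-built", 4),
                       ScanConfig(step_arcmin=60.0), rng_seed=4)
        cloud = scan_to_points(scan)
        est = estimate_normals(cloud, scale_config, calibration)
        ok = np.isfinite(est.normals).all(axis=1)
        dots = np.einsum("ij,ij->i", est.normals[ok], cloud.xyz[ok])
        assert (dots < 1e-9).all()

    def test_matches_per_point_select_scale(self, scale_config, calibration):
        cloud = planar_calibration_cloud(3.0, range_noise_m=0.001, step_arcmin=30.0, rng_seed=2)
        rng = np.random.default_rng(1)
        idx = rng.choice(len(cloud), size=15, replace=False)
        est = estimate_normals(cloud, scale_config, calibration, query_indices=idx)
        for row, i in enumerate(idx):
            sel = select_scale(int(i), cloud, scale_config, calibration)
            assert est.status[row] == sel.status
            if sel.fit is not None:
                agree = abs(est.normals[row] @ sel.fit.normal)
                assert agree == pytest.approx(1.0, abs=1e-9)
                assert est.k[row] == sel.selected_k

    def test_indoor_scene_median_error_below_2deg(self, scale_config, calibration):
        scan = raycast(build_scene("indoor", 1), ScanConfig(step_arcmin=60.0), rng_seed=5)
        cloud = scan_to_points(scan)
        est = estimate_normals(cloud, scale_config, calibration)
        tn = cloud.true_normals
        ok = np.isfinite(est.normals).all(axis=1)
        dots = np.abs(np.einsum("ij,ij->i", est.normals[ok], tn[ok]))
        err = np.degrees(np.arccos(np.clip(dots, -1, 1)))
        assert np.median(err) < 2.0

    def test_clutter_selects_smaller_k_than_walls(self, scale_config, calibration):
        # grass-like spheroid clutter vs a wall: adaptive scale picks
        # smaller neighbourhoods in the clutter.
        from attiscan.scenes import Box, SceneSpec, Spheroid, SENSOR_HEIGHT_M
        from conftest import ground_plane

        rng = np.random.default_rng(11)
        clutter = tuple(
            Spheroid(
                center=np.array(
                    [rng.uniform(3, 6), rng.uniform(-2, 2), rng.uniform(-1.5, 0.5)]
                ),
                a=rng.uniform(0.05, 0.3),
                b=rng.uniform(0.05, 0.3),
            )
            for _ in range(40)
        )
        wall = Box(
            lo=np.array([-8.0, 4.0, -SENSOR_HEIGHT_M]),
            hi=np.array([8.0, 5.0, 3.0]),
        )
        scene = SceneSpec("outdoor-natural", (ground_plane(), wall) + clutter)
        scan = raycast(scene, ScanConfig(step_arcmin=45.0), rng_seed=6)
        cloud = scan_to_points(scan)
        est = estimate_normals(cloud, scale_config, calibration)
        is_wall = cloud.prim_id == 1
        is_clutter = cloud.prim_id >= 2
        ok = est.k > 0
        assert est.k[is_clutter & ok].mean() < est.k[is_wall & ok].mean()

    def test_status_counts_sum(self, scale_config, calibration):
        scan = raycast(build_scene("outdoor-natural", 2), ScanConfig(step_arcmin=60.0), rng_seed=3)
        cloud = scan_to_points(scan)
        est = estimate_normals(cloud, scale_config, calibration)
        assert sum(est.counts().values()) == len(cloud)


class TestAttitudeRecovery:
    @pytest.mark.parametrize("category", ["indoor", "outdoor-built"])
    def test_median_slant_error_below_3deg_on_planes(
        self, category, scale_config, calibration
    ):
        from attiscan.geometry import slant_tilt_arrays
        from attiscan.scenes import Box, PlanePatch

        scan = raycast(build_scene(category, 1), ScanConfig(step_arcmin=60.0), rng_seed=8)
        cloud = scan_to_points(scan)
        est = estimate_normals(cloud, scale_config, calibration)
        ok = np.isfinite(est.normals).all(axis=1)
        tn = cloud.true_normals.copy()
        flip = np.einsum("ij,ij->i", tn, cloud.xyz) > 0
        tn[flip] = -tn[flip]
        s_est, _, _ = slant_tilt_arrays(est.normals[ok], cloud.view_dirs[ok])
        s_true, _, _ = slant_tilt_arrays(tn[ok], cloud.view_dirs[ok])
        err = np.abs(s_est - s_true)
        assert np.median(err[np.isfinite(err)]) < 3.0
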