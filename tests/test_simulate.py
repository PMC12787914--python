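"""Scene generation and scan simulation."""

import numpy as np
import pytest

import stemscan as ss
from stemscan.simulate import pattern_directions


def _angles(dirs):
    az = np.degrees(np.arctan2(dirs[:, 1], dirs[:, 0]))
    el = np.degrees(np.arcsin(np.clip(dirs[:, 2], -1, 1)))
    return az, el


class TestPatterns:
    def test_rosette_emits_rate_times_duration_directions(self):
        prof = ss.DEFAULT_PROFILES["lca_tls"]
        assert len(ss.rosette_directions(prof, 1.0, seed=0)) == 240_000
        assert len(ss.rosette_directions(prof, 0.0, seed=0)) == 0

    def test_negative_duration_rejected(self):
        prof = ss.DEFAULT_PROFILES["lca_tls"]
        with pytest.raises(ValueError):
            ss.rosette_directions(prof, -1.0, seed=0)

    def test_rosette_requires_rosette_profile(self):
        with pytest.raises(ValueError):
            ss.rosette_directions(ss.DEFAULT_PROFILES["riegl"], 1.0, seed=0)

    def test_rosette_coverage_grows_with_dwell_time(self):
        # oracle: direct occupancy count on a 100x100 angular grid
        prof = ss.DEFAULT_PROFILES["lca_tls"]
        counts = []
        for t in (0.1, 0.5, 2.0):
            az, el = _angles(ss.rosette_directions(prof, t, seed=9))
            h, _, _ = np.histogram2d(az, el, bins=100)
            counts.append((h > 0).sum())
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[0] < counts[2]

    @pytest.mark.parametrize("device", ["riegl", "stonex", "lca_tls", "iphone"])
    def test_all_directions_inside_fov(self, device):
        prof = ss.DEFAULT_PROFILES[device]
        dirs = pattern_directions(prof, 0.05, seed=3)
        az, el = _angles(dirs)
        tol = 1e-9
        if prof.fov_h < 360:
            assert np.all(np.abs(az) <= prof.fov_h / 2 + tol)
        lo = prof.fov_v_offset - prof.fov_v / 2
        hi = prof.fov_v_offset + prof.fov_v / 2
        assert np.all((el >= lo - tol) & (el <= hi + tol))


class TestSimulateScan:
    def test_noiseless_points_lie_on_cylinder_surface(self):
        scene = ss.Scene(objects=[ss.TubeSpec("T", 30.0, 200.0, (5.0, 0.0))])
        prof = ss.DeviceProfile("d", 50_000, 90, 90, 0.0, 50.0)
        cloud = ss.simulate_scan(scene, ss.ScanPose((0, 0, 1.0)), prof, seed=1)
        pts = cloud.points[cloud.points[:, 2] > 1e-6]  # drop ground hits
        r = np.hypot(pts[:, 0] - 5.0, pts[:, 1])
        assert len(pts) > 100
        assert np.abs(r - 0.15).max() < 1e-9

    def test_bit_identical_for_identical_seed(self):
        scene = ss.Scene(objects=[ss.TubeSpec("T", 30.0, 200.0, (5.0, 0.0))])
        prof = ss.DeviceProfile("d", 50_000, 90, 90, 0.02, 50.0)
        pose = ss.ScanPose((0, 0, 1.0))
        a = ss.simulate_scan(scene, pose, prof, seed=7)
        b = ss.simulate_scan(scene, pose, prof, seed=7)
        assert np.array_equal(a.points, b.points)

    def test_short_range_device_misses_tree_top(self):
        tree = ss.TreeSpec("T", 25.6, 15.7, (2.0, 0.0), crown_base=9.4)
        scene = ss.Scene(objects=[tree])
        prof = ss.DEFAULT_PROFILES["iphone"]
        pose = ss.ScanPose((0, 0, 1.4), yaw=0.0, duration=2.0)
        cloud = ss.simulate_scan(scene, pose, prof, seed=4)
        assert len(cloud) > 0
        # nothing beyond the 5 m range sphere, so the upper stem is empty
        d = np.linalg.norm(cloud.points - np.array([0, 0, 1.4]), axis=1)
        assert d.max() <= prof.max_range + 1e-6
        assert cloud.points[:, 2].max() < 8.0

    def test_detection_floor_censors_thin_tube(self):
        thin = ss.TubeSpec("thin", 2.6, 100.0, (3.0, 0.0))
        fat = ss.TubeSpec("fat", 25.0, 100.0, (3.0, 2.0))
        scene = ss.Scene(objects=[thin, fat])
        prof = ss.DeviceProfile(
            "d", 200_000, 360, 90, 0.0, 50.0, detection_floor_diameter=0.05
        )
        cloud = ss.simulate_scan(scene, ss.ScanPose((0, 0, 0.8)), prof, seed=5)
        near_thin = np.hypot(cloud.points[:, 0] - 3.0, cloud.points[:, 1]) < 0.3
        on_thin = near_thin & (cloud.points[:, 2] > 1e-6)
        assert on_thin.sum() == 0
        near_fat = np.hypot(cloud.points[:, 0] - 3.0, cloud.points[:, 1] - 2.0) < 0.3
        assert (near_fat & (cloud.points[:, 2] > 1e-6)).sum() > 100

    def test_range_noise_calibration_at_20m(self):
        # a floor scanned from 20 m straight above: ranging residual sigma
        # must match the profile's 2 cm within 3 standard errors
        scene = ss.Scene(objects=[ss.TubeSpec("far", 1.0, 1.0, (500.0, 500.0))])
        prof = ss.DeviceProfile("cal", 300_000, 20, 20, 0.02, 100.0)
        pose = ss.ScanPose((0, 0, 20.0), pitch=90.0, duration=0.1)
        cloud = ss.simulate_scan(scene, pose, prof, seed=6)
        o = np.array([0.0, 0.0, 20.0])
        delta = cloud.points - o
        t_meas = np.linalg.norm(delta, axis=1)
        t_true = -20.0 / (delta[:, 2] / t_meas)
        res = t_meas - t_true
        n = len(res)
        assert n >= 10_000
        se = 0.02 / np.sqrt(2 * n)
        assert abs(res.std() - 0.02) < 3 * se

    def test_empty_scene_rejected(self):
        prof = ss.DeviceProfile("d", 1000, 90, 90, 0.0, 10.0)
        with pytest.raises(ValueError):
            ss.simulate_scan(ss.Scene(objects=[]), ss.ScanPose((0, 0, 1)), prof, 0)


class TestScenes:
    def test_default_lab_scene_matches_benchmark_tubes(self, lab_scene):
        assert len(lab_scene.objects) == 12
        dia = sorted(t.diameter for t in lab_scene.objects)
        assert dia[0] == pytest.approx(2.6)
        assert dia[-1] == pytest.approx(50.5)

    def test_empty_and_overlapping_lab_scenes_rejected(self):
        with pytest.raises(ValueError):
            ss.make_lab_scene([])
        t = ss.TubeSpec("a", 20.0, 100.0, (1.0, 1.0))
        u = ss.TubeSpec("b", 20.0, 100.0, (1.0, 1.0))
        with pytest.raises(ValueError, match="overlap"):
            ss.make_lab_scene([t, u])

    def test_plantation_from_30m_plot_has_64_stems(self):
        # oracle: floor(30/4)+1 = 8 stems per axis
        scene = ss.plantation_from_extent(30.0, 30.0, 4.0, seed=1)
        assert len(scene.objects) == 64

    def test_zero_sd_gives_equal_diameters(self):
        scene = ss.make_plantation_scene(2, 3, dbh_sd=0.0, th_sd=0.0, seed=1)
        dbh = {round(t.dbh, 9) for t in scene.objects}
        assert dbh == {25.6}

    def test_seed_changes_diameters_not_layout(self):
        a = ss.make_plantation_scene(2, 2, seed=1, position_jitter=0.0)
        b = ss.make_plantation_scene(2, 2, seed=2, position_jitter=0.0)
        assert [t.stem_xy for t in a.objects] == [t.stem_xy for t in b.objects]
        assert [t.dbh for t in a.objects] != [t.dbh for t in b.objects]

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            ss.make_plantation_scene(0, 3)
        with pytest.raises(ValueError):
            ss.make_plantation_scene(2, 2, spacing=0.0)


class TestMerge:
    def test_sixteen_scans_concatenate(self):
        pts = np.random.default_rng(0).uniform(0, 1, (50, 3))
        clouds = [ss.PointCloud(pts, device="lca_tls") for _ in range(16)]
        merged = ss.merge_scans(clouds)
        assert len(merged) == 16 * 50
        assert set(np.unique(merged.scan_id)) == set(range(16))

    def test_single_cloud_identity(self):
        c = ss.PointCloud(np.zeros((3, 3)), device="x")
        m = ss.merge_scans([c])
        assert np.array_equal(m.points, c.points)
        assert m.device == "x"

    def test_empty_and_mixed_device_rejected(self):
        with pytest.raises(ValueError):
            ss.merge_scans([])
        a = ss.PointCloud(np.zeros((1, 3)), device="a")
        b = ss.PointCloud(np.zeros((1, 3)), device="b")
        with pytest.raises(ValueError, match="device"):
            ss.merge_scans([a, b])
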