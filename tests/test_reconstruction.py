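import math

import numpy as np
import pytest

from citruslines import reconstruction as rec
from citruslines import segmentation, centerline
from citruslines.reconstruction import (
    CameraModel, RigidTransform, triangulate_height, height_to_shift,
    distort_point, undistort_point, profile_from_centerline, icp_align,
    merge_profiles, PointCloud, write_ply, read_ply)


@pytest.fixture
def simple_cam():
    return CameraModel(M1=10.0, M2=100.0, theta=math.pi / 4)


class TestTriangulation:
    def test_zero_shift(self, simple_cam):
        assert triangulate_height(0.0, simple_cam) == 0.0

    def test_closed_form(self, simple_cam):
        # h = M2*n/(n + M1*tan(theta)) = 100*1/(1+10)
        assert triangulate_height(1.0, simple_cam) == pytest.approx(100 / 11)

    def test_monotone_and_bounded(self, simple_cam):
        n = np.linspace(0, 500, 200)
        h = triangulate_height(n, simple_cam)
        assert np.all(np.diff(h) > 0)
        assert np.all(h < simple_cam.M2)

    def test_inverse_round_trip(self, cam):
        h = np.linspace(0, 25, 50)
        assert np.allclose(triangulate_height(height_to_shift(h, cam), cam), h)

    def test_bad_denominator(self, simple_cam):
        with pytest.raises(ValueError):
            triangulate_height(-20.0, simple_cam)


class TestDistortion:
    def test_zero_coefficients_identity(self, cam):
        p = np.array([[100.0, 200.0], [320.0, 240.0]])
        assert np.allclose(undistort_point(p, cam), p)

    def test_round_trip(self):
        cam = CameraModel(k1=-0.1, k2=0.02, p1=1e-4, p2=-2e-4,
                          fx=1000, fy=1000, cx=320, cy=240)
        pts = np.array([[300.0, 230.0], [350.0, 260.0], [320.0, 240.0]])
        distorted = np.atleast_2d(distort_point(pts, cam))
        back = np.atleast_2d(undistort_point(distorted, cam))
        assert np.allclose(back, pts, atol=1e-6)

    def test_principal_point_fixed(self):
        cam = CameraModel(k1=-0.2, fx=1000, fy=1000, cx=320, cy=240)
        assert np.allclose(undistort_point([320.0, 240.0], cam), [320.0, 240.0])


class TestProfile:
    def test_reference_row_gives_zero_height(self, cam):
        path = np.array([[cam.reference_row, c] for c in range(10, 20)], float)
        prof = profile_from_centerline(path, 0, cam)
        assert np.allclose(prof.points[:, 2], 0.0)

    def test_conveyor_y(self, cam):
        path = np.array([[cam.reference_row, 5.0]])
        prof = profile_from_centerline(path, 3, cam)
        assert prof.points[0, 1] == pytest.approx(3 * 20.0 / 30.0)

    def test_phantom_round_trip_on_true_centerlines(self, cam, clean_spec,
                                                    clean_phantom, clean_frames):
        field, _ = clean_phantom
        errs = []
        for i in range(clean_spec.n_frames):
            rows = clean_frames.true_rows[i]
            path = np.stack([rows, np.arange(len(rows), dtype=float)], axis=1)
            prof = profile_from_centerline(path, i, cam)
            errs.append(prof.points[:, 2] - field.z[i])
        rmse = np.sqrt(np.mean(np.concatenate(errs) ** 2))
        assert rmse < 1e-9  # exact inverse of the render relation

    def test_extracted_round_trip(self, cam, clean_spec, clean_phantom,
                                  clean_frames):
        field, _ = clean_phantom
        errs = []
        for i, frame in enumerate(clean_frames.frames):
            mask = segmentation.segment_stripe(frame)
            path = centerline.prune_to_main_branch(centerline.thin(mask))
            path = centerline.subpixel_refine(
                path, segmentation.extract_v_channel(frame), half_width=6)
            prof = profile_from_centerline(path, i, cam)
            cols = np.clip(np.round(path.points[:, 1]).astype(int), 0,
                           clean_spec.image_width - 1)
            errs.append(prof.points[:, 2] - field.z[i][cols])
        rmse = np.sqrt(np.mean(np.concatenate(errs) ** 2))
        assert rmse < 0.05


class TestICP:
    def test_identity_on_same_cloud(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(100, 3))
        tf = icp_align(pts, pts)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tf.translation, 0.0, atol=1e-9)
        assert tf.rms == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(-10, 10, size=(300, 3))
        angle = math.radians(5.0)
        R = np.array([[math.cos(angle), -math.sin(angle), 0],
                      [math.sin(angle), math.cos(angle), 0],
                      [0, 0, 1]])
        t = np.array([1.0, 0.5, 0.2])
        target = src @ R.T + t
        tf = icp_align(src, target)
        assert np.abs(tf.rotation - R).max() < 1e-4
        assert np.abs(tf.translation - t).max() < 1e-4

    def test_residual_nonincreasing(self):
        rng = np.random.default_rng(2)
        src = rng.uniform(-5, 5, size=(200, 3))
        R = np.eye(3)
        target = src + np.array([0.5, -0.3, 0.2])
        # track rms across manual iterations
        tf = RigidTransform.identity()
        from scipy.spatial import cKDTree
        tree = cKDTree(target)
        last = np.inf
        for _ in range(10):
            moved = tf.apply(src)
            dist, idx = tree.query(moved)
            rms = float(np.sqrt(np.mean(dist ** 2)))
            assert rms <= last + 1e-12
            last = rms
            tf = rec._best_rigid(moved, target[idx]).compose(tf)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            icp_align(np.zeros((2, 3)), np.ones((10, 3)))

    def test_collinear_target_rejected(self):
        line = np.stack([np.arange(10.0), np.zeros(10), np.zeros(10)], axis=1)
        with pytest.raises(ValueError, match="rank-deficient"):
            icp_align(np.random.default_rng(0).normal(size=(10, 3)), line)


class TestMerge:
    def _profiles(self, cam, clean_spec, clean_frames):
        profiles = []
        for i in range(clean_spec.n_frames):
            rows = clean_frames.true_rows[i]
            path = np.stack([rows, np.arange(len(rows), dtype=float)], axis=1)
            profiles.append(profile_from_centerline(path, i, cam))
        return profiles

    def test_single_profile_identity(self, cam):
        path = np.array([[cam.reference_row - r, 100.0 + r] for r in range(20)],
                        dtype=float)
        prof = profile_from_centerline(path, 0, cam)
        cloud = merge_profiles([prof], cam)
        assert np.array_equal(cloud.points, prof.points)

    def test_nominal_span(self, cam):
        profiles = []
        for i in range(90):
            path = np.array([[cam.reference_row - r, 100.0 + r]
                             for r in range(5)], dtype=float)
            profiles.append(profile_from_centerline(path, i, cam))
        cloud = merge_profiles(profiles, cam)
        span = cloud.points[:, 1].max() - cloud.points[:, 1].min()
        assert span == pytest.approx(89 * 20.0 / 30.0)

    def test_icp_matches_nominal_on_clean_phantom(self, cam, clean_spec,
                                                  clean_frames):
        profiles = self._profiles(cam, clean_spec, clean_frames)
        nominal = merge_profiles(profiles, cam, use_icp=False)
        with pytest.warns(UserWarning):
            refined = merge_profiles(profiles, cam, use_icp=True)
        assert np.abs(nominal.points - refined.points).max() < 1e-3

    def test_empty_rejected(self, cam):
        with pytest.raises(ValueError):
            merge_profiles([], cam)


class TestPlyIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        cloud = PointCloud(rng.normal(size=(50, 3)),
                           rng.integers(0, 5, size=50))
        path = tmp_path / "cloud.ply"
        write_ply(cloud, path)
        back = read_ply(path)
        assert np.allclose(back.points, cloud.points, atol=1e-5)
        assert np.array_equal(back.frame_index, cloud.frame_index)
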