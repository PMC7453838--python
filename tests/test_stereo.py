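"""Epipolar geometry, stereo cost and relative-orientation recovery."""

import numpy as np
import pytest

from camfit import (Camera, CameraPose, CorrespondenceSet, ScaleConstraint,
                    StereoModel, epipolar_line, generate_stereo_scene,
                    relative_camera, stereo_cost, triangulate)
from camfit.stereo import CoincidentCamerasError
from camfit.synthetic import default_intrinsics

REL_TRUTH = np.array([90.0, 0.0, 2.0, -1.0, -4.0])


def fundamental_matrix(cam_a: Camera, cam_b: Camera) -> np.ndarray:
    """Independent oracle: assemble F from the known poses and intrinsics.

    With p_b = R_rel p_a + t_rel (camera-frame coordinates), the essential
    matrix is E = [t_rel]x R_rel and F = K_b^-T E K_a^-1.
    """
    def K(cam):
        f = cam.intrinsics.f_pix
        cx, cy = cam.intrinsics.center
        return np.array([[f, 0, cx], [0, f, cy], [0, 0, 1.0]])

    r_rel = cam_b.rotation @ cam_a.rotation.T
    t_rel = cam_b.rotation @ (cam_a.position - cam_b.position)
    tx = np.array([[0, -t_rel[2], t_rel[1]],
                   [t_rel[2], 0, -t_rel[0]],
                   [-t_rel[1], t_rel[0], 0]])
    return np.linalg.inv(K(cam_b)).T @ tx @ r_rel @ np.linalg.inv(K(cam_a))


def epipolar_distance_via_f(points_a, points_b, F) -> np.ndarray:
    ha = np.hstack([points_a, np.ones((len(points_a), 1))])
    hb = np.hstack([points_b, np.ones((len(points_b), 1))])
    lines = ha @ F.T
    return np.abs(np.einsum("ij,ij->i", hb, lines)) / np.hypot(
        lines[:, 0], lines[:, 1])


@pytest.fixture(scope="module")
def noiseless_rig():
    corr, truth = generate_stereo_scene(seed=31, noise_px=0.0)
    return corr, truth


class TestEpipolarLine:
    def test_corresponding_point_lies_on_line(self, noiseless_rig):
        corr, truth = noiseless_rig
        cam_a, cam_b = truth["camera_a"], truth["camera_b"]
        for a, b in zip(corr.points_a[:5], corr.points_b[:5]):
            normal, offset = epipolar_line(a, cam_a, cam_b)
            assert abs(normal @ b - offset) < 1e-8

    def test_rectified_parallel_rig_gives_horizontal_rows(self):
        intr = default_intrinsics()
        pose_a = CameraPose(elevation_m=10.0, tilt_deg=90.0)
        pose_b = CameraPose(elevation_m=10.0, tilt_deg=90.0, pos_x_m=2.0)
        cam_a, cam_b = Camera(intr, pose_a), Camera(intr, pose_b)
        for uv in ([1000.0, 700.0], [2304.0, 1296.0], [4000.0, 2000.0]):
            normal, offset = epipolar_line(np.array(uv), cam_a, cam_b)
            # horizontal line: unit normal along v, offset at the same row
            assert abs(abs(normal[1]) - 1.0) < 1e-9
            assert abs(offset / normal[1] - uv[1]) < 1e-6

    def test_agrees_with_fundamental_matrix_oracle(self, noiseless_rig, rng):
        corr, truth = noiseless_rig
        cam_a, cam_b = truth["camera_a"], truth["camera_b"]
        F = fundamental_matrix(cam_a, cam_b)
        # evaluate on perturbed clicks so distances are non-trivial
        pts_b = corr.points_b + rng.normal(0, 5.0, corr.points_b.shape)
        d_oracle = epipolar_distance_via_f(corr.points_a, pts_b, F)
        d_geom = np.array([
            abs(n @ b - o) for (n, o), b in
            ((epipolar_line(a, cam_a, cam_b), b)
             for a, b in zip(corr.points_a, pts_b))])
        np.testing.assert_allclose(d_geom, d_oracle, atol=1e-6)

    def test_coincident_cameras_rejected(self):
        intr = default_intrinsics()
        cam = Camera(intr, CameraPose(elevation_m=10.0, tilt_deg=80.0))
        with pytest.raises(CoincidentCamerasError):
            epipolar_line(np.array([100.0, 100.0]), cam, cam)


class TestStereoCost:
    def test_zero_at_truth_noiseless(self, noiseless_rig):
        corr, truth = noiseless_rig
        intr = default_intrinsics()
        c = stereo_cost(truth["rel_params"], corr, intr, intr,
                        pose_a=truth["camera_a"].pose)
        assert c < 1e-8

    def test_nonnegative_and_order_one_with_noise(self):
        corr, truth = generate_stereo_scene(seed=32, noise_px=1.0)
        intr = default_intrinsics()
        c = stereo_cost(truth["rel_params"], corr, intr, intr,
                        pose_a=truth["camera_a"].pose)
        assert 0.0 < c < 10.0

    def test_perturbation_increases_cost(self, noiseless_rig):
        corr, truth = noiseless_rig
        intr = default_intrinsics()
        kw = dict(pose_a=truth["camera_a"].pose)
        base = stereo_cost(truth["rel_params"], corr, intr, intr, **kw)
        for j in range(5):
            for sign in (+1, -1):
                pert = truth["rel_params"].copy()
                pert[j] += sign * 1.0
                assert stereo_cost(pert, corr, intr, intr, **kw) > base

    def test_swapped_correspondences_match_inverse_pose(self, noiseless_rig):
        corr, truth = noiseless_rig
        intr = default_intrinsics()
        cam_a, cam_b = truth["camera_a"], truth["camera_b"]
        # the inverse relative pose, expressed against camera B's frame
        delta = cam_a.position - cam_b.position
        az = np.degrees(np.arctan2(delta[0], delta[1]))
        inc = np.degrees(np.arcsin(delta[2] / np.linalg.norm(delta)))
        inv_rel = [az, inc, -REL_TRUTH[2], -REL_TRUTH[3], -REL_TRUTH[4]]
        c = stereo_cost(inv_rel, corr.swapped(), intr, intr,
                        pose_a=cam_b.pose)
        assert c < 1e-8


class TestTriangulate:
    def test_noiseless_points_recovered(self, noiseless_rig):
        corr, truth = noiseless_rig
        pts, gaps = triangulate(corr.points_a, corr.points_b,
                                truth["camera_a"], truth["camera_b"])
        np.testing.assert_allclose(pts, truth["world_points"], atol=1e-8)
        assert np.max(gaps) < 1e-8

    def test_object_height_from_stereo(self):
        corr, truth = generate_stereo_scene(seed=33, noise_px=0.5)
        pts, _ = triangulate(corr.points_a[:2], corr.points_b[:2],
                             truth["camera_a"], truth["camera_b"])
        height = np.linalg.norm(pts[0] - pts[1])
        assert height == pytest.approx(0.75, abs=0.05)

    def test_swapping_cameras_keeps_midpoint(self, noiseless_rig):
        corr, truth = noiseless_rig
        p1, _ = triangulate(corr.points_a, corr.points_b,
                            truth["camera_a"], truth["camera_b"])
        p2, _ = triangulate(corr.points_b, corr.points_a,
                            truth["camera_b"], truth["camera_a"])
        np.testing.assert_allclose(p1, p2, atol=1e-9)


class TestFitRelativeOrientation:
    def test_recovery_with_baseline_constraint(self):
        corr, truth = generate_stereo_scene(seed=34, noise_px=0.5)
        model = StereoModel(corr, default_intrinsics(),
                            pose_a=truth["camera_a"].pose, sigma_px=0.5)
        res = model.fit(n_iter=3000, seed=35)
        fitted = np.array([res.params[n] for n in model.param_names])
        assert np.max(np.abs(fitted[2:] - REL_TRUTH[2:])) < 0.5
        assert abs((fitted[0] - REL_TRUTH[0] + 180) % 360 - 180) < 2.0
        assert res.baseline_m == pytest.approx(5.0)

    def test_known_size_scale_matches_baseline(self):
        corr, truth = generate_stereo_scene(seed=36, noise_px=0.5)
        sized = CorrespondenceSet(
            corr.points_a, corr.points_b,
            ScaleConstraint(known_size=(0, 1, 0.75)))
        model = StereoModel(sized, default_intrinsics(),
                            pose_a=truth["camera_a"].pose, sigma_px=0.5)
        res = model.fit(n_iter=3000, seed=37)
        # a single ~90 px object clicked to 0.5 px carries a few percent of
        # intrinsic scale noise; the constraint itself limits the accuracy
        assert res.baseline_m == pytest.approx(5.0, rel=0.06)

    def test_few_correspondences_warn(self):
        with pytest.warns(UserWarning, match="at least 8"):
            CorrespondenceSet(np.zeros((4, 2)), np.zeros((4, 2)),
                              ScaleConstraint(baseline_m=1.0))

    def test_scale_constraint_validation(self):
        with pytest.raises(ValueError, match="exactly one"):
            ScaleConstraint()
        with pytest.raises(ValueError, match="exactly one"):
            ScaleConstraint(baseline_m=1.0, known_size=(0, 1, 0.75))
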