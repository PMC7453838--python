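"""Projection, backprojection and rigid-frame geometry."""

import numpy as np
import pytest

from camfit import (Camera, CameraIntrinsics, CameraPose,
                    FootConstraintError, NoGroundIntersectionError,
                    effective_focal_length, rotation_world_to_camera)
from camfit.camera import Projection

from conftest import visible_ground_pixels


class TestEffectiveFocalLength:
    def test_benchmark_camera(self, intrinsics):
        # 14 mm * 4608 px / 17.3 mm, evaluated directly
        assert effective_focal_length(intrinsics) == pytest.approx(
            3729.01734104, abs=1e-6)

    def test_unit_scaling(self):
        intr = CameraIntrinsics(1.0, 1.0, 1.0, 1000, 1000)
        assert effective_focal_length(intr) == 1000.0

    def test_linear_in_image_width(self, intrinsics):
        doubled = CameraIntrinsics(
            intrinsics.focal_length_mm, intrinsics.sensor_width_mm,
            intrinsics.sensor_height_mm, 2 * intrinsics.image_width_px,
            2 * intrinsics.image_height_px)
        assert effective_focal_length(doubled) == pytest.approx(
            2 * effective_focal_length(intrinsics))

    def test_aspect_mismatch_warns(self):
        with pytest.warns(UserWarning, match="aspect"):
            CameraIntrinsics(14.0, 17.3, 9.7, 4608, 1000)


class TestWorldToCamera:
    def test_on_axis_horizontal(self):
        cam = Camera(CameraIntrinsics(1, 1, 1, 100, 100),
                     CameraPose(elevation_m=5.0, tilt_deg=90.0))
        pc = cam.world_to_camera([0.0, 12.0, 5.0])
        assert pc == pytest.approx([0.0, 0.0, 12.0], abs=1e-12)

    def test_nadir_sees_origin_ahead(self):
        cam = Camera(CameraIntrinsics(1, 1, 1, 100, 100),
                     CameraPose(elevation_m=7.0, tilt_deg=0.0))
        pc = cam.world_to_camera([0.0, 0.0, 0.0])
        assert pc == pytest.approx([0.0, 0.0, 7.0], abs=1e-12)

    def test_rigidity_and_handedness(self, rng):
        pose = CameraPose(elevation_m=3.0, tilt_deg=72.0, roll_deg=-8.0,
                          heading_deg=213.0, pos_x_m=4.0, pos_y_m=-9.0)
        cam = Camera(CameraIntrinsics(1, 1, 1, 10, 10), pose)
        p = rng.normal(0, 50, (30, 3))
        q = rng.normal(0, 50, (30, 3))
        d_world = np.linalg.norm(p - q, axis=1)
        d_cam = np.linalg.norm(cam.world_to_camera(p) - cam.world_to_camera(q),
                               axis=1)
        np.testing.assert_allclose(d_cam, d_world, rtol=1e-12)
        assert np.linalg.det(rotation_world_to_camera(pose)) == pytest.approx(1.0)

    def test_roundtrip_with_camera_to_world(self, camera, rng):
        p = rng.normal(0, 30, (20, 3))
        np.testing.assert_allclose(
            camera.camera_to_world(camera.world_to_camera(p)), p, atol=1e-9)


class TestProject:
    def test_on_axis_point_hits_principal_point(self):
        intr = CameraIntrinsics(1, 1, 0.75, 640, 480)
        cam = Camera(intr, CameraPose(elevation_m=5.0, tilt_deg=90.0))
        uv, visible = cam.project([0.0, 10.0, 5.0])
        assert visible
        assert uv == pytest.approx([320.0, 240.0], abs=1e-9)

    def test_rectilinear_preserves_collinearity(self, camera, rng):
        # three collinear world points stay collinear in the image
        for _ in range(20):
            a = rng.normal([0, 100, 0], [20, 30, 3])
            b = rng.normal([0, 100, 0], [20, 30, 3])
            lam = rng.uniform(0.2, 0.8)
            c = a + lam * (b - a)
            uv, vis = camera.project(np.stack([a, b, c]))
            if not np.all(vis):
                continue
            e1, e2 = uv[1] - uv[0], uv[2] - uv[0]
            cross = e1[0] * e2[1] - e1[1] * e2[0]
            span = np.linalg.norm(uv[1] - uv[0])
            assert abs(cross) / max(span, 1.0) < 1e-6

    def test_center_pixel_ground_distance_matches_tangent(self, camera):
        # the optical axis meets the ground at h*tan(tilt) from the camera
        center = camera.intrinsics.center
        ground = camera.backproject_to_plane(center)
        dist = np.hypot(ground[0] - camera.pose.pos_x_m,
                        ground[1] - camera.pose.pos_y_m)
        expected = 16.1 * np.tan(np.radians(85.3))
        assert dist == pytest.approx(expected, abs=1e-6)
        uv, vis = camera.project(ground)
        assert vis
        np.testing.assert_allclose(uv, center, atol=1e-6)

    def test_behind_camera_gets_sentinel_not_mirror(self, camera):
        behind = camera.position + np.array([0.0, -100.0, 0.0])
        uv, vis = camera.project(behind)
        assert not vis
        assert np.all(np.isnan(uv))

    def test_cylindrical_agrees_with_rectilinear_near_axis(self, intrinsics):
        cyl = CameraIntrinsics(
            intrinsics.focal_length_mm, intrinsics.sensor_width_mm,
            intrinsics.sensor_height_mm, intrinsics.image_width_px,
            intrinsics.image_height_px, projection="cylindrical")
        pose = CameraPose(elevation_m=16.1, tilt_deg=85.3)
        cam_r = Camera(intrinsics, pose)
        cam_c = Camera(cyl, pose)
        # rays within 0.5 degrees of the optical axis
        f = intrinsics.f_pix
        r_half_deg = f * np.tan(np.radians(0.5))
        for du, dv in [(r_half_deg, 0), (0, r_half_deg),
                       (-r_half_deg / 2, r_half_deg / 2)]:
            uv = intrinsics.center + [du, dv]
            p = cam_r.backproject_to_plane(uv)
            uv_c, _ = cam_c.project(p)
            assert abs(uv_c[0] - uv[0]) < 0.01


@pytest.mark.parametrize("projection", ["rectilinear", "cylindrical",
                                        "equirectangular"])
@pytest.mark.parametrize("distortion", [(0.0, 0.0, 0.0),
                                        (-0.08, 0.012, 0.0)])
class TestBackprojectRoundTrip:
    def test_project_backproject_identity(self, projection, distortion, rng):
        intr = CameraIntrinsics(14.0, 17.3, 9.7, 4608, 2592,
                                projection=projection, distortion=distortion)
        cam = Camera(intr, CameraPose(elevation_m=16.1, tilt_deg=85.3,
                                      roll_deg=0.3, heading_deg=40.0))
        uv = visible_ground_pixels(cam, rng, 1000)
        ground = cam.backproject_to_plane(uv)
        assert np.allclose(ground[:, 2], 0.0, atol=1e-9)
        uv_back, vis = cam.project(ground)
        assert np.max(np.abs(uv_back - uv)) < 1e-6


class TestBackprojectErrors:
    def test_horizontal_ray_never_meets_ground(self):
        intr = CameraIntrinsics(14.0, 17.3, 9.7, 4608, 2592)
        cam = Camera(intr, CameraPose(elevation_m=16.1, tilt_deg=90.0))
        with pytest.raises(NoGroundIntersectionError):
            cam.backproject_to_plane(intr.center)

    def test_pixel_above_horizon_errors(self, camera):
        with pytest.raises(NoGroundIntersectionError):
            camera.backproject_to_plane([2304.0, 100.0])

    def test_non_strict_returns_nan(self, camera):
        out = camera.backproject_to_plane([2304.0, 100.0], strict=False)
        assert np.all(np.isnan(out))


class TestFootConstraint:
    def test_generator_heights_recovered_exactly(self, camera):
        # project synthetic 0.75 m objects, then back-solve with the truth
        feet_w = np.array([[xm, ym, 0.0] for xm, ym in
                           [(-20.0, 80.0), (5.0, 120.0), (30.0, 60.0)]])
        heads_w = feet_w + [0.0, 0.0, 0.75]
        uv_feet, _ = camera.project(feet_w)
        uv_heads, _ = camera.project(heads_w)
        ground = camera.backproject_to_plane(uv_feet)
        heads = camera.backproject_with_foot_constraint(uv_heads, ground)
        np.testing.assert_allclose(heads[:, 2], 0.75, atol=1e-6)
        np.testing.assert_allclose(heads[:, :2], feet_w[:, :2], atol=1e-6)

    def test_head_equal_foot_gives_zero_height(self, camera):
        uv = np.array([[2304.0, 2000.0]])
        ground = camera.backproject_to_plane(uv)
        head = camera.backproject_with_foot_constraint(uv, ground)
        assert head[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_diverging_head_ray_errors(self, camera):
        ground = camera.backproject_to_plane(np.array([[2304.0, 2000.0]]))
        # a head pixel on the opposite side: its ray walks away from the axis
        with pytest.raises(FootConstraintError):
            camera.backproject_with_foot_constraint(
                np.array([[2304.0, 2000.0]]),
                ground * np.array([-1.0, -1.0, 1.0]))


class TestPoseValidation:
    def test_angle_normalization(self):
        pose = CameraPose(elevation_m=1.0, tilt_deg=10.0, roll_deg=-270.0,
                          heading_deg=400.0)
        assert pose.heading_deg == pytest.approx(40.0)
        assert pose.roll_deg == pytest.approx(90.0)

    def test_tilt_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            CameraPose(elevation_m=1.0, tilt_deg=180.0)
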