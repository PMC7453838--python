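"""Synthetic scenes with known ground truth for every fitting routine.

The generators emulate the manual-annotation workflow: world geometry with an
exactly known camera is projected to pixel coordinates and perturbed by
isotropic Gaussian "click noise".  Each generator returns the input object a
fit expects plus a truth record sufficient to verify the fit without any
external data.  Generation is bit-reproducible under a fixed seed.

The default object scene mirrors the standard benchmark configuration:
rectangles 0.30 m wide and 0.75 m tall placed uniformly at ground distances
of 50-150 m, viewed by a 14 mm camera (17.3 x 9.7 mm sensor, 4608 x 2592 px)
from 16.1 m elevation at 85.3 deg tilt and 0.3 deg roll.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .camera import Camera, CameraIntrinsics, CameraPose
from .georef import LandmarkSet
from .heights import ClickSet
from .horizon import HorizonModel, horizon_in_image
from .stereo import CorrespondenceSet, ScaleConstraint, relative_camera

__all__ = ["SceneSpec", "SceneTruth", "default_intrinsics", "default_pose",
           "generate_object_scene", "generate_horizon_clicks",
           "generate_landmark_scene", "generate_stereo_scene",
           "render_ground_pattern"]


def default_intrinsics(**overrides) -> CameraIntrinsics:
    """The benchmark camera: 14 mm lens, 17.3 x 9.7 mm sensor, 4608 x 2592 px."""
    kw = dict(focal_length_mm=14.0, sensor_width_mm=17.3, sensor_height_mm=9.7,
              image_width_px=4608, image_height_px=2592)
    kw.update(overrides)
    return CameraIntrinsics(**kw)


def default_pose(**overrides) -> CameraPose:
    """The benchmark pose: 16.1 m elevation, 85.3 deg tilt, 0.3 deg roll."""
    kw = dict(elevation_m=16.1, tilt_deg=85.3, roll_deg=0.3)
    kw.update(overrides)
    return CameraPose(**kw)


@dataclasses.dataclass
class SceneSpec:
    """Generator parameters for a synthetic object scene."""

    n_objects: int = 50
    object_height_m: float = 0.75
    object_width_m: float = 0.30
    distance_range_m: tuple = (50.0, 150.0)
    intrinsics: CameraIntrinsics = dataclasses.field(default_factory=default_intrinsics)
    pose: CameraPose = dataclasses.field(default_factory=default_pose)
    click_noise_px: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        lo, hi = self.distance_range_m
        if not (0 < lo < hi):
            raise ValueError("distance range must be positive and ordered")
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")


@dataclasses.dataclass
class SceneTruth:
    """Ground truth saved alongside a generated scene."""

    camera: Camera
    foot_world: np.ndarray
    head_world: np.ndarray

    @property
    def pose(self) -> CameraPose:
        return self.camera.pose

    @property
    def heights(self) -> np.ndarray:
        return self.head_world[:, 2] - self.foot_world[:, 2]


def _noisy_inside(uv: np.ndarray, noise_px: float, rng: np.random.Generator,
                  width: int, height: int, max_tries: int = 100) -> np.ndarray:
    """Add Gaussian click noise, redrawing clicks that land outside the frame."""
    if noise_px == 0:
        return uv.copy()
    out = uv + rng.normal(0.0, noise_px, uv.shape)
    for _ in range(max_tries):
        bad = ~((out[:, 0] >= 0) & (out[:, 0] <= width)
                & (out[:, 1] >= 0) & (out[:, 1] <= height))
        if not np.any(bad):
            return out
        out[bad] = uv[bad] + rng.normal(0.0, noise_px, (bad.sum(), 2))
    raise RuntimeError("could not keep noisy clicks inside the frame")


def generate_object_scene(spec: SceneSpec,
                          rng: np.random.Generator | None = None
                          ) -> tuple[ClickSet, SceneTruth]:
    """Place objects uniformly in the visible ground wedge and project them.

    Objects are drawn uniformly in azimuth (within the camera's horizontal
    field of view) and in ground distance within ``spec.distance_range_m``;
    placements whose foot or head would project outside the frame are
    rejected and redrawn.  Click noise is isotropic Gaussian in pixels.

    Raises
    ------
    RuntimeError
        If the camera sees no ground within the distance range.
    """
    rng = rng or np.random.default_rng(spec.seed)
    intr, pose = spec.intrinsics, spec.pose
    cam = Camera(intr, pose)
    half_fov = np.arctan(intr.image_width_px / 2.0 / intr.f_pix)
    heading = np.radians(pose.heading_deg)
    w, h = intr.image_width_px, intr.image_height_px
    margin = 3.0 * spec.click_noise_px + 1.0

    feet, heads = [], []
    attempts, max_attempts = 0, 2000 * spec.n_objects
    while len(feet) < spec.n_objects:
        if attempts >= max_attempts:
            raise RuntimeError(
                "camera sees no (or almost no) ground within the requested "
                "distance range; cannot place objects")
        attempts += 1
        az = heading + rng.uniform(-half_fov, half_fov)
        dist = rng.uniform(*spec.distance_range_m)
        foot = np.array([pose.pos_x_m + dist * np.sin(az),
                         pose.pos_y_m + dist * np.cos(az), 0.0])
        head = foot + np.array([0.0, 0.0, spec.object_height_m])
        uv, vis = cam.project(np.stack([foot, head]))
        inside = (np.all(vis)
                  and np.all(uv[:, 0] > margin) and np.all(uv[:, 0] < w - margin)
                  and np.all(uv[:, 1] > margin) and np.all(uv[:, 1] < h - margin))
        if inside:
            feet.append(foot)
            heads.append(head)

    foot_world = np.array(feet)
    head_world = np.array(heads)
    uv_foot, _ = cam.project(foot_world)
    uv_head, _ = cam.project(head_world)
    uv_foot = _noisy_inside(uv_foot, spec.click_noise_px, rng, w, h)
    uv_head = _noisy_inside(uv_head, spec.click_noise_px, rng, w, h)
    clicks = ClickSet(foot=uv_foot, head=uv_head,
                      click_noise_px=max(spec.click_noise_px, 1e-6))
    return clicks, SceneTruth(camera=cam, foot_world=foot_world,
                              head_world=head_world)


def generate_horizon_clicks(spec: SceneSpec, n_points: int = 3,
                            horizon_model: HorizonModel | None = None,
                            rng: np.random.Generator | None = None
                            ) -> np.ndarray:
    """Sample clicks on the model horizon trace, with the scene's click noise.

    Raises
    ------
    ValueError
        If the horizon is not visible in the frame.
    """
    rng = rng or np.random.default_rng(spec.seed)
    pts = horizon_in_image(spec.intrinsics, spec.pose,
                           horizon_model or HorizonModel(), n_points=n_points)
    if len(pts) == 0:
        raise ValueError("horizon is outside the frame for this camera")
    return _noisy_inside(pts, spec.click_noise_px, rng,
                         spec.intrinsics.image_width_px,
                         spec.intrinsics.image_height_px)


def generate_landmark_scene(elevation_m: float = 300.0, n_landmarks: int = 8,
                            noise_px: float = 0.5, seed=None,
                            intrinsics: CameraIntrinsics | None = None,
                            tilt_deg: float = 15.0, heading_deg: float = 35.0,
                            pos_x_m: float = 20.0, pos_y_m: float = -40.0
                            ) -> tuple[LandmarkSet, SceneTruth]:
    """Aerial-survey-style scene: landmarks on the ground seen from high up.

    Defaults emulate oblique photographs taken from roughly 300 m above
    ground with eight identifiable points.  Targets are exact ground
    coordinates; the pixel clicks carry the noise.
    """
    rng = np.random.default_rng(seed)
    intr = intrinsics or default_intrinsics()
    pose = CameraPose(elevation_m=elevation_m, tilt_deg=tilt_deg,
                      heading_deg=heading_deg, pos_x_m=pos_x_m,
                      pos_y_m=pos_y_m)
    cam = Camera(intr, pose)
    w, h = intr.image_width_px, intr.image_height_px
    uv = np.stack([rng.uniform(0.08 * w, 0.92 * w, n_landmarks),
                   rng.uniform(0.08 * h, 0.92 * h, n_landmarks)], axis=1)
    ground = cam.backproject_to_plane(uv, z_plane=0.0)
    uv_noisy = _noisy_inside(uv, noise_px, rng, w, h)
    lm = LandmarkSet(image_points=uv_noisy, target_points=ground[:, :2])
    truth = SceneTruth(camera=cam, foot_world=ground,
                       head_world=ground.copy())
    return lm, truth


def generate_stereo_scene(baseline_m: float = 5.0, n_points: int = 20,
                          noise_px: float = 0.5, seed=None,
                          intrinsics: CameraIntrinsics | None = None,
                          rel_truth=(90.0, 0.0, 2.0, -1.0, -4.0),
                          object_height_m: float = 0.75):
    """Two-camera rig viewing shared points; first two points span one object.

    Camera A looks roughly horizontally from 10 m elevation; camera B is
    displaced by ``baseline_m`` along the relative direction in ``rel_truth``
    (azimuth, inclination, d_tilt, d_roll, d_heading).  Points 0 and 1 are
    the bottom and top of a vertical object of ``object_height_m`` so the
    known-size scale constraint can be exercised; the returned
    CorrespondenceSet carries the baseline constraint.

    Returns ``(corr, truth)`` where ``truth`` is a dict with the cameras, the
    relative parameters and the world points.
    """
    rng = np.random.default_rng(seed)
    intr = intrinsics or default_intrinsics()
    pose_a = CameraPose(elevation_m=10.0, tilt_deg=80.0)
    cam_a = Camera(intr, pose_a)
    cam_b = relative_camera(cam_a, rel_truth, intr, scale=baseline_m)

    pts = [np.array([0.0, 30.0, 0.0]),
           np.array([0.0, 30.0, object_height_m])]
    attempts = 0
    while len(pts) < n_points:
        if attempts > 5000 * n_points:
            raise RuntimeError("could not place stereo points visible in both "
                               "frames")
        attempts += 1
        az = np.radians(rng.uniform(-20.0, 20.0))
        dist = rng.uniform(15.0, 60.0)
        z = rng.uniform(0.0, 2.0)
        p = np.array([dist * np.sin(az), dist * np.cos(az), z])
        _, vis_a = cam_a.project(p)
        _, vis_b = cam_b.project(p)
        if vis_a and vis_b:
            pts.append(p)
    world = np.array(pts)
    uv_a, vis_a = cam_a.project(world)
    uv_b, vis_b = cam_b.project(world)
    if not (np.all(vis_a) and np.all(vis_b)):
        raise RuntimeError("fixed object points are not visible in both frames")
    w, h = intr.image_width_px, intr.image_height_px
    uv_a = _noisy_inside(uv_a, noise_px, rng, w, h)
    uv_b = _noisy_inside(uv_b, noise_px, rng, w, h)
    corr = CorrespondenceSet(points_a=uv_a, points_b=uv_b,
                             scale=ScaleConstraint(baseline_m=baseline_m))
    truth = {"camera_a": cam_a, "camera_b": cam_b,
             "rel_params": np.asarray(rel_truth, dtype=float),
             "baseline_m": baseline_m, "world_points": world,
             "known_size": (0, 1, object_height_m)}
    return corr, truth


def render_ground_pattern(camera: Camera, pattern, fill: float = 0.0
                          ) -> np.ndarray:
    """Render an image by sampling a ground-plane pattern through a camera.

    ``pattern(x, y)`` receives world ground coordinates and returns
    intensities; pixels whose rays miss the ground get ``fill``.  Used to
    build synthetic rasters for testing top-view warps.
    """
    intr = camera.intrinsics
    w, h = intr.image_width_px, intr.image_height_px
    u, v = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    uv = np.stack([u.ravel(), v.ravel()], axis=1)
    ground = camera.backproject_to_plane(uv, z_plane=0.0, strict=False)
    img = np.full(w * h, fill, dtype=float)
    ok = np.isfinite(ground[:, 0])
    img[ok] = pattern(ground[ok, 0], ground[ok, 1])
    return img.reshape(h, w)
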