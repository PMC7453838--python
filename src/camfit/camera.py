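"""Camera geometry: intrinsics, pose, projection and constrained backprojection.

Conventions
-----------
World frame
    Metric, z up, ``z = 0`` is the reference ground plane.  The camera sits at
    ``(pos_x, pos_y, elevation)``.
Camera frame
    ``x_c`` right, ``y_c`` down, ``z_c`` forward along the optical axis.
Angles
    *tilt* is the angle between the vertical and the optical axis (0 = nadir,
    90 deg = horizontal); *roll* rotates about the optical axis (0 = lower
    sensor edge horizontal); *heading* rotates the viewing direction in the
    horizontal plane, measured clockwise from the world +y axis.  Degrees at
    the interface, radians internally.
Pixels
    Continuous coordinates, origin at the top-left corner of the top-left
    pixel, ``u`` rightward, ``v`` downward.  Sub-pixel values are meaningful
    and projected points may fall outside the image rectangle (visibility is
    reported separately).

The world-to-camera rotation is composed as ``R = R_roll @ R_tilt @ R_heading``
applied after translating by minus the camera position:

* ``R_heading`` rotates about the world z axis so the viewing azimuth maps to +y,
* ``R_tilt`` maps the intermediate frame to the camera frame, with tilt = 0
  looking straight down (the image "up" direction then points along world +y),
* ``R_roll`` rotates about the optical axis.

All operations accept single points (shape ``(2,)``/``(3,)``) or batches
(``(n, 2)``/``(n, 3)``) and return matching shapes.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings

import numpy as np

from .distortion import apply_distortion, invert_distortion

__all__ = [
    "Projection", "CameraIntrinsics", "CameraPose", "Camera",
    "effective_focal_length", "rotation_world_to_camera",
    "NoGroundIntersectionError", "FootConstraintError",
]

#: Sentinel pixel value for points that cannot be projected (behind a
#: rectilinear camera).  They are additionally flagged invisible.
INVALID_PIXEL = np.nan


class NoGroundIntersectionError(ValueError):
    """A pixel ray is parallel to, or points away from, the requested plane."""


class FootConstraintError(ValueError):
    """A head-pixel ray has no sensible intersection with the vertical axis
    through the foot point (near-vertical ray or intersection behind the
    camera)."""


class Projection(str, enum.Enum):
    RECTILINEAR = "rectilinear"
    CYLINDRICAL = "cylindrical"
    EQUIRECTANGULAR = "equirectangular"


def _as_batch(points, dim):
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != dim:
        raise ValueError(f"expected points of dimension {dim}, got shape {pts.shape}")
    return pts, single


@dataclasses.dataclass(frozen=True)
class CameraIntrinsics:
    """Sensor and lens properties of a camera.

    Parameters
    ----------
    focal_length_mm : float
        Physical focal length in mm.
    sensor_width_mm, sensor_height_mm : float
        Sensor dimensions in mm.
    image_width_px, image_height_px : int
        Image dimensions in pixels.
    projection : Projection or str
        ``rectilinear`` (pinhole), ``cylindrical`` or ``equirectangular``.
    distortion : tuple of 3 floats
        Radial distortion coefficients ``(k1, k2, k3)`` acting in normalized
        image coordinates.
    aspect_tolerance : float
        Relative tolerance for the sensor-vs-image aspect-ratio consistency
        check (square pixels are assumed; a mismatch beyond the tolerance
        triggers a warning, not an error).
    """

    focal_length_mm: float
    sensor_width_mm: float
    sensor_height_mm: float
    image_width_px: int
    image_height_px: int
    projection: Projection = Projection.RECTILINEAR
    distortion: tuple = (0.0, 0.0, 0.0)
    aspect_tolerance: float = 0.01

    def __post_init__(self):
        for name in ("focal_length_mm", "sensor_width_mm", "sensor_height_mm",
                     "image_width_px", "image_height_px"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        object.__setattr__(self, "projection", Projection(self.projection))
        object.__setattr__(self, "distortion", tuple(float(k) for k in self.distortion))
        if len(self.distortion) != 3:
            raise ValueError("distortion must have exactly three coefficients")
        f_w = self.focal_length_mm * self.image_width_px / self.sensor_width_mm
        f_h = self.focal_length_mm * self.image_height_px / self.sensor_height_mm
        if abs(f_w - f_h) / f_w > self.aspect_tolerance:
            warnings.warn(
                "sensor and image aspect ratios disagree by more than "
                f"{self.aspect_tolerance:.1%}: focal length in pixels is "
                f"{f_w:.1f} from the width but {f_h:.1f} from the height; "
                "square pixels are assumed (width-based value used)",
                stacklevel=3)

    @property
    def f_pix(self) -> float:
        """Effective focal length in pixels, ``f * w_image / w_sensor``."""
        return self.focal_length_mm * self.image_width_px / self.sensor_width_mm

    @property
    def center(self) -> np.ndarray:
        """Principal point: the image center ``(w/2, h/2)`` in pixels."""
        return np.array([self.image_width_px / 2.0, self.image_height_px / 2.0])

    @property
    def has_distortion(self) -> bool:
        return any(k != 0.0 for k in self.distortion)


def effective_focal_length(intrinsics: CameraIntrinsics) -> float:
    """Effective focal length in pixels (re-scaling from sensor mm to image px)."""
    return intrinsics.f_pix


@dataclasses.dataclass(frozen=True)
class CameraPose:
    """Extrinsic placement of a camera.

    elevation_m is the camera height above the z = 0 reference plane; it must
    be positive for ground backprojection to be solvable.  Angles are stored
    in degrees; heading is normalized to [0, 360) and roll to (-180, 180].
    """

    elevation_m: float
    tilt_deg: float
    roll_deg: float = 0.0
    heading_deg: float = 0.0
    pos_x_m: float = 0.0
    pos_y_m: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.tilt_deg < 180.0):
            raise ValueError("tilt_deg must lie in [0, 180)")
        heading = float(self.heading_deg) % 360.0
        roll = (float(self.roll_deg) + 180.0) % 360.0 - 180.0
        if roll == -180.0:
            roll = 180.0
        object.__setattr__(self, "heading_deg", heading)
        object.__setattr__(self, "roll_deg", roll)

    @property
    def position(self) -> np.ndarray:
        """Camera center ``(pos_x, pos_y, elevation)`` in world coordinates."""
        return np.array([self.pos_x_m, self.pos_y_m, self.elevation_m])


def rotation_world_to_camera(pose: CameraPose) -> np.ndarray:
    """3x3 rotation taking world-frame vectors to camera-frame vectors.

    ``R = R_roll @ R_tilt @ R_heading`` with the conventions documented in the
    module header.  The full world-to-camera map for points is
    ``p_c = R @ (p_w - camera_position)``.
    """
    tau = np.radians(pose.tilt_deg)
    rho = np.radians(pose.roll_deg)
    phi = np.radians(pose.heading_deg)
    ch, sh = np.cos(phi), np.sin(phi)
    # heading: azimuth (clockwise from +y) of the view direction maps to +y
    r_head = np.array([[ch, -sh, 0.0],
                       [sh, ch, 0.0],
                       [0.0, 0.0, 1.0]])
    ct, st = np.cos(tau), np.sin(tau)
    # tilt: 0 = nadir (forward = -z_world), 90 = horizontal (forward = +y)
    r_tilt = np.array([[1.0, 0.0, 0.0],
                       [0.0, -ct, -st],
                       [0.0, st, -ct]])
    cr, sr = np.cos(rho), np.sin(rho)
    r_roll = np.array([[cr, sr, 0.0],
                       [-sr, cr, 0.0],
                       [0.0, 0.0, 1.0]])
    return r_roll @ r_tilt @ r_head


def camera_rays_from_pixels(intrinsics: CameraIntrinsics, pixels) -> np.ndarray:
    """Unit ray directions in the *camera* frame for the given pixels.

    Pose-independent: undistorts the normalized coordinates and inverts the
    projection model.  Useful for precomputing click geometry before a fit.
    """
    uv, single = _as_batch(pixels, 2)
    ab = (uv - intrinsics.center) / intrinsics.f_pix
    if intrinsics.has_distortion:
        ab = invert_distortion(ab, intrinsics.distortion)
    a, b = ab[:, 0], ab[:, 1]
    proj = intrinsics.projection
    if proj is Projection.RECTILINEAR:
        d = np.stack([a, b, np.ones_like(a)], axis=1)
    elif proj is Projection.CYLINDRICAL:
        d = np.stack([np.sin(a), b, np.cos(a)], axis=1)
    else:  # equirectangular
        cb = np.cos(b)
        d = np.stack([cb * np.sin(a), np.sin(b), cb * np.cos(a)], axis=1)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return d[0] if single else d


class Camera:
    """A camera = intrinsics + pose, with forward and inverse mappings."""

    def __init__(self, intrinsics: CameraIntrinsics, pose: CameraPose):
        self.intrinsics = intrinsics
        self.pose = pose
        self._R = rotation_world_to_camera(pose)
        self._C = pose.position

    def __repr__(self):
        return (f"Camera(f={self.intrinsics.focal_length_mm} mm, "
                f"{self.intrinsics.projection.value}, elevation="
                f"{self.pose.elevation_m} m, tilt={self.pose.tilt_deg} deg, "
                f"roll={self.pose.roll_deg} deg, heading={self.pose.heading_deg} deg)")

    @property
    def rotation(self) -> np.ndarray:
        return self._R

    @property
    def position(self) -> np.ndarray:
        return self._C

    # ---------------------------------------------------------------- frames
    def world_to_camera(self, points):
        """Rigid map of world points into the camera frame."""
        pts, single = _as_batch(points, 3)
        pc = (pts - self._C) @ self._R.T
        return pc[0] if single else pc

    def camera_to_world(self, points):
        pts, single = _as_batch(points, 3)
        pw = pts @ self._R + self._C
        return pw[0] if single else pw

    # ------------------------------------------------------------ projection
    def _project_camera_frame(self, pc):
        """Project camera-frame points/directions to pixels.

        Returns ``(uv, in_front)``; ``in_front`` is False for rectilinear
        points at or behind the image plane, whose pixels are set to the NaN
        sentinel.
        """
        x, y, z = pc[:, 0], pc[:, 1], pc[:, 2]
        intr = self.intrinsics
        proj = intr.projection
        with np.errstate(divide="ignore", invalid="ignore"):
            if proj is Projection.RECTILINEAR:
                in_front = z > 0
                a = np.where(in_front, x / np.where(in_front, z, 1.0), np.nan)
                b = np.where(in_front, y / np.where(in_front, z, 1.0), np.nan)
            else:
                rho = np.hypot(x, z)
                degenerate = rho == 0
                in_front = ~degenerate
                a = np.arctan2(x, z)
                if proj is Projection.CYLINDRICAL:
                    b = np.where(in_front, y / np.where(degenerate, 1.0, rho), np.nan)
                else:
                    b = np.arctan2(y, rho)
                a = np.where(in_front, a, np.nan)
        ab = np.stack([a, b], axis=1)
        if intr.has_distortion:
            finite = np.all(np.isfinite(ab), axis=1)
            out = np.full_like(ab, np.nan)
            out[finite] = apply_distortion(ab[finite], intr.distortion)
            ab = out
        uv = intr.f_pix * ab + intr.center
        return uv, in_front

    def project(self, points):
        """Project world points to pixel coordinates.

        Returns
        -------
        uv : ndarray, shape (..., 2)
            Pixel coordinates; NaN sentinel where the point is behind a
            rectilinear camera.
        visible : ndarray of bool
            True where the point is in front of the camera *and* inside the
            image rectangle.
        """
        pts, single = _as_batch(points, 3)
        pc = (pts - self._C) @ self._R.T
        uv, in_front = self._project_camera_frame(pc)
        visible = in_front & self._inside_frame(uv)
        if single:
            return uv[0], bool(visible[0])
        return uv, visible

    def project_directions(self, dirs_world):
        """Project world-frame view *directions* (no translation) to pixels."""
        dirs, single = _as_batch(dirs_world, 3)
        pc = dirs @ self._R.T
        uv, in_front = self._project_camera_frame(pc)
        if single:
            return uv[0], bool(in_front[0])
        return uv, in_front

    def _inside_frame(self, uv):
        w, h = self.intrinsics.image_width_px, self.intrinsics.image_height_px
        with np.errstate(invalid="ignore"):
            return (np.isfinite(uv).all(axis=1)
                    & (uv[:, 0] >= 0) & (uv[:, 0] <= w)
                    & (uv[:, 1] >= 0) & (uv[:, 1] <= h))

    # ---------------------------------------------------------- backprojection
    def pixel_rays(self, pixels):
        """Unit world-frame ray directions for the given pixels."""
        d_cam = camera_rays_from_pixels(self.intrinsics, pixels)
        single = d_cam.ndim == 1
        d_cam = np.atleast_2d(d_cam)
        d_world = d_cam @ self._R
        return d_world[0] if single else d_world

    def backproject_to_plane(self, pixels, z_plane: float = 0.0, strict: bool = True):
        """Intersect pixel rays with the horizontal plane ``z = z_plane``.

        Only intersections in front of the camera are valid.  With
        ``strict=True`` (default) an invalid ray raises
        :class:`NoGroundIntersectionError`; otherwise the corresponding rows
        are NaN.
        """
        uv, single = _as_batch(pixels, 2)
        d = np.atleast_2d(self.pixel_rays(uv))
        dz = d[:, 2]
        dist = z_plane - self._C[2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = dist / dz
        valid = np.isfinite(t) & (t > 0) & (np.abs(dz) > 1e-15)
        if strict and not np.all(valid):
            bad = np.flatnonzero(~valid)
            raise NoGroundIntersectionError(
                f"pixel ray(s) {bad.tolist()} do not intersect the plane "
                f"z={z_plane} in front of the camera (ray parallel to the "
                "plane or pointing away, e.g. a pixel above the horizon)")
        pts = self._C + t[:, None] * d
        pts[~valid] = np.nan
        return pts[0] if single else pts

    def backproject_with_foot_constraint(self, head_pixels, foot_world,
                                         strict: bool = True):
        """Backproject head pixels constrained to the foot's horizontal position.

        The head-pixel ray is intersected with the vertical axis through the
        foot's ground point, taking the point on the ray closest to that axis.
        The returned z coordinate is the estimated object height above the
        foot plane.
        """
        uv, single = _as_batch(head_pixels, 2)
        feet, _ = _as_batch(foot_world, 3)
        if feet.shape[0] != uv.shape[0]:
            raise ValueError("head_pixels and foot_world must pair up")
        d = np.atleast_2d(self.pixel_rays(uv))
        dxy = d[:, :2]
        denom = np.sum(dxy * dxy, axis=1)
        rel = feet[:, :2] - self._C[:2]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.sum(rel * dxy, axis=1) / denom
        valid = np.isfinite(t) & (t > 0) & (denom > 1e-18)
        if strict and not np.all(valid):
            bad = np.flatnonzero(~valid)
            raise FootConstraintError(
                f"head ray(s) {bad.tolist()} have no forward intersection with "
                "the vertical axis through the foot point")
        pts = self._C + t[:, None] * d
        pts[~valid] = np.nan
        return pts[0] if single else pts
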