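"""Stereo orientation: relative pose of two cameras from corresponding clicks.

When object sizes are unknown, two views of the same scene constrain the
cameras' *relative* orientation.  The fit minimizes the symmetric
point-to-epipolar-line distance in pixels: for each correspondence, the pixel
in image B should lie on the epipolar line of its partner pixel in image A,
and vice versa.  Pixel-space distances are preferred over world-space ray
distances because the latter mix scales across depth.

The relative pose has 5 identifiable degrees of freedom - the translation
*direction* (azimuth and inclination on the unit sphere) and three rotation
offsets (tilt/roll/heading deltas added to camera A's angles) - because the
epipolar cost is blind to scale.  The absolute scale is restored afterwards
from either a known baseline length or one known object size, and objects are
measured by triangulating pixel rays (midpoint of the common perpendicular).

Posterior uncertainty again comes from Metropolis sampling, in contrast to
closed-form approaches (e.g. the eight-point algorithm) that return only a
fundamental matrix without uncertainties.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import optimize

from .camera import Camera, CameraIntrinsics, CameraPose
from .sampling import ChainSummary, metropolis_sample

__all__ = ["ScaleConstraint", "CorrespondenceSet", "epipolar_line",
           "stereo_cost", "StereoModel", "StereoResults", "triangulate",
           "fit_relative_orientation", "relative_camera",
           "CoincidentCamerasError"]

_LOG_2PI = math.log(2.0 * math.pi)

#: Pixel distance charged when an epipolar line cannot be constructed for a
#: candidate pose (degenerate geometry); large but finite.
_DEGENERATE_PX = 1e4


class CoincidentCamerasError(ValueError):
    """Epipolar geometry is undefined for coincident camera centers."""


@dataclasses.dataclass(frozen=True)
class ScaleConstraint:
    """Absolute-scale information for a stereo rig.

    Exactly one of the two options must be given:

    * ``baseline_m`` - the distance between the two camera centers, or
    * ``known_size`` - ``(index_bottom, index_top, size_m)``: two
      correspondence indices marking the two ends of one object of known
      metric size.
    """

    baseline_m: float | None = None
    known_size: tuple | None = None

    def __post_init__(self):
        if (self.baseline_m is None) == (self.known_size is None):
            raise ValueError("give exactly one of baseline_m or known_size")
        if self.baseline_m is not None and not self.baseline_m > 0:
            raise ValueError("baseline must be positive")
        if self.known_size is not None:
            i, j, size = self.known_size
            if i == j or not size > 0:
                raise ValueError("known_size needs two distinct indices and a "
                                 "positive size")


@dataclasses.dataclass
class CorrespondenceSet:
    """Index-paired pixel clicks in two images plus one scale constraint."""

    points_a: np.ndarray
    points_b: np.ndarray
    scale: ScaleConstraint

    def __post_init__(self):
        self.points_a = np.atleast_2d(np.asarray(self.points_a, float))
        self.points_b = np.atleast_2d(np.asarray(self.points_b, float))
        if self.points_a.shape != self.points_b.shape or self.points_a.shape[1] != 2:
            raise ValueError("points_a and points_b must be (n, 2) of equal length")
        if len(self.points_a) < 8:
            warnings.warn(f"only {len(self.points_a)} correspondences; at "
                          "least 8 are recommended for a stable relative-pose "
                          "fit", stacklevel=2)

    def swapped(self) -> "CorrespondenceSet":
        """The same correspondences with the two cameras exchanged."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return CorrespondenceSet(self.points_b.copy(),
                                     self.points_a.copy(), self.scale)

    def __len__(self):
        return len(self.points_a)


def _direction_unit(azimuth_deg: float, inclination_deg: float) -> np.ndarray:
    """Unit vector from azimuth (clockwise from +y) and inclination above
    the horizontal."""
    az = math.radians(azimuth_deg)
    inc = math.radians(inclination_deg)
    c = math.cos(inc)
    return np.array([math.sin(az) * c, math.cos(az) * c, math.sin(inc)])


def relative_camera(cam_a: Camera, rel_params, intrinsics_b: CameraIntrinsics,
                    scale: float = 1.0) -> Camera:
    """Build camera B from camera A and relative-pose parameters.

    ``rel_params`` is (azimuth_deg, inclination_deg, d_tilt, d_roll,
    d_heading): B sits at ``A + scale * u(azimuth, inclination)`` and its
    tilt/roll/heading are A's plus the deltas.
    """
    az, inc, d_tilt, d_roll, d_head = (float(v) for v in rel_params[:5])
    pos_b = cam_a.position + scale * _direction_unit(az, inc)
    pose_a = cam_a.pose
    pose_b = CameraPose(elevation_m=pos_b[2],
                        tilt_deg=pose_a.tilt_deg + d_tilt,
                        roll_deg=pose_a.roll_deg + d_roll,
                        heading_deg=pose_a.heading_deg + d_head,
                        pos_x_m=pos_b[0], pos_y_m=pos_b[1])
    return Camera(intrinsics_b, pose_b)


def _epipolar_lines(points_a, cam_a: Camera, cam_b: Camera):
    """Vectorized epipolar lines in image B for pixels in image A.

    Each line is built geometrically: two points along A's pixel ray are
    projected into B and joined.  Returns unit normals ``(n, 2)``, offsets
    ``(n,)`` (so that point-line distance is ``|normal . p - offset|`` in
    pixels) and a validity mask.
    """
    baseline = np.linalg.norm(cam_b.position - cam_a.position)
    if baseline < 1e-12:
        raise CoincidentCamerasError("camera centers coincide; epipolar "
                                     "geometry is undefined")
    pts, = (np.atleast_2d(np.asarray(points_a, float)),)
    dirs = np.atleast_2d(cam_a.pixel_rays(pts))
    # sample the ray at two depths of the order of the baseline and beyond
    t1, t2 = 2.0 * baseline, 50.0 * baseline
    p1 = cam_a.position + t1 * dirs
    p2 = cam_a.position + t2 * dirs
    uv1, vis1 = cam_b.project(p1)
    uv2, vis2 = cam_b.project(p2)
    uv1, uv2 = np.atleast_2d(uv1), np.atleast_2d(uv2)
    tang = uv2 - uv1
    norm = np.linalg.norm(tang, axis=1)
    valid = (np.isfinite(uv1).all(axis=1) & np.isfinite(uv2).all(axis=1)
             & (norm > 1e-9))
    normal = np.empty_like(tang)
    normal[:, 0] = -tang[:, 1]
    normal[:, 1] = tang[:, 0]
    normal[valid] /= norm[valid, None]
    offset = np.einsum("ij,ij->i", normal, uv1)
    return normal, offset, valid


def epipolar_line(point_a, cam_a: Camera, cam_b: Camera):
    """Epipolar line in image B of a single pixel in image A.

    Returns ``(normal, offset)`` with a unit normal, so the distance of a
    pixel ``p`` in B to the line is ``|normal . p - offset|`` in pixels.
    """
    normal, offset, valid = _epipolar_lines(np.atleast_2d(point_a), cam_a, cam_b)
    if not valid[0]:
        raise ValueError("epipolar line is degenerate for this point/pose")
    return normal[0], float(offset[0])


def _directed_distances(points_a, points_b, cam_a, cam_b) -> np.ndarray:
    """Distances of B-pixels to the epipolar lines of their A-partners."""
    normal, offset, valid = _epipolar_lines(points_a, cam_a, cam_b)
    pts_b = np.atleast_2d(np.asarray(points_b, float))
    d = np.abs(np.einsum("ij,ij->i", normal, pts_b) - offset)
    return np.where(valid, d, _DEGENERATE_PX)


def stereo_cost(rel_params, corr: CorrespondenceSet,
                intrinsics_a: CameraIntrinsics, intrinsics_b: CameraIntrinsics,
                pose_a: CameraPose | None = None) -> float:
    """Symmetric mean point-to-epipolar-line distance (px) for a relative pose.

    ``pose_a`` anchors the frame of camera A (default: a canonical horizontal
    camera at the origin); the cost depends only on the *relative* pose, and
    is evaluated with a unit-length baseline since it is scale-blind.
    """
    if pose_a is None:
        pose_a = CameraPose(elevation_m=1.0, tilt_deg=90.0)
    cam_a = Camera(intrinsics_a, pose_a)
    try:
        cam_b = relative_camera(cam_a, rel_params, intrinsics_b, scale=1.0)
    except ValueError:
        return _DEGENERATE_PX
    d_ab = _directed_distances(corr.points_a, corr.points_b, cam_a, cam_b)
    d_ba = _directed_distances(corr.points_b, corr.points_a, cam_b, cam_a)
    return float(0.5 * (d_ab.mean() + d_ba.mean()))


def _closest_ray_points(uv_a, uv_b, cam_a: Camera, cam_b: Camera):
    """Closest points of paired pixel rays: returns (pa, pb, ta, tb, gaps)."""
    a = np.atleast_2d(np.asarray(uv_a, float))
    b = np.atleast_2d(np.asarray(uv_b, float))
    da = np.atleast_2d(cam_a.pixel_rays(a))
    db = np.atleast_2d(cam_b.pixel_rays(b))
    oa, ob = cam_a.position, cam_b.position
    w0 = oa - ob
    d_ab = np.einsum("ij,ij->i", da, db)
    denom = 1.0 - d_ab ** 2                      # rays are unit vectors
    sa = np.einsum("ij,j->i", db * d_ab[:, None] - da, w0)
    sb = np.einsum("ij,j->i", db - da * d_ab[:, None], w0)
    near_parallel = denom < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = sa / denom
        tb = sb / denom
    pa = oa + ta[:, None] * da
    pb = ob + tb[:, None] * db
    gaps = np.linalg.norm(pa - pb, axis=1)
    pa[near_parallel] = np.nan
    pb[near_parallel] = np.nan
    gaps[near_parallel] = np.inf
    return pa, pb, ta, tb, gaps


def triangulate(uv_a, uv_b, cam_a: Camera, cam_b: Camera,
                gap_warn_m: float | None = None):
    """Triangulate paired pixels as the midpoint of the common perpendicular.

    Returns ``(points, gaps)`` where ``gaps`` is the closest distance between
    the two rays (m) - a quality measure that is 0 for exactly intersecting
    rays and grows with click noise or near-parallel geometry.  Near-parallel
    rays yield NaN points.
    """
    singleton = np.asarray(uv_a).ndim == 1
    pa, pb, _, _, gaps = _closest_ray_points(uv_a, uv_b, cam_a, cam_b)
    mid = 0.5 * (pa + pb)
    if gap_warn_m is not None and np.any(gaps > gap_warn_m):
        warnings.warn("triangulated rays have large closest-approach gaps; "
                      "results are low-confidence", stacklevel=2)
    if singleton:
        return mid[0], float(gaps[0])
    return mid, gaps


class StereoModel:
    """Posterior model for the 5-d.o.f. relative pose of a stereo rig.

    The likelihood converts the symmetric epipolar distances to a Gaussian
    score with pixel scale ``sigma_px`` (default 1 px).
    """

    param_names = ["azimuth_deg", "inclination_deg", "d_tilt_deg",
                   "d_roll_deg", "d_heading_deg"]

    def __init__(self, corr: CorrespondenceSet, intrinsics_a: CameraIntrinsics,
                 intrinsics_b: CameraIntrinsics | None = None,
                 pose_a: CameraPose | None = None, sigma_px: float = 1.0):
        self.corr = corr
        self.intrinsics_a = intrinsics_a
        self.intrinsics_b = intrinsics_b or intrinsics_a
        self.pose_a = pose_a or CameraPose(elevation_m=1.0, tilt_deg=90.0)
        self.sigma_px = float(sigma_px)
        self._cam_a = Camera(self.intrinsics_a, self.pose_a)

    def _distances(self, rel_params) -> np.ndarray | None:
        try:
            cam_b = relative_camera(self._cam_a, rel_params,
                                    self.intrinsics_b, scale=1.0)
        except ValueError:
            return None
        d_ab = _directed_distances(self.corr.points_a, self.corr.points_b,
                                   self._cam_a, cam_b)
        d_ba = _directed_distances(self.corr.points_b, self.corr.points_a,
                                   cam_b, self._cam_a)
        return np.concatenate([d_ab, d_ba])

    def cost(self, rel_params) -> float:
        d = self._distances(np.asarray(rel_params, dtype=float))
        if d is None:
            return _DEGENERATE_PX
        return float(0.5 * (d[:len(self.corr)].mean() + d[len(self.corr):].mean()))

    def front_fraction(self, rel_params) -> float:
        """Fraction of correspondences triangulating in front of both cameras.

        The epipolar cost is invariant under reversing the baseline (the
        "twisted-pair" ambiguity); requiring positive ray depths (cheirality)
        selects the physical solution.
        """
        try:
            cam_b = relative_camera(self._cam_a, rel_params,
                                    self.intrinsics_b, scale=1.0)
        except ValueError:
            return 0.0
        _, _, ta, tb, _ = _closest_ray_points(self.corr.points_a,
                                              self.corr.points_b,
                                              self._cam_a, cam_b)
        return float(np.mean((ta > 0) & (tb > 0)))

    def loglike(self, rel_params) -> float:
        rel_params = np.asarray(rel_params, dtype=float)
        if not (-90.0 < rel_params[1] < 90.0):
            return -np.inf
        if np.any(np.abs(rel_params[2:5]) > 90.0):
            return -np.inf
        d = self._distances(rel_params)
        if d is None:
            return -np.inf
        if self.front_fraction(rel_params) < 0.5:  # cheirality
            return -np.inf
        return float(-0.5 * np.sum((d / self.sigma_px) ** 2)
                     - d.size * (math.log(self.sigma_px) + 0.5 * _LOG_2PI))

    def _signed_residuals(self, rel_params) -> np.ndarray:
        """Signed epipolar residuals (2n,) in both directions, for LM."""
        try:
            cam_b = relative_camera(self._cam_a, rel_params,
                                    self.intrinsics_b, scale=1.0)
        except ValueError:
            return np.full(2 * len(self.corr), _DEGENERATE_PX)

        def signed(points_a, points_b, ca, cb):
            normal, offset, valid = _epipolar_lines(points_a, ca, cb)
            pts_b = np.atleast_2d(np.asarray(points_b, float))
            d = np.einsum("ij,ij->i", normal, pts_b) - offset
            return np.where(valid, d, _DEGENERATE_PX)

        return np.concatenate([
            signed(self.corr.points_a, self.corr.points_b, self._cam_a, cam_b),
            signed(self.corr.points_b, self.corr.points_a, cam_b, self._cam_a)])

    def _optimize_init(self, rng: np.random.Generator, n_starts: int = 10
                       ) -> np.ndarray:
        best_x, best_c = None, np.inf
        for _ in range(n_starts):
            x0 = np.array([rng.uniform(0.0, 360.0), rng.uniform(-30.0, 30.0),
                           rng.uniform(-10.0, 10.0), rng.uniform(-10.0, 10.0),
                           rng.uniform(-10.0, 10.0)])
            try:
                res = optimize.least_squares(self._signed_residuals, x0,
                                             method="lm", max_nfev=2000)
            except Exception:
                continue
            c = self.cost(res.x)
            if c < best_c:
                best_x, best_c = res.x, c
            if best_c < 2.0 * self.sigma_px:
                break
        # resolve the baseline-reversal ambiguity by cheirality
        twin = best_x.copy()
        twin[0] = (twin[0] + 180.0) % 360.0
        twin[1] = -twin[1]
        if self.front_fraction(twin) > self.front_fraction(best_x):
            best_x = twin
        return best_x

    def scale_from_constraint(self, rel_params) -> float:
        """Metric scale factor implied by the rig's scale constraint."""
        sc = self.corr.scale
        if sc.baseline_m is not None:
            return float(sc.baseline_m)
        i, j, size = sc.known_size
        cam_b = relative_camera(self._cam_a, rel_params, self.intrinsics_b,
                                scale=1.0)
        pts, _ = triangulate(self.corr.points_a[[i, j]],
                             self.corr.points_b[[i, j]], self._cam_a, cam_b)
        d_unit = float(np.linalg.norm(pts[0] - pts[1]))
        if not np.isfinite(d_unit) or d_unit <= 0:
            raise ValueError("known-size pair cannot be triangulated under "
                             "the fitted pose")
        return float(size) / d_unit

    def fit(self, n_iter: int = 10_000, seed=None, init=None,
            proposal_scales=None, adapt: bool = True,
            burn_in_frac: float = 0.2) -> "StereoResults":
        rng = np.random.default_rng(seed)
        x0 = self._optimize_init(rng) if init is None else np.asarray(init, float)
        if proposal_scales is None:
            proposal_scales = [0.2, 0.2, 0.1, 0.1, 0.1]
        chain = metropolis_sample(self.loglike, x0, proposal_scales, n_iter,
                                  rng=rng, adapt=adapt,
                                  burn_in_frac=burn_in_frac,
                                  param_names=list(self.param_names))
        chain.seed = seed
        return StereoResults(chain, self)


class StereoResults:
    """Relative-pose posterior plus the scale restored from the constraint."""

    def __init__(self, chain: ChainSummary, model: StereoModel):
        self.chain = chain
        self.model = model

    @property
    def params(self) -> dict:
        return dict(zip(self.chain.param_names, self.chain.mean))

    @property
    def bse(self) -> dict:
        return dict(zip(self.chain.param_names, self.chain.sd))

    @property
    def scale_m(self) -> float:
        return self.model.scale_from_constraint(self.chain.mean)

    @property
    def baseline_m(self) -> float:
        """Distance between the two camera centers (m)."""
        return self.scale_m  # translation direction is a unit vector

    @property
    def camera_b(self) -> Camera:
        """Camera B at the posterior-mean relative pose, metrically scaled."""
        return relative_camera(self.model._cam_a, self.chain.mean,
                               self.model.intrinsics_b, scale=self.scale_m)

    def triangulate(self, uv_a=None, uv_b=None):
        """Triangulate correspondences (default: the fitted set) in meters."""
        if uv_a is None:
            uv_a, uv_b = self.model.corr.points_a, self.model.corr.points_b
        return triangulate(uv_a, uv_b, self.model._cam_a, self.camera_b)

    def summary(self) -> str:
        head = ("Stereo relative-orientation fit\n"
                f"correspondences: {len(self.model.corr)}   "
                f"pixel noise scale: {self.model.sigma_px} px   "
                f"baseline: {self.baseline_m:.3f} m\n\n")
        return head + self.chain.summary()


def fit_relative_orientation(corr: CorrespondenceSet,
                             intrinsics_a: CameraIntrinsics,
                             intrinsics_b: CameraIntrinsics | None = None,
                             **options) -> StereoResults:
    """Fit the relative orientation of two cameras from correspondences."""
    pose_a = options.pop("pose_a", None)
    sigma_px = options.pop("sigma_px", 1.0)
    model = StereoModel(corr, intrinsics_a, intrinsics_b, pose_a=pose_a,
                        sigma_px=sigma_px)
    return model.fit(**options)
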