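"""Geo-registration: fit camera position, heading, elevation and tilt from
landmark correspondences between the image and a map.

For near-nadir imagery (e.g. photographs from an aircraft) object sizes vary
too little across the frame for the height-based fit, and the horizon is not
visible.  If geo-referenced landmarks can be identified in the image, the
camera pose is instead estimated by backprojecting the clicked image points
onto the ground plane and minimizing their distances to the known map
coordinates.  Five parameters are fitted: elevation, tilt, x/y position and
heading; roll is held at zero by default (near-nadir roll and heading are
partially degenerate) but can be unlocked.

Uncertainty is quantified with the same Metropolis machinery as the
height-based fit, using an isotropic Gaussian measurement model on the
ground-plane distances; a deterministic least-squares refinement of the
posterior mean is reported alongside.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import optimize

from .camera import Camera, CameraIntrinsics, CameraPose
from .sampling import ChainSummary, metropolis_sample

__all__ = ["LandmarkSet", "latlon_to_local", "local_to_latlon",
           "registration_cost", "GeoRegistrationModel", "GeoRefResults",
           "fit_georeference"]

EARTH_RADIUS_M = 6_371_000.0
_LOG_2PI = math.log(2.0 * math.pi)

#: Ground-distance (m) charged to a landmark whose ray misses the ground plane
#: under a candidate pose; keeps the cost finite so samplers stay total.
_MISS_DISTANCE_M = 1e6


def latlon_to_local(lat, lon, ref_lat, ref_lon,
                    radius: float = EARTH_RADIUS_M):
    """Equirectangular local-tangent-plane projection about a reference point.

    Returns metric ``(x, y)`` with x east and y north.  Adequate for scenes up
    to a few kilometres; the inverse is :func:`local_to_latlon`.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude must lie in [-90, 90]")
    y = np.radians(lat - ref_lat) * radius
    x = np.radians(lon - ref_lon) * radius * math.cos(math.radians(ref_lat))
    return x, y


def local_to_latlon(x, y, ref_lat, ref_lon,
                    radius: float = EARTH_RADIUS_M):
    """Inverse of :func:`latlon_to_local` (round-trip exact to float precision)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lat = ref_lat + np.degrees(y / radius)
    lon = ref_lon + np.degrees(x / (radius * math.cos(math.radians(ref_lat))))
    return lat, lon


@dataclasses.dataclass
class LandmarkSet:
    """Index-paired image pixels and metric map targets (local tangent frame)."""

    image_points: np.ndarray
    target_points: np.ndarray

    def __post_init__(self):
        self.image_points = np.atleast_2d(np.asarray(self.image_points, float))
        self.target_points = np.atleast_2d(np.asarray(self.target_points, float))
        if self.image_points.shape[1] != 2 or self.target_points.shape[1] != 2:
            raise ValueError("image and target points must be (n, 2)")
        if len(self.image_points) != len(self.target_points):
            raise ValueError("image and target points must pair up by index")
        if len(self.image_points) < 3:
            raise ValueError("at least 3 landmark pairs are required to fit "
                             "the 5 pose parameters")
        if self._collinear(self.target_points):
            warnings.warn("landmark targets are nearly collinear; the pose "
                          "fit will be ill-conditioned", stacklevel=2)

    @staticmethod
    def _collinear(pts: np.ndarray, tol: float = 1e-3) -> bool:
        centered = pts - pts.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        return bool(s[0] > 0 and s[1] / s[0] < tol)

    @classmethod
    def from_latlon(cls, image_points, lat, lon, ref_lat=None, ref_lon=None):
        """Build a landmark set from geographic targets.

        The reference point defaults to the centroid of the targets; it is
        stored on the instance as ``(ref_lat, ref_lon)`` for converting
        results back.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        if ref_lat is None:
            ref_lat = float(lat.mean())
        if ref_lon is None:
            ref_lon = float(lon.mean())
        x, y = latlon_to_local(lat, lon, ref_lat, ref_lon)
        obj = cls(image_points, np.stack([x, y], axis=1))
        obj.ref_lat, obj.ref_lon = ref_lat, ref_lon
        return obj

    def __len__(self):
        return len(self.image_points)


def _ground_distances(params, lm: LandmarkSet, intrinsics: CameraIntrinsics,
                      roll_deg: float = 0.0) -> np.ndarray:
    """Per-landmark ground-plane distances (m) under a candidate pose."""
    elevation, tilt, pos_x, pos_y, heading = (float(v) for v in params[:5])
    if len(params) > 5:
        roll_deg = float(params[5])
    if elevation <= 0 or not (0 <= tilt < 90):
        return np.full(len(lm), _MISS_DISTANCE_M)
    pose = CameraPose(elevation_m=elevation, tilt_deg=tilt, roll_deg=roll_deg,
                      heading_deg=heading, pos_x_m=pos_x, pos_y_m=pos_y)
    cam = Camera(intrinsics, pose)
    ground = cam.backproject_to_plane(lm.image_points, z_plane=0.0, strict=False)
    d = np.linalg.norm(ground[:, :2] - lm.target_points, axis=1)
    return np.where(np.isfinite(d), d, _MISS_DISTANCE_M)


def registration_cost(params, lm: LandmarkSet,
                      intrinsics: CameraIntrinsics) -> float:
    """RMS ground-plane distance (m) between backprojected landmarks and targets.

    ``params`` is (elevation, tilt, pos_x, pos_y, heading[, roll]).  Landmarks
    whose rays miss the ground under the candidate pose are charged a large
    finite distance, keeping the cost total for optimizers and samplers.
    """
    d = _ground_distances(np.asarray(params, dtype=float), lm, intrinsics)
    return float(np.sqrt(np.mean(d * d)))


class GeoRegistrationModel:
    """Posterior model for (elevation, tilt, pos_x, pos_y, heading).

    The measurement model is isotropic Gaussian noise of scale ``sigma_m``
    (default 1 m) on the ground-plane position of each landmark.
    """

    def __init__(self, landmarks: LandmarkSet, intrinsics: CameraIntrinsics,
                 sigma_m: float = 1.0, fit_roll: bool = False):
        self.landmarks = landmarks
        self.intrinsics = intrinsics
        self.sigma_m = float(sigma_m)
        self.fit_roll = fit_roll
        self.param_names = ["elevation_m", "tilt_deg", "pos_x_m", "pos_y_m",
                            "heading_deg"]
        if fit_roll:
            self.param_names.append("roll_deg")

    def residuals(self, params) -> np.ndarray:
        """2n vector of x/y ground-plane residuals (m), for least squares."""
        params = np.asarray(params, dtype=float)
        elevation, tilt = params[0], params[1]
        if elevation <= 0 or not (0 <= tilt < 90):
            return np.full(2 * len(self.landmarks), _MISS_DISTANCE_M)
        roll = float(params[5]) if self.fit_roll and len(params) > 5 else 0.0
        pose = CameraPose(elevation_m=elevation, tilt_deg=tilt, roll_deg=roll,
                          heading_deg=params[4], pos_x_m=params[2],
                          pos_y_m=params[3])
        cam = Camera(self.intrinsics, pose)
        ground = cam.backproject_to_plane(self.landmarks.image_points,
                                          z_plane=0.0, strict=False)
        res = ground[:, :2] - self.landmarks.target_points
        res = np.where(np.isfinite(res), res, _MISS_DISTANCE_M)
        return res.ravel()

    def cost(self, params) -> float:
        d = _ground_distances(np.asarray(params, dtype=float), self.landmarks,
                              self.intrinsics)
        return float(np.sqrt(np.mean(d * d)))

    def loglike(self, params) -> float:
        params = np.asarray(params, dtype=float)
        d = _ground_distances(params, self.landmarks, self.intrinsics)
        n = d.size
        return float(-0.5 * np.sum((d / self.sigma_m) ** 2)
                     - n * (math.log(self.sigma_m) + _LOG_2PI))

    def refine(self, params0) -> np.ndarray:
        """Deterministic least-squares refinement of a parameter vector."""
        res = optimize.least_squares(self.residuals,
                                     np.asarray(params0, dtype=float),
                                     method="lm", max_nfev=2000)
        return res.x

    def _initial_guess(self, rng: np.random.Generator, n_starts: int = 15
                       ) -> np.ndarray:
        """Multi-start least squares from heuristic random initializations."""
        targets = self.landmarks.target_points
        centroid = targets.mean(axis=0)
        span = max(np.ptp(targets, axis=0).max(), 10.0)
        best_x, best_c = None, np.inf
        for _ in range(n_starts):
            x0 = np.array([
                math.exp(rng.uniform(math.log(10.0), math.log(2000.0))),
                rng.uniform(0.5, 45.0),
                centroid[0] + rng.uniform(-2 * span, 2 * span),
                centroid[1] + rng.uniform(-2 * span, 2 * span),
                rng.uniform(0.0, 360.0),
            ])
            if self.fit_roll:
                x0 = np.append(x0, rng.uniform(-5.0, 5.0))
            try:
                x = self.refine(x0)
            except Exception:
                continue
            c = self.cost(x)
            if c < best_c:
                best_x, best_c = x, c
            if best_c < 10.0 * self.sigma_m:
                break
        if best_x is None:
            raise RuntimeError("geo-registration initialization failed")
        return best_x

    def fit(self, n_iter: int = 10_000, seed=None, init=None,
            proposal_scales=None, adapt: bool = True, refine: bool = True,
            burn_in_frac: float = 0.2) -> "GeoRefResults":
        rng = np.random.default_rng(seed)
        x0 = self._initial_guess(rng) if init is None else np.asarray(init, float)
        if proposal_scales is None:
            proposal_scales = [1.0, 0.2, 1.0, 1.0, 0.2]
            if self.fit_roll:
                proposal_scales.append(0.2)
        chain = metropolis_sample(self.loglike, x0, proposal_scales, n_iter,
                                  rng=rng, adapt=adapt,
                                  burn_in_frac=burn_in_frac,
                                  param_names=list(self.param_names))
        chain.seed = seed
        refined = self.refine(chain.mean) if refine else None
        return GeoRefResults(chain, self, refined)


class GeoRefResults:
    """Posterior chain plus (optionally) a least-squares refined point estimate."""

    def __init__(self, chain: ChainSummary, model: GeoRegistrationModel,
                 refined_params: np.ndarray | None):
        self.chain = chain
        self.model = model
        self.refined_params = refined_params

    @property
    def params(self) -> dict:
        return dict(zip(self.chain.param_names, self.chain.mean))

    @property
    def bse(self) -> dict:
        return dict(zip(self.chain.param_names, self.chain.sd))

    @property
    def best_params(self) -> np.ndarray:
        if self.refined_params is not None:
            return self.refined_params
        return self.chain.mean

    @property
    def rms_m(self) -> float:
        """RMS ground distance (m) at the best point estimate."""
        return self.model.cost(self.best_params)

    @property
    def pose(self) -> CameraPose:
        p = self.best_params
        roll = float(p[5]) if self.model.fit_roll and len(p) > 5 else 0.0
        return CameraPose(elevation_m=p[0], tilt_deg=p[1], roll_deg=roll,
                          heading_deg=p[4], pos_x_m=p[2], pos_y_m=p[3])

    @property
    def camera(self) -> Camera:
        return Camera(self.model.intrinsics, self.pose)

    def summary(self) -> str:
        head = ("Geo-registration fit from landmark correspondences\n"
                f"landmarks: {len(self.model.landmarks)}   "
                f"measurement sd: {self.model.sigma_m} m   "
                f"rms at best estimate: {self.rms_m:.3f} m\n\n")
        body = self.chain.summary()
        if self.refined_params is not None:
            ref = ", ".join(f"{n}={v:.4f}" for n, v in
                            zip(self.chain.param_names, self.refined_params))
            body += f"\nleast-squares refined estimate: {ref}\n"
        return head + body


def fit_georeference(landmarks: LandmarkSet, intrinsics: CameraIntrinsics,
                     **options) -> GeoRefResults:
    """Fit camera elevation, tilt, x/y position and heading from landmarks."""
    sigma_m = options.pop("sigma_m", 1.0)
    fit_roll = options.pop("fit_roll", False)
    model = GeoRegistrationModel(landmarks, intrinsics, sigma_m=sigma_m,
                                 fit_roll=fit_roll)
    return model.fit(**options)
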