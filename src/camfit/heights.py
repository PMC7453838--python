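"""Extrinsic calibration from known object heights (foot/head clicks).

The measurement model follows the object-height argument: each annotated
object contributes a foot pixel (assumed to lie on the ground plane z = 0) and
a head pixel.  For a candidate pose the foot is backprojected onto the ground,
the head ray is intersected with the vertical axis through that foot point,
and the resulting height is scored under a user-supplied height distribution
(typically normal with known mean; its spread may be sampled as a free
parameter).  Optionally, clicked horizon points are scored by their pixel
distance to the projected spherical-earth horizon.  The joint posterior over
(elevation, tilt, roll) is explored with Metropolis sampling.

Heading and x/y position are not identifiable from heights or the horizon
(both are invariant under rotating the camera about the vertical axis and
sliding it along the ground), so they are held fixed at zero during this fit.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import optimize

from .camera import (Camera, CameraIntrinsics, CameraPose,
                     camera_rays_from_pixels)
from .horizon import HorizonModel, horizon_trace, point_to_polyline_distance
from .sampling import ChainSummary, metropolis_sample

__all__ = ["ClickSet", "HeightPrior", "ObjectHeightModel", "ExtrinsicResults",
           "object_height_loglik", "horizon_loglik", "fit_extrinsics"]

_LOG_2PI = math.log(2.0 * math.pi)

#: Finite log-probability penalty used where the sampler must stay total:
#: e.g. horizon clicks provided but the model horizon not projectable for
#: the candidate pose.  Large finite beats -inf so chains can recover.
_SOFT_PENALTY = -1e8

FREE = "free"


@dataclasses.dataclass
class ClickSet:
    """Paired foot/head pixel annotations plus optional horizon clicks."""

    foot: np.ndarray
    head: np.ndarray
    horizon: np.ndarray | None = None
    click_noise_px: float = 1.0

    def __post_init__(self):
        self.foot = np.atleast_2d(np.asarray(self.foot, dtype=float))
        self.head = np.atleast_2d(np.asarray(self.head, dtype=float))
        if self.foot.shape != self.head.shape or self.foot.shape[1] != 2:
            raise ValueError("foot and head must be (n, 2) arrays of equal length")
        if len(self.foot) < 1:
            raise ValueError("at least one foot/head pair is required")
        if self.horizon is not None:
            self.horizon = np.atleast_2d(np.asarray(self.horizon, dtype=float))
            if self.horizon.shape[1] != 2:
                raise ValueError("horizon clicks must be (m, 2)")
            if len(self.horizon) == 0:
                self.horizon = None
        if not self.click_noise_px > 0:
            raise ValueError("click_noise_px must be positive")

    @property
    def n_objects(self) -> int:
        return len(self.foot)


@dataclasses.dataclass
class HeightPrior:
    """Distribution of the true object heights.

    ``sd_m`` may be a positive float or the string ``"free"``, in which case
    the spread is sampled (in log space, to enforce positivity) alongside the
    pose parameters.  A non-Gaussian distribution can be supplied as
    ``logpdf`` (vectorized over heights); it overrides the normal density.
    """

    mean_m: float
    sd_m: float | str = 0.05
    logpdf: object = None

    def __post_init__(self):
        if not self.mean_m > 0:
            raise ValueError("mean height must be positive")
        if not self.is_free and not float(self.sd_m) > 0:
            raise ValueError("sd_m must be positive (or 'free')")

    @property
    def is_free(self) -> bool:
        return isinstance(self.sd_m, str) and self.sd_m.lower() == FREE


def _normal_loglik(heights: np.ndarray, mean: float, sd: float) -> float:
    z = (heights - mean) / sd
    return float(-0.5 * np.sum(z * z) - heights.size * (math.log(sd) + 0.5 * _LOG_2PI))


class ObjectHeightModel:
    """Posterior model for (elevation, tilt, roll) given foot/head clicks.

    Parameters
    ----------
    clicks : ClickSet
    intrinsics : CameraIntrinsics
    prior : HeightPrior
    horizon_model : HorizonModel, optional
        Earth model used to score horizon clicks; defaults to the standard
        6 371 km sphere.  Ignored when the click set has no horizon points.
    bounds : dict, optional
        Flat-prior support per parameter; defaults to elevation 1-100 m,
        tilt 30-120 deg, roll +/-10 deg.
    """

    def __init__(self, clicks: ClickSet, intrinsics: CameraIntrinsics,
                 prior: HeightPrior, horizon_model: HorizonModel | None = None,
                 bounds: dict | None = None):
        self.clicks = clicks
        self.intrinsics = intrinsics
        self.prior = prior
        self.horizon_model = horizon_model or HorizonModel()
        default_bounds = {
            "elevation_m": (1.0, 100.0),
            "tilt_deg": (30.0, 120.0),
            "roll_deg": (-10.0, 10.0),
            "log_height_sd": (math.log(1e-3), math.log(0.5)),
        }
        if bounds:
            default_bounds.update(bounds)
        self.bounds = default_bounds
        self.param_names = ["elevation_m", "tilt_deg", "roll_deg"]
        if prior.is_free:
            self.param_names.append("log_height_sd")
        # Pixel rays in the camera frame are pose-independent: precompute.
        self._rays_foot = camera_rays_from_pixels(intrinsics, clicks.foot)
        self._rays_head = camera_rays_from_pixels(intrinsics, clicks.head)

    # ------------------------------------------------------------------ core
    def _heights(self, elevation: float, rot: np.ndarray) -> np.ndarray | None:
        """Per-object heights implied by a pose, or None when infeasible."""
        dw_f = self._rays_foot @ rot            # world-frame foot rays
        dz = dw_f[:, 2]
        if np.any(dz >= -1e-12):                # foot click at/above horizon
            return None
        t = -elevation / dz
        foot_xy = t[:, None] * dw_f[:, :2]
        dw_h = self._rays_head @ rot
        dxy = dw_h[:, :2]
        denom = np.einsum("ij,ij->i", dxy, dxy)
        if np.any(denom <= 1e-18):
            return None
        t_h = np.einsum("ij,ij->i", foot_xy, dxy) / denom
        if np.any(t_h <= 0):
            return None
        return elevation + t_h * dw_h[:, 2]

    def _height_term(self, heights: np.ndarray, sd: float) -> float:
        if self.prior.logpdf is not None:
            return float(np.sum(self.prior.logpdf(heights)))
        return _normal_loglik(heights, self.prior.mean_m, sd)

    def _horizon_term(self, camera: Camera) -> float:
        trace = horizon_trace(camera, self.horizon_model, n_dense=41, widen=1.2)
        if len(trace) < 2:
            return _SOFT_PENALTY
        d = point_to_polyline_distance(self.clicks.horizon, trace)
        sigma = self.clicks.click_noise_px
        return float(-0.5 * np.sum((d / sigma) ** 2)
                     - d.size * (math.log(sigma) + 0.5 * _LOG_2PI))

    def loglike(self, params) -> float:
        """Log posterior density (up to a constant) of a parameter vector."""
        params = np.asarray(params, dtype=float)
        for value, name in zip(params, self.param_names):
            lo, hi = self.bounds[name]
            if not (lo <= value <= hi):
                return -np.inf
        elevation, tilt, roll = params[:3]
        sd = math.exp(params[3]) if self.prior.is_free else float(self.prior.sd_m)
        pose = CameraPose(elevation_m=elevation, tilt_deg=tilt, roll_deg=roll)
        cam = Camera(self.intrinsics, pose)
        heights = self._heights(elevation, cam.rotation)
        if heights is None:
            return -np.inf
        ll = self._height_term(heights, sd)
        if self.clicks.horizon is not None:
            ll += self._horizon_term(cam)
        return ll

    # ------------------------------------------------------------------- fit
    def _random_init(self, rng: np.random.Generator, max_restarts: int = 10):
        ranges = [(1.0, 100.0), (30.0, 120.0), (-10.0, 10.0)]
        if self.prior.is_free:
            ranges.append((math.log(0.01), math.log(0.2)))
        for _ in range(max_restarts):
            x = np.array([rng.uniform(lo, hi) for lo, hi in ranges])
            if np.isfinite(self.loglike(x)):
                return x
        raise RuntimeError("could not find a feasible random initialization "
                           f"in {max_restarts} restarts")

    def _optimize_init(self, x0: np.ndarray) -> np.ndarray:
        """Deterministic refinement of a starting point.

        With a free height spread the pose is climbed first at a fixed,
        moderate spread (otherwise the optimizer can inflate the spread to
        absorb a wrong elevation), then the spread is set from the residual
        height scatter before a joint polish.
        """
        def _nm(fun, x):
            res = optimize.minimize(fun, x, method="Nelder-Mead",
                                    options={"maxiter": 400 * len(x),
                                             "xatol": 1e-6, "fatol": 1e-8})
            return res.x

        def negloglik(p):
            ll = self.loglike(p)
            return 1e15 if not np.isfinite(ll) else -ll

        if self.prior.is_free:
            sd_fixed = math.log(max(0.1 * self.prior.mean_m, 1e-3))
            pose = _nm(lambda p: negloglik(np.append(p, sd_fixed)), x0[:3])
            cam = Camera(self.intrinsics,
                         CameraPose(elevation_m=np.clip(pose[0], 1.0, 100.0),
                                    tilt_deg=np.clip(pose[1], 30.0, 120.0),
                                    roll_deg=np.clip(pose[2], -10.0, 10.0)))
            heights = self._heights(cam.pose.elevation_m, cam.rotation)
            if heights is not None:
                resid = float(np.std(heights - self.prior.mean_m))
                lo, hi = self.bounds["log_height_sd"]
                sd0 = np.clip(math.log(max(resid, 1e-3)), lo, hi)
            else:
                sd0 = sd_fixed
            x0 = np.append(pose, sd0)
        x = _nm(negloglik, x0)
        return x if np.isfinite(self.loglike(x)) else x0

    def fit(self, n_iter: int = 10_000, seed=None, init=None,
            proposal_scales=None, adapt: bool = True,
            optimize_init: bool = True, burn_in_frac: float = 0.2
            ) -> "ExtrinsicResults":
        """Sample the posterior and return an :class:`ExtrinsicResults`.

        A random initialization (restarted until feasible) is refined by a
        deterministic Nelder-Mead climb before sampling, unless an explicit
        ``init`` is given or ``optimize_init=False``.
        """
        rng = np.random.default_rng(seed)
        if init is None:
            if optimize_init:
                best_x, best_ll = None, -np.inf
                for _ in range(5):  # multi-start against local optima
                    x = self._optimize_init(self._random_init(rng))
                    ll = self.loglike(x)
                    if ll > best_ll:
                        best_x, best_ll = x, ll
                x0 = best_x
            else:
                x0 = self._random_init(rng)
        else:
            x0 = np.asarray(init, dtype=float)
        if proposal_scales is None:
            proposal_scales = [0.5, 0.5, 0.5, 0.3][: len(self.param_names)]
        chain = metropolis_sample(self.loglike, x0, proposal_scales, n_iter,
                                  rng=rng, adapt=adapt,
                                  burn_in_frac=burn_in_frac,
                                  param_names=list(self.param_names))
        chain.seed = seed
        if self.prior.is_free:
            j = self.param_names.index("log_height_sd")
            samples = chain.samples.copy()
            samples[:, j] = np.exp(samples[:, j])
            names = list(self.param_names)
            names[j] = "height_sd_m"
            chain = ChainSummary(samples=samples, param_names=names,
                                 acceptance_rate=chain.acceptance_rate,
                                 seed=seed, n_iter=n_iter,
                                 n_burn=chain.n_burn)
        return ExtrinsicResults(chain, self)


class ExtrinsicResults:
    """Results of an object-height extrinsic fit.

    Exposes the posterior chain (``.chain``), posterior means (``.params``),
    standard deviations (``.bse``) and a ``summary()`` table.  ``.pose``
    returns a :class:`CameraPose` built from the posterior means (heading and
    x/y position zero, as they are not identified by this fit).
    """

    def __init__(self, chain: ChainSummary, model: ObjectHeightModel):
        self.chain = chain
        self.model = model

    @property
    def param_names(self):
        return self.chain.param_names

    @property
    def params(self) -> dict:
        return dict(zip(self.chain.param_names, self.chain.mean))

    @property
    def bse(self) -> dict:
        return dict(zip(self.chain.param_names, self.chain.sd))

    @property
    def pose(self) -> CameraPose:
        p = self.params
        return CameraPose(elevation_m=p["elevation_m"], tilt_deg=p["tilt_deg"],
                          roll_deg=p["roll_deg"])

    @property
    def camera(self) -> Camera:
        return Camera(self.model.intrinsics, self.pose)

    def summary(self) -> str:
        n = self.model.clicks.n_objects
        hz = (0 if self.model.clicks.horizon is None
              else len(self.model.clicks.horizon))
        head = ("Extrinsic camera fit from object heights\n"
                f"objects: {n}   horizon clicks: {hz}   "
                f"height prior: N({self.model.prior.mean_m}, "
                f"{self.model.prior.sd_m})\n\n")
        return head + self.chain.summary()

    def plot_posteriors(self, axes=None):
        return self.chain.plot_posteriors(axes=axes)


# ------------------------------------------------------- functional wrappers

def object_height_loglik(params, clicks: ClickSet, prior: HeightPrior,
                         intrinsics: CameraIntrinsics,
                         horizon_model: HorizonModel | None = None) -> float:
    """Log likelihood of (elevation, tilt, roll[, log sd]) given clicks.

    Horizon clicks present in ``clicks`` are included in the score; see
    :class:`ObjectHeightModel` for the measurement model.
    """
    model = ObjectHeightModel(clicks, intrinsics, prior, horizon_model)
    return model.loglike(params)


def horizon_loglik(params, horizon_clicks, intrinsics: CameraIntrinsics,
                   horizon_model: HorizonModel | None = None,
                   click_noise_px: float = 1.0) -> float:
    """Gaussian log likelihood of horizon clicks alone under a pose.

    ``params`` is (elevation, tilt, roll).  The penalty is on the
    perpendicular pixel distance of each click to the projected horizon
    trace, with the click-noise scale as standard deviation.  A pose whose
    horizon cannot be projected at all receives a large finite penalty.
    """
    horizon_clicks = np.atleast_2d(np.asarray(horizon_clicks, dtype=float))
    if len(horizon_clicks) < 2:
        raise ValueError("at least two horizon points are required for slope "
                         "information")
    elevation, tilt, roll = (float(v) for v in np.asarray(params, dtype=float)[:3])
    pose = CameraPose(elevation_m=elevation, tilt_deg=tilt, roll_deg=roll)
    cam = Camera(intrinsics, pose)
    trace = horizon_trace(cam, horizon_model or HorizonModel(),
                          n_dense=41, widen=1.2)
    if len(trace) < 2:
        return _SOFT_PENALTY
    d = point_to_polyline_distance(horizon_clicks, trace)
    return float(-0.5 * np.sum((d / click_noise_px) ** 2)
                 - d.size * (math.log(click_noise_px) + 0.5 * _LOG_2PI))


def fit_extrinsics(clicks: ClickSet, prior: HeightPrior,
                   intrinsics: CameraIntrinsics, **options) -> ExtrinsicResults:
    """Fit elevation, tilt and roll from foot/head (and horizon) clicks.

    Thin wrapper around ``ObjectHeightModel(...).fit(**options)``.
    """
    horizon_model = options.pop("horizon_model", None)
    bounds = options.pop("bounds", None)
    model = ObjectHeightModel(clicks, intrinsics, prior,
                              horizon_model=horizon_model, bounds=bounds)
    return model.fit(**options)
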