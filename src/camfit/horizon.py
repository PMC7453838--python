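"""Spherical-earth horizon: dip angle and the horizon trace in the image.

For a camera at height ``h`` above a sphere of radius ``R``, sight lines
tangent to the sphere are dipped below the horizontal by

    delta = arccos(R / (R + h)),

which for small ``h`` approaches ``sqrt(2 h / R)``.  The horizon is therefore
the cone of directions with inclination ``-delta``; its image trace is
computed by projecting direction vectors sampled over azimuth.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .camera import Camera, Projection

__all__ = ["HorizonModel", "horizon_in_image", "horizon_trace",
           "point_to_polyline_distance"]


@dataclasses.dataclass(frozen=True)
class HorizonModel:
    """Perfectly spherical earth of radius ``earth_radius_m`` (no refraction)."""

    earth_radius_m: float = 6_371_000.0

    def __post_init__(self):
        if not self.earth_radius_m > 0:
            raise ValueError("earth_radius_m must be positive")

    def dip_angle(self, elevation_m: float) -> float:
        """Dip of the horizon below the horizontal, in radians."""
        if elevation_m < 0:
            raise ValueError("elevation must be non-negative")
        r = self.earth_radius_m
        return float(np.arccos(r / (r + elevation_m)))


def _horizon_directions(dip: float, azimuths_rad: np.ndarray) -> np.ndarray:
    cd = np.cos(dip)
    return np.stack([np.sin(azimuths_rad) * cd,
                     np.cos(azimuths_rad) * cd,
                     -np.sin(dip) * np.ones_like(azimuths_rad)], axis=1)


def _azimuth_span(camera: Camera, widen: float) -> tuple[float, float]:
    """Azimuth window (radians, about the heading) covering the image width."""
    intr = camera.intrinsics
    half_w = intr.image_width_px / 2.0 / intr.f_pix
    if intr.projection is Projection.RECTILINEAR:
        half = np.arctan(half_w)
    else:
        half = min(half_w, np.pi * 0.999)
    half = min(half * widen, np.pi * 0.999)
    heading = np.radians(camera.pose.heading_deg)
    return heading - half, heading + half


def horizon_trace(camera: Camera, horizon_model: HorizonModel | None = None,
                  n_dense: int = 65, widen: float = 1.3) -> np.ndarray:
    """Dense pixel trace of the horizon across (and slightly beyond) the frame.

    The trace is *not* clipped to the image rectangle; rows where the horizon
    direction cannot be projected are dropped.  Returns an ``(m, 2)`` array,
    possibly empty.
    """
    hm = horizon_model or HorizonModel()
    dip = hm.dip_angle(camera.pose.elevation_m)
    lo, hi = _azimuth_span(camera, widen)
    az = np.linspace(lo, hi, n_dense)
    uv, ok = camera.project_directions(_horizon_directions(dip, az))
    return uv[ok & np.isfinite(uv).all(axis=1)]


def horizon_in_image(intrinsics, pose, horizon_model: HorizonModel | None = None,
                     n_points: int = 3) -> np.ndarray:
    """Sample ``n_points`` along the visible image trace of the horizon.

    Returns an ``(n_points, 2)`` array of pixel coordinates, or an empty
    ``(0, 2)`` array when the horizon lies entirely outside the frame.
    """
    if pose.elevation_m <= 0:
        raise ValueError("horizon requires a positive camera elevation")
    cam = Camera(intrinsics, pose)
    trace = horizon_trace(cam, horizon_model, n_dense=1025, widen=1.0)
    if trace.size == 0:
        return np.empty((0, 2))
    w, h = intrinsics.image_width_px, intrinsics.image_height_px
    inside = ((trace[:, 0] >= 0) & (trace[:, 0] <= w)
              & (trace[:, 1] >= 0) & (trace[:, 1] <= h))
    if not np.any(inside):
        return np.empty((0, 2))
    idx = np.flatnonzero(inside)
    pick = np.unique(np.linspace(idx[0], idx[-1], n_points).round().astype(int))
    pts = trace[pick]
    if len(pts) < n_points:  # duplicate indices on a very short visible arc
        pts = np.repeat(pts, int(np.ceil(n_points / len(pts))), axis=0)[:n_points]
    return pts


def point_to_polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance from each point to a polyline (in pixels)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    line = np.asarray(polyline, dtype=float)
    if len(line) == 0:
        return np.full(len(pts), np.inf)
    if len(line) == 1:
        return np.linalg.norm(pts - line[0], axis=1)
    a = line[:-1]                      # (s, 2) segment starts
    ab = line[1:] - a                  # (s, 2) segment vectors
    ab2 = np.maximum(np.sum(ab * ab, axis=1), 1e-300)
    ap = pts[:, None, :] - a[None, :, :]          # (p, s, 2)
    t = np.clip(np.einsum("psd,sd->ps", ap, ab) / ab2, 0.0, 1.0)
    closest = a[None] + t[..., None] * ab[None]
    d = np.linalg.norm(pts[:, None, :] - closest, axis=2)
    return d.min(axis=1)
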