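"""Radial lens distortion in normalized image coordinates.

The model is the classic three-coefficient radial polynomial about the
principal point,

    r' = r * (1 + k1*r**2 + k2*r**4 + k3*r**6),

applied to coordinates that have already been divided by the effective focal
length (so ``r`` is of order 1 at the image border for typical lenses).  The
forward map is closed form; the inverse is computed by a damped Newton
iteration on the radius.
"""

from __future__ import annotations

import numpy as np

__all__ = ["apply_distortion", "invert_distortion", "DistortionInversionError"]


class DistortionInversionError(RuntimeError):
    """Raised when the radial distortion polynomial cannot be inverted.

    This happens for extreme coefficients that make the radius mapping
    non-monotonic inside the requested domain.
    """


def apply_distortion(xy: np.ndarray, k) -> np.ndarray:
    """Apply radial distortion to normalized points.

    Parameters
    ----------
    xy : array_like, shape (..., 2)
        Undistorted normalized coordinates (origin at the principal point).
    k : sequence of 3 floats
        Radial coefficients ``(k1, k2, k3)``.

    Returns
    -------
    ndarray, shape (..., 2)
        Distorted normalized coordinates.  ``k = (0, 0, 0)`` is the identity
        and the origin is a fixed point for any ``k``.
    """
    xy = np.asarray(xy, dtype=float)
    k1, k2, k3 = (float(v) for v in k)
    if k1 == 0.0 and k2 == 0.0 and k3 == 0.0:
        return xy.copy()
    r2 = np.sum(xy * xy, axis=-1, keepdims=True)
    factor = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
    return xy * factor


def invert_distortion(xy: np.ndarray, k, tol: float = 1e-10,
                      max_iter: int = 100) -> np.ndarray:
    """Invert :func:`apply_distortion` numerically.

    Solves ``r * (1 + k1 r^2 + k2 r^4 + k3 r^6) = r_d`` for each input radius
    with a damped Newton iteration started at ``r = r_d``.

    Raises
    ------
    DistortionInversionError
        If the iteration has not reached ``tol`` (in normalized units) after
        ``max_iter`` steps, which indicates coefficients outside the
        invertible regime.
    """
    xy = np.asarray(xy, dtype=float)
    k1, k2, k3 = (float(v) for v in k)
    if k1 == 0.0 and k2 == 0.0 and k3 == 0.0:
        return xy.copy()

    rd = np.sqrt(np.sum(xy * xy, axis=-1))
    r = rd.copy()
    converged = np.zeros(r.shape, dtype=bool)
    for _ in range(max_iter):
        r2 = r * r
        f = r * (1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))) - rd
        converged = np.abs(f) < tol
        if np.all(converged):
            break
        fp = 1.0 + r2 * (3.0 * k1 + r2 * (5.0 * k2 + r2 * 7.0 * k3))
        # Damp where the derivative is small or negative (non-monotonic zone)
        fp = np.where(np.abs(fp) < 1e-6, np.sign(fp) * 1e-6 + (fp == 0) * 1e-6, fp)
        step = f / fp
        # limit steps to half the current radius to avoid overshooting to r<0
        max_step = 0.5 * np.maximum(r, 1e-3)
        step = np.clip(step, -max_step, max_step)
        r = r - step
        r = np.maximum(r, 0.0)
    if not np.all(converged):
        raise DistortionInversionError(
            "radial distortion inversion did not converge; coefficients "
            f"k={(k1, k2, k3)} are outside the invertible range for the "
            "requested radii")
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(rd > 0, r / np.where(rd > 0, rd, 1.0), 1.0)
    return xy * scale[..., None]
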