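"""Top-view ("bird's-eye") projection of an oblique image onto the ground plane.

The warp is an inverse mapping: every cell of a metric ground grid is
projected through the calibrated camera and samples the source image
bilinearly at the resulting pixel.  Cells whose projection falls outside the
frame, behind the camera or above the horizon are transparent (alpha = 0).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .camera import Camera

__all__ = ["topview_map", "read_raster", "write_raster"]


def topview_map(image: np.ndarray, camera: Camera, extent_m,
                resolution_m_per_px: float) -> np.ndarray:
    """Warp an oblique image to a metric ground-plane grid.

    Parameters
    ----------
    image : ndarray
        Source raster, gray ``(H, W)``, RGB ``(H, W, 3)`` or RGBA.
    camera : Camera
        Calibrated camera that took the image.
    extent_m : (x_min, x_max, y_min, y_max)
        Ground rectangle to cover, in world meters.
    resolution_m_per_px : float
        Ground sampling distance of the output.

    Returns
    -------
    ndarray, shape (rows, cols, 4), uint8
        RGBA top view; the first row is the northern (largest y) edge, so the
        array displays with north up.  No-data cells have alpha 0.
    """
    if resolution_m_per_px <= 0:
        raise ValueError("resolution must be strictly positive")
    img = np.asarray(image)
    if img.dtype != np.uint8:
        arr = np.asarray(img, dtype=float)
        if arr.max() <= 1.0:
            arr = arr * 255.0
        img = np.clip(arr, 0, 255).astype(np.uint8)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    alpha_src = img[..., 3] if img.shape[-1] == 4 else None
    rgb = img[..., :3]

    x_min, x_max, y_min, y_max = (float(v) for v in extent_m)
    if not (x_max > x_min and y_max > y_min):
        raise ValueError("extent must be ordered (x_min < x_max, y_min < y_max)")
    res = float(resolution_m_per_px)
    xs = np.arange(x_min + res / 2.0, x_max, res)
    ys = np.arange(y_max - res / 2.0, y_min, -res)   # north up
    gx, gy = np.meshgrid(xs, ys)
    ground = np.stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)], axis=1)
    uv, visible = camera.project(ground)

    out = np.zeros((len(ys), len(xs), 4), dtype=np.uint8)
    vis = visible.reshape(len(ys), len(xs))
    # map_coordinates indexes (row, col) = (v, u); pixel centers at +0.5
    coords = np.stack([uv[:, 1] - 0.5, uv[:, 0] - 0.5])
    coords = np.nan_to_num(coords, nan=-10.0)
    for c in range(3):
        sampled = ndimage.map_coordinates(rgb[..., c].astype(float), coords,
                                          order=1, mode="constant", cval=0.0)
        out[..., c] = np.clip(sampled.reshape(len(ys), len(xs)), 0, 255)
    alpha = np.where(vis, 255, 0).astype(np.uint8)
    if alpha_src is not None:
        a = ndimage.map_coordinates(alpha_src.astype(float), coords, order=1,
                                    mode="constant", cval=0.0)
        alpha = np.minimum(alpha, a.reshape(len(ys), len(xs)).astype(np.uint8))
    out[..., 3] = alpha
    return out


def read_raster(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF raster as a numpy array."""
    import imageio.v3 as iio

    return iio.imread(path)


def write_raster(path, array: np.ndarray) -> None:
    """Write a raster (alpha channel preserved for PNG/TIFF)."""
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(array))
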