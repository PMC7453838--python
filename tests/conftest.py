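import numpy as np
import pytest

from camfit import (Camera, CameraPose, SceneSpec, default_intrinsics,
                    default_pose)


@pytest.fixture(scope="session")
def intrinsics():
    """Benchmark 14 mm camera (17.3 x 9.7 mm sensor, 4608 x 2592 px)."""
    return default_intrinsics()


@pytest.fixture(scope="session")
def pose():
    """Benchmark pose: 16.1 m elevation, 85.3 deg tilt, 0.3 deg roll."""
    return default_pose()


@pytest.fixture(scope="session")
def camera(intrinsics, pose):
    return Camera(intrinsics, pose)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def visible_ground_pixels(camera, rng, n):
    """Pixels uniform in the frame whose rays hit the ground, n of them."""
    intr = camera.intrinsics
    w, h = intr.image_width_px, intr.image_height_px
    out = []
    while len(out) < n:
        uv = np.stack([rng.uniform(0, w, 4 * n), rng.uniform(0, h, 4 * n)],
                      axis=1)
        ground = camera.backproject_to_plane(uv, strict=False)
        ok = np.isfinite(ground[:, 0])
        out.extend(uv[ok][: n - len(out)])
    return np.array(out)
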