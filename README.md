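# camfit

Extrinsic camera calibration and metric ground-plane mapping for wildlife
monitoring imagery — with full posterior uncertainty from Metropolis
Monte-Carlo sampling.

## The problem

Fixed cameras, time-lapse rigs and aerial photographs are standard tools for
observing animals (penguin colonies are the motivating case), but turning an
oblique photograph into counts, positions, sizes or areas requires knowing
where the camera was and how it was oriented.  The *intrinsic* parameters
(focal length `f`, sensor size, image size, lens distortion) are usually
known from the hardware; the *extrinsic* parameters — elevation `h` above
the ground plane, tilt `α_tilt` (0 = straight down, 90° = horizontal), roll
`α_roll`, heading `α_heading` and x/y position — often are not measurable in
the field.

`camfit` estimates the extrinsic parameters from evidence *inside* the
image:

* **Known object heights** — paired foot/head clicks on objects of known
  height distribution (e.g. standing penguins, 0.75 m).  Each candidate pose
  implies a height per object: the foot pixel is backprojected onto the
  ground plane `z = 0`, the head pixel ray is intersected with the vertical
  axis through that foot point, and the resulting heights are scored under
  the height distribution.
* **A visible horizon** — the astronomical horizon of a spherical earth,
  dipped `arccos(R/(R+h))` below horizontal, is projected into the image and
  clicked horizon points are scored by their pixel distance to it.  This
  sharply constrains tilt and roll.
* **Geo-referenced landmarks** — image/map point correspondences; the camera
  position, heading, elevation and tilt minimize ground-plane distances
  between backprojected clicks and map targets (for near-nadir aerial
  images, where the height method fails).
* **A second view** — relative orientation of two cameras from corresponding
  clicks, by minimizing symmetric point-to-epipolar-line pixel distances,
  with scale restored from a known baseline or one known object size.

All fits share one engine: random-walk Metropolis sampling of the posterior
(proposals accepted with probability `min(1, p1/p0)`), so every estimate
comes with standard deviations and credible intervals rather than a point
value.  The forward model is a pinhole camera
(`u = f_pix·x_c/z_c + w/2`, `f_pix = f·w_image/w_sensor`) with optional
cylindrical/equirectangular projections and 3-coefficient radial distortion;
the calibrated camera then maps pixels ↔ metric ground coordinates and warps
images to "bird's-eye" top views.

## Worked example

Simulate the standard benchmark scene — fifty 0.75 m objects at 50–150 m,
camera at 16.1 m elevation, 85.3° tilt, 0.3° roll, 1 px click noise, three
horizon clicks — and fit elevation/tilt/roll with the height spread left
free:

```python
import numpy as np
import camfit as cf

spec = cf.SceneSpec(seed=1)                      # benchmark defaults
rng = np.random.default_rng(1)
clicks, truth = cf.generate_object_scene(spec, rng=rng)
clicks.horizon = cf.generate_horizon_clicks(spec, n_points=3, rng=rng)

prior = cf.HeightPrior(mean_m=0.75, sd_m="free")
res = cf.ObjectHeightModel(clicks, spec.intrinsics, prior).fit(
    n_iter=10_000, seed=1)
print(res.summary())
```

```
Extrinsic camera fit from object heights
objects: 50   horizon clicks: 3   height prior: N(0.75, free)

parameter               mean          sd         16%         84%        2.5%       97.5%
----------------------------------------------------------------------------------------
elevation_m          16.0081      0.1211     15.8895     16.1314     15.7653     16.2387
tilt_deg             85.2954      0.0087     85.2865     85.3040     85.2787     85.3121
roll_deg              0.2895      0.0180      0.2711      0.3075      0.2555      0.3253
height_sd_m           0.0388      0.0039      0.0350      0.0428      0.0322      0.0474

acceptance rate: 0.328   samples: 8000   seed: 1
```

The posterior means recover the generating values (16.1 m, 85.3°, 0.3°)
well within one posterior standard deviation for tilt/roll and within 0.6 %
for elevation; `height_sd_m` is the fitted spread of the implied object
heights, here driven purely by the 1 px click noise.  The calibrated camera
(`res.camera`) then maps clicks to ground coordinates
(`.backproject_to_plane`) or produces a top view (`cf.topview_map`).

The same workflow is available from the shell:

```
camfit simulate objects --out scene --seed 1
camfit fit --camera scene/camera.yaml --clicks scene/clicks.csv \
           --height-mean 0.75 --height-sd free --iters 10000 --seed 1 --out fit
camfit georef --camera cam.yaml --landmarks lm.csv --iters 10000 --seed 1 --out geo
camfit stereo --camera-a a.yaml --camera-b b.yaml --corr corr.csv \
              --baseline 5.0 --iters 10000 --seed 1 --out rig
```

Every output directory contains a `manifest.json` (command, input hashes,
seed, version) sufficient for exact replay.

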