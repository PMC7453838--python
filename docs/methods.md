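# Methods

## Camera model

World coordinates are metric with z up; `z = 0` is the reference ground
plane and the camera center sits at `(pos_x, pos_y, elevation)`.  The camera
frame is x right, y down, z forward.  A world point is mapped into the
camera frame by `p_c = R (p_w − C)` with `R = R_roll · R_tilt · R_heading`:

* `R_heading` rotates about the world z axis; heading is measured clockwise
  from world +y, so the viewing azimuth maps onto +y,
* `R_tilt` rotates about the camera x axis with tilt = 0 meaning nadir
  (looking straight down, image "up" towards world +y) and tilt = 90°
  meaning a horizontal optical axis,
* `R_roll` rotates about the optical axis (0 = lower sensor edge
  horizontal).

Pixel coordinates are continuous with the origin at the top-left corner of
the top-left pixel, u rightward, v downward; sub-pixel values are
meaningful.  The projection uses the effective focal length
`f_pix = f · w_image / w_sensor` and the principal point at the image
center; square pixels are assumed, and a sensor/image aspect mismatch
beyond 1 % triggers a warning.  Three projection models are supported:

* rectilinear (pinhole): `u = f_pix·x_c/z_c + w/2`, `v = f_pix·y_c/z_c + h/2`;
* cylindrical: `u = f_pix·atan2(x_c, z_c) + w/2`,
  `v = f_pix·y_c/hypot(x_c, z_c) + h/2`;
* equirectangular: as cylindrical but `v` uses `atan2(y_c, hypot(x_c, z_c))`.

Radial distortion `r' = r(1 + k1 r² + k2 r⁴ + k3 r⁶)` acts in normalized
image coordinates (pixel offsets divided by `f_pix`) before the pixel
offset; the inverse is a damped Newton iteration on the radius with
tolerance 1e−10 in normalized units, raising an explicit error outside the
invertible regime.  Rectilinear points at or behind the image plane receive
a NaN pixel sentinel plus an `invisible` flag rather than an exception, so
batch projection of mixed point sets is total.

Backprojection is under-determined by one degree of freedom and is resolved
by a constraint: intersection with a horizontal plane `z = z_plane` (rays
parallel to or pointing away from the plane raise a "no ground
intersection" error), or, for head clicks, the point on the pixel ray
closest to the vertical axis through the already-backprojected foot point.
The round trip project∘backproject is exact to better than 1e−6 px for all
three projections, with and without distortion.

The horizon of a spherical earth (radius fixed at 6 371 000 m) is the cone
of directions dipped `δ = arccos(R/(R+h))` below horizontal, which for
small h equals `√(2h/R)` to within 1 % up to h ≈ 1000 m.  Its image trace
is computed by projecting direction vectors over azimuth; the trace is a
conic in the rectilinear image but is handled as a dense polyline (41–1025
samples depending on use), whose chord error (~1e−3 px across a 63° field
of view) is far below any click noise.  Atmospheric refraction is ignored.

## Height-based extrinsic fit

Inputs: n paired foot/head clicks, optionally m ≥ 2 horizon clicks, the
intrinsics, and a height distribution (normal with mean and either fixed or
free sd; any custom log-density can be supplied).  For a candidate
(elevation, tilt, roll) the implied height of each object is computed as
described above and scored under the height distribution; horizon clicks
add a Gaussian penalty on the perpendicular pixel distance to the projected
horizon with the click-noise scale (default 1 px) as standard deviation.
The two log-likelihood terms are summed without extra weights — the click
noise scale is the only weighting knob.  Poses that put a foot click at or
above the local horizon are infeasible (−∞); a pose whose horizon cannot be
projected at all while horizon clicks exist receives a large finite penalty
(−1e8) so the sampler remains total.  Heading and x/y position are not
identifiable from heights or the horizon and are fixed at zero.

Priors on the pose are flat on elevation 1–100 m, tilt 30–120°, roll ±10°;
the height distribution is the only informative term.  When the height sd
is free it is sampled in log space (support 1e−3–0.5 m) to enforce
positivity, and results report the transformed `height_sd_m` chain.

## Metropolis sampler

A plain random-walk Metropolis chain with symmetric Gaussian proposals:
default initial scales (0.5 m, 0.5°, 0.5°, 0.3 log-units) for (elevation,
tilt, roll, log sd).  The chain runs `n_iter` iterations (default 10 000);
the first 20 % are discarded as burn-in.  During burn-in only, the proposal
is adapted: a global scale factor targets a 20–40 % acceptance rate, and
halfway through burn-in the proposal covariance is replaced by the scaled
empirical covariance of the chain so far (`2.38²/d · Σ̂`, Haario-style) —
necessary because the elevation/tilt posterior is a narrow correlated ridge
when no horizon is available.  The kernel is frozen after burn-in, so the
retained samples come from a fixed, valid Metropolis kernel.  Chains are
bit-reproducible given a seed; a chain that accepts nothing raises a
diagnostic error suggesting smaller proposal scales.

Initialization draws from broad uniform ranges (elevation 1–100 m, tilt
30–120°, roll ±10°), redrawing up to 10 times if the start is infeasible.
Because a 10 000-step random walk started tens of degrees from a
horizon-sharpened mode does not reliably converge, the default adds a
deterministic refinement of the random start before sampling: five
multi-started Nelder-Mead climbs, keeping the best.  With a free height sd
the pose is climbed first at a fixed moderate sd, the sd is then set from
the residual height scatter, and a joint polish follows — otherwise the
optimizer can inflate the sd to absorb a wrong elevation.  Pure
random-start sampling remains available (`optimize_init=False`).

Summaries report posterior mean, sd, and central 68 %/95 % quantile
intervals per parameter plus the acceptance rate.

## Geo-registration fit

For near-nadir imagery the fitted parameters are (elevation, tilt, pos_x,
pos_y, heading); roll is fixed at 0 by default because roll and heading are
partially degenerate near nadir (a flag unlocks it).  Map targets given as
latitude/longitude are converted to a local tangent plane by the
equirectangular approximation about a reference point (round-trip exact to
1e−9°, adequate below ~10 km scenes).  The measurement model is isotropic
Gaussian noise (default σ = 1 m) on the ground-plane position of each
backprojected landmark; rays that miss the ground under a candidate pose
are charged a large finite distance (1e6 m) so the cost stays total.  At
least three non-collinear landmark pairs are required (collinearity is
detected and warned).  The fit runs Levenberg–Marquardt least squares from
up to 15 heuristic random starts to locate the basin, samples the posterior
by Metropolis, and reports a deterministic least-squares refinement of the
posterior mean alongside the chain; with ≥ 4 non-collinear noiseless
landmarks the refined estimate is exact to numerical tolerance.

## Stereo relative orientation

The identifiable relative pose of two cameras has five degrees of freedom:
the unit translation direction (azimuth clockwise from +y, inclination
above horizontal) and tilt/roll/heading offsets added to camera A's angles
— the same angle vocabulary as the rest of the package, rather than
quaternions.  The cost is the symmetric mean of point-to-epipolar-line
distances in pixels (epipolar lines built geometrically by projecting two
points of A's pixel ray into B), converted to a Gaussian log-likelihood
with pixel scale σ = 1 px by default.  Pixel-space distances are preferred
over world-space ray distances, whose scale varies with depth.  The
epipolar cost is blind to the overall scale and to reversing the baseline;
the reversal ("twisted pair") is resolved by cheirality — a pose must
triangulate at least half of the correspondences in front of both cameras
— and the scale is restored afterwards from the constraint: either the
known baseline length, or one known object size whose two endpoint
correspondences are triangulated at unit scale.  Initialization is
multi-start Levenberg–Marquardt on the signed epipolar residuals, followed
by Metropolis sampling.  Triangulation returns the midpoint of the common
perpendicular of the two pixel rays, with the ray gap reported as a quality
measure; near-parallel rays are flagged.  The eight-point/fundamental-
matrix construction exists only as an independent oracle in the test suite,
never as the estimation path.

## Synthetic scenes

The generators define the study conditions and provide ground truth for
every fit.  The object scene places axis-aligned rectangles of height
0.75 m (width 0.30 m) uniformly in azimuth across the camera's field of
view and uniformly in ground distance over 50–150 m — "randomly placed" is
interpreted as uniform over the visible wedge intersected with the distance
annulus — projects foot and head, and adds isotropic Gaussian click noise
(default σ = 1 px, redrawn for the rare click that would leave the frame).
The default camera is the benchmark configuration: f = 14 mm, sensor
17.3 × 9.7 mm, 4608 × 2592 px, elevation 16.1 m, tilt 85.3°, roll 0.3°.
Horizon clicks (default 3, the minimum practical input) are sampled on the
model horizon trace.  The landmark scene uses the same intrinsics from
300 m elevation at 15° tilt with 8 landmarks and 0.5 px click noise; the
stereo scene uses a 5 m baseline, 20 shared points at 15–60 m, 0.5 px
noise, with points 0/1 spanning one 0.75 m object for the known-size
constraint.  All generators are bit-reproducible under a fixed seed.

What the generators do *not* emulate: manual-clicking biases (real clicks
are not zero-mean isotropic Gaussian), terrain relief (the ground is
exactly flat), occlusion, object lean, height variation beyond the stated
distribution, refraction, and rolling shutter.  Passing tests therefore
demonstrate correctness of the geometry and inference under the stated
noise model, not robustness to violations of it.

## Numerical choices and problem sizes

* Distortion inversion: damped Newton, tolerance 1e−10, max 100 iterations.
* Horizon trace: 41-point polyline inside likelihoods (chord error ≪ click
  noise), 1025 points when sampling clicks.
* Degenerate-geometry penalties are large and finite (−1e8 log-lik, 1e6 m,
  1e4 px) rather than −∞ wherever optimizers and samplers must remain
  total.
* The test suite and the acceptance script use 6 000-iteration chains for
  the replicate sweeps (uncertainty-scaling and horizon-benefit studies;
  40 and 20 fits respectively) and the full 10 000 iterations for single
  benchmark fits; posterior sds are stable at these lengths.  The
  acceptance script's replicate study uses 20 seeds.

## Known limitations

* Flat-ground assumption everywhere; no DEM/terrain support.
* The tangent-plane approximation distorts beyond ~10 km.
* Heading is reported on the real line by the samplers (no circular
  statistics); posteriors spanning the 0/360° wrap would summarize poorly,
  though concentrated posteriors — the practical case — are unaffected.
* Single-chain inference: convergence is monitored only through acceptance
  rates and the multi-start initialization, not R-hat across chains.
* The known-size stereo scale constraint inherits the full click noise of
  one small object; expect a few percent of scale uncertainty per ~100 px
  object.
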