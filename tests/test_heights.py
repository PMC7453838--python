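"""Object-height likelihood and the Metropolis extrinsic fit."""

import math

import numpy as np
import pytest

from camfit import (ClickSet, HeightPrior, HorizonModel, ObjectHeightModel,
                    SceneSpec, fit_extrinsics, generate_horizon_clicks,
                    generate_object_scene, horizon_loglik,
                    object_height_loglik)

TRUTH = np.array([16.1, 85.3, 0.3])


@pytest.fixture(scope="module")
def noiseless_scene():
    spec = SceneSpec(seed=21, click_noise_px=0.0)
    clicks, truth = generate_object_scene(spec)
    return spec, clicks, truth


@pytest.fixture(scope="module")
def noisy_scene():
    spec = SceneSpec(seed=22)
    rng = np.random.default_rng(22)
    clicks, truth = generate_object_scene(spec, rng=rng)
    clicks.horizon = generate_horizon_clicks(spec, n_points=3, rng=rng)
    return spec, clicks, truth


class TestObjectHeightLoglik:
    def test_maximized_at_generating_pose(self, noiseless_scene):
        # brute-force grid over tilt: the likelihood peaks at the truth
        spec, clicks, _ = noiseless_scene
        prior = HeightPrior(mean_m=0.75, sd_m=0.05)
        tilts = np.arange(83.3, 87.3 + 1e-9, 0.25)
        lls = [object_height_loglik([16.1, t, 0.3], clicks, prior,
                                    spec.intrinsics) for t in tilts]
        assert tilts[int(np.argmax(lls))] == pytest.approx(85.3)

    def test_single_pair_head_equals_foot(self, intrinsics):
        clicks = ClickSet(foot=[[2304.0, 2000.0]], head=[[2304.0, 2000.0]])
        prior = HeightPrior(mean_m=0.75, sd_m=0.05)
        ll = object_height_loglik(TRUTH, clicks, prior, intrinsics)
        expected = (-0.5 * (0.75 / 0.05) ** 2 - math.log(0.05)
                    - 0.5 * math.log(2 * math.pi))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_additivity_under_duplication(self, noiseless_scene, intrinsics):
        spec, clicks, _ = noiseless_scene
        prior = HeightPrior(mean_m=0.75, sd_m=0.05)
        doubled = ClickSet(foot=np.vstack([clicks.foot, clicks.foot]),
                           head=np.vstack([clicks.head, clicks.head]))
        single = object_height_loglik(TRUTH, clicks, prior, intrinsics)
        assert object_height_loglik(TRUTH, doubled, prior,
                                    intrinsics) == pytest.approx(2 * single)

    def test_invariant_under_pair_shuffling(self, noisy_scene, rng):
        spec, clicks, _ = noisy_scene
        prior = HeightPrior(mean_m=0.75, sd_m=0.05)
        perm = rng.permutation(clicks.n_objects)
        shuffled = ClickSet(foot=clicks.foot[perm], head=clicks.head[perm],
                            horizon=clicks.horizon)
        a = object_height_loglik(TRUTH, clicks, prior, spec.intrinsics)
        b = object_height_loglik(TRUTH, shuffled, prior, spec.intrinsics)
        assert a == pytest.approx(b, rel=1e-12)

    def test_foot_above_horizon_is_rejected(self, intrinsics):
        clicks = ClickSet(foot=[[2304.0, 100.0]], head=[[2304.0, 90.0]])
        prior = HeightPrior(mean_m=0.75, sd_m=0.05)
        assert object_height_loglik(TRUTH, clicks, prior,
                                    intrinsics) == -np.inf


class TestHorizonLoglik:
    def test_clicks_on_model_horizon_maximize(self, noisy_scene):
        spec, _, _ = noisy_scene
        spec0 = SceneSpec(seed=5, click_noise_px=0.0)
        pts = generate_horizon_clicks(spec0, n_points=3)
        ll_truth = horizon_loglik(TRUTH, pts, spec0.intrinsics)
        # near-zero distance: log-lik at the Gaussian mode (3 points, sigma=1)
        mode = 3 * (-0.5 * math.log(2 * math.pi))
        assert ll_truth == pytest.approx(mode, abs=1e-3)
        for delta in ([0.0, 0.2, 0.0], [0.5, 0.0, 0.0], [0.0, 0.0, 0.5]):
            assert horizon_loglik(TRUTH + delta, pts, spec0.intrinsics) < ll_truth

    def test_one_degree_tilt_moves_horizon_by_f_tan(self, intrinsics):
        spec0 = SceneSpec(seed=5, click_noise_px=0.0)
        pts = generate_horizon_clicks(spec0, n_points=3)
        shift = intrinsics.f_pix * math.tan(math.radians(1.0))
        ll = horizon_loglik(TRUTH + [0.0, 1.0, 0.0], pts, intrinsics)
        # Gaussian penalty with sigma = 1 px for 3 points displaced by ~shift
        # first-order displacement; the exact trace moves slightly more
        # because the horizon sits a few degrees off the optical axis
        expected = (-0.5 * 3 * shift ** 2) + 3 * (-0.5 * math.log(2 * math.pi))
        assert ll == pytest.approx(expected, rel=0.05)

    def test_three_points_accepted_as_minimum_input(self, intrinsics):
        spec0 = SceneSpec(seed=6, click_noise_px=0.0)
        pts = generate_horizon_clicks(spec0, n_points=3)
        assert len(pts) == 3
        assert np.isfinite(horizon_loglik(TRUTH, pts, intrinsics))

    def test_fewer_than_two_points_rejected(self, intrinsics):
        with pytest.raises(ValueError, match="two horizon points"):
            horizon_loglik(TRUTH, [[100.0, 900.0]], intrinsics)

    def test_unprojectable_horizon_penalized_finitely(self, intrinsics):
        spec0 = SceneSpec(seed=6, click_noise_px=0.0)
        pts = generate_horizon_clicks(spec0, n_points=3)
        ll = horizon_loglik([16.1, 45.0, 0.0], pts, intrinsics)
        assert np.isfinite(ll) and ll < -1e6


class TestFitExtrinsics:
    def test_recovers_truth_within_posterior_sd(self, noisy_scene):
        spec, clicks, truth = noisy_scene
        prior = HeightPrior(mean_m=0.75, sd_m="free")
        res = fit_extrinsics(clicks, prior, spec.intrinsics, n_iter=6000,
                             seed=101)
        for name, value in zip(["elevation_m", "tilt_deg", "roll_deg"], TRUTH):
            err = abs(res.params[name] - value)
            assert err < 4 * res.bse[name] + 1e-3, name

    def test_seed_reproducibility(self, noisy_scene):
        spec, clicks, _ = noisy_scene
        prior = HeightPrior(mean_m=0.75, sd_m=0.05)
        model = ObjectHeightModel(clicks, spec.intrinsics, prior)
        a = model.fit(n_iter=1500, seed=55)
        b = model.fit(n_iter=1500, seed=55)
        np.testing.assert_array_equal(a.chain.samples, b.chain.samples)

    def test_free_sd_reported_on_natural_scale(self, noisy_scene):
        spec, clicks, _ = noisy_scene
        prior = HeightPrior(mean_m=0.75, sd_m="free")
        model = ObjectHeightModel(clicks, spec.intrinsics, prior)
        res = model.fit(n_iter=3000, seed=77)
        assert "height_sd_m" in res.params
        assert 0.0 < res.params["height_sd_m"] < 0.2

    def test_single_object_no_horizon_flags_wide_posterior(self, intrinsics):
        spec = SceneSpec(seed=30, n_objects=2)
        clicks, _ = generate_object_scene(spec)
        prior = HeightPrior(mean_m=0.75, sd_m=0.05)
        res = fit_extrinsics(clicks, prior, intrinsics, n_iter=3000, seed=3)
        # under-constrained: completes, but the elevation posterior is wide
        assert res.bse["elevation_m"] > 0.5

    def test_summary_mentions_inputs(self, noisy_scene):
        spec, clicks, _ = noisy_scene
        prior = HeightPrior(mean_m=0.75, sd_m=0.05)
        res = ObjectHeightModel(clicks, spec.intrinsics, prior).fit(
            n_iter=1200, seed=9)
        text = res.summary()
        assert "objects: 50" in text and "elevation_m" in text
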