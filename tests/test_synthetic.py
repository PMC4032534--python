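"""Synthetic growth curves, collision observations and ridge points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colirange.params import CollisionGeometry
from colirange.synthetic import (
    CollisionObservation,
    GrowthCurve,
    gen_collision_observation,
    gen_growth_curve,
    gen_ridge_points,
    growth_curves_from_csv,
    growth_curves_to_csv,
)


class TestGrowthCurve:
    def test_zero_velocity_curve_is_flat(self):
        c = gen_growth_curve(0.0, lag_mean=5.0, times=[0, 5, 10, 20], r0=300.0)
        assert np.allclose(c.radii, 300.0)

    def test_piecewise_linear_closed_form(self):
        c = gen_growth_curve(50.0, lag_mean=8.0, accel_span=0.0, noise_sd=0.0,
                             times=[0, 10, 20], r0=500.0)
        assert np.allclose(c.radii, [500.0, 600.0, 1100.0])

    def test_quadratic_ramp_is_c1_and_reaches_velocity(self):
        t = np.linspace(0, 40, 401)
        c = gen_growth_curve(50.0, lag_mean=8.0, accel_span=6.0, times=t, r0=0.0)
        slopes = np.diff(c.radii) / np.diff(t)
        # slope ramps from 0 to the velocity and stays there
        assert slopes.max() <= 50.0 + 1e-6
        assert np.allclose(slopes[t[1:] > 15.0], 50.0)
        assert np.allclose(c.radii[t <= 8.0], 0.0)

    def test_tail_slope_recovers_velocity_under_noise(self):
        # oracle: ordinary least squares on the final linear third
        t = np.arange(0.0, 60.0, 2.0)
        c = gen_growth_curve(50.0, lag_mean=8.0, noise_sd=5.0, times=t, seed=42)
        n = len(t) // 3
        slope = np.polyfit(t[-n:], c.radii[-n:], 1)[0]
        assert slope == pytest.approx(50.0, abs=3.0)

    def test_seed_determinism(self):
        a = gen_growth_curve(30.0, 6.0, lag_sd=2.0, noise_sd=4.0, seed=7)
        b = gen_growth_curve(30.0, 6.0, lag_sd=2.0, noise_sd=4.0, seed=7)
        assert np.array_equal(a.radii, b.radii)
        c = gen_growth_curve(30.0, 6.0, lag_sd=2.0, noise_sd=4.0, seed=8)
        assert not np.array_equal(a.radii, c.radii)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(v=st.floats(0, 100), lag=st.floats(0, 20), span=st.floats(0, 10))
    def test_noiseless_curves_are_monotone(self, v, lag, span):
        c = gen_growth_curve(v, lag, accel_span=span, times=np.linspace(0, 48, 25))
        assert np.all(np.diff(c.radii) >= -1e-9)

    @pytest.mark.parametrize("bad", [dict(velocity=-1.0), dict(times=[0, 0, 1]),
                                     dict(times=[3, 2, 1]), dict(noise_sd=-1.0)])
    def test_input_errors(self, bad):
        kw = dict(velocity=10.0, lag_mean=5.0, times=[0, 1, 2])
        kw.update(bad)
        with pytest.raises(ValueError):
            gen_growth_curve(**kw)

    def test_csv_round_trip(self, tmp_path):
        curves = [gen_growth_curve(30.0, 5.0, noise_sd=2.0, seed=s, strain_id=sid,
                                   marker=m)
                  for s, (sid, m) in enumerate([("S", "GFP"), ("C", "nfp")])]
        path = tmp_path / "curves.csv"
        growth_curves_to_csv(curves, path)
        back = growth_curves_from_csv(path)
        assert len(back) == 2
        assert {(c.strain_id, c.marker) for c in back} == {("S", "GFP"), ("C", "nfp")}
        assert np.allclose(back[0].radii, curves[0].radii)


class TestCollision:
    def test_no_toxin_fronts_meet(self):
        obs = gen_collision_observation(0.0, 125.0, seed=0)
        assert obs.final_gap == 0.0

    def test_gap_same_order_as_decay_length(self):
        # strong producer: gap positive and of order lambda = 125 µm
        obs = gen_collision_observation(7.389, 125.0, seed=1)
        assert 30.0 < obs.final_gap < 800.0

    def test_replicate_means_agree(self):
        # replicate-spread oracle: two independent 10-replicate means differ
        # by less than 3 patch widths (75 µm)
        geom = CollisionGeometry(observation_time=30.0)
        g1 = np.mean([gen_collision_observation(7.389, 125.0, geom, seed=s).final_gap
                      for s in range(10)])
        g2 = np.mean([gen_collision_observation(7.389, 125.0, geom, seed=s).final_gap
                      for s in range(100, 110)])
        assert abs(g1 - g2) < 75.0

    def test_gap_grows_with_lambda(self):
        geom = CollisionGeometry(observation_time=30.0)
        short = np.mean([gen_collision_observation(7.389, 60.0, geom, seed=s).final_gap
                         for s in range(5)])
        long = np.mean([gen_collision_observation(7.389, 150.0, geom, seed=s).final_gap
                        for s in range(5)])
        assert long > short

    def test_overlapping_droplets_rejected(self):
        with pytest.raises(ValueError):
            CollisionGeometry(center_separation=300.0, droplet_radius=200.0)

    def test_invariants(self):
        with pytest.raises(ValueError):
            CollisionObservation(initial_center_separation=0.0, final_gap=1.0,
                                 observation_time=1.0)
        with pytest.raises(ValueError):
            CollisionObservation(initial_center_separation=100.0, final_gap=-1.0,
                                 observation_time=1.0)


class TestRidgePoints:
    def test_linear_value(self):
        pts = gen_ridge_points("linear", (0.17, 0.49), [1.0])
        assert pts[0, 1] == pytest.approx(0.66)

    def test_power_loglog_slope_exact(self):
        pts = gen_ridge_points("power", (2.0, 2.46), np.geomspace(0.5, 5, 12))
        slope = np.polyfit(np.log(pts[:, 0]), np.log(pts[:, 1]), 1)[0]
        assert slope == pytest.approx(-2.46, abs=1e-12)

    def test_saturation_limit(self):
        pts = gen_ridge_points("saturation", (0.01, 0.14, 0.24), [1e7])
        assert pts[0, 1] == pytest.approx(0.14, rel=1e-5)

    def test_unknown_form_and_arity(self):
        with pytest.raises(ValueError):
            gen_ridge_points("exponential", (1.0, 2.0), [1.0])
        with pytest.raises(ValueError):
            gen_ridge_points("linear", (1.0, 2.0, 3.0), [1.0])

    def test_seeded_noise_is_deterministic(self):
        a = gen_ridge_points("linear", (0.0, 1.0), [1, 2, 3], noise_sd=0.1, seed=4)
        b = gen_ridge_points("linear", (0.0, 1.0), [1, 2, 3], noise_sd=0.1, seed=4)
        assert np.array_equal(a, b)
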