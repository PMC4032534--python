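"""Lattice engine: seeding, exact Gillespie semantics, whole-run behaviour."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from colirange.params import (
    C,
    FREE,
    LYSED,
    R,
    S,
    InoculumSpec,
    LagDistribution,
    LatticeConfig,
    ToxinParams,
    make_scenario,
)
from colirange.simulator import (
    assign_toxic,
    run_expansion,
    seed_inoculum,
    step,
)


class TestSeeding:
    cfg = LatticeConfig(patch_size=25.0, inoculum_radius=500.0, stop_radius=1200.0)

    def test_pure_inoculum(self):
        lat = seed_inoculum(InoculumSpec((1.0, 0.0, 0.0)), self.cfg, {"S": 1.0}, 0)
        colonized = lat.state[lat.state != FREE]
        assert len(colonized) > 0 and np.all(colonized == S)

    def test_equal_ratios_multinomial(self):
        cfg = LatticeConfig(patch_size=25.0, inoculum_radius=1000.0, stop_radius=2100.0)
        lat = seed_inoculum(InoculumSpec((1.0, 1.0, 1.0)), cfg,
                            {"S": 1.0, "R": 1.0, "C": 1.0}, 3)
        n = int((lat.state != FREE).sum())
        assert n > 1000
        sd = math.sqrt(n * (1 / 3) * (2 / 3))
        for code in (S, R, C):
            assert abs(int((lat.state == code).sum()) - n / 3) < 3 * sd

    def test_one_tenth_c_fraction(self):
        cfg = LatticeConfig(patch_size=25.0, inoculum_radius=1000.0, stop_radius=2100.0)
        lat = seed_inoculum(InoculumSpec((1.0, 1.0, 0.1)), cfg,
                            {"S": 1.0, "R": 1.0, "C": 1.0}, 5)
        n = int((lat.state != FREE).sum())
        frac = 0.1 / 2.1
        sd = math.sqrt(n * frac * (1 - frac))
        assert abs(int((lat.state == C).sum()) - n * frac) < 3 * sd

    def test_lags_drawn_nonnegative(self):
        lat = seed_inoculum(InoculumSpec((1.0, 1.0, 1.0)), self.cfg,
                            {"S": 1.0, "R": 1.0, "C": 1.0}, 1,
                            lag=LagDistribution(2.0, 5.0))
        lags = lat.act_time[lat.state != FREE]
        assert np.all(lags >= 0)

    def test_grid_must_hold_stop_radius(self):
        with pytest.raises(ValueError):
            LatticeConfig(patch_size=25.0, inoculum_radius=2000.0,
                          stop_radius=2100.0, grid_extent=160)

    def test_droplet_must_fit_on_grid(self):
        from colirange.params import LagDistribution
        from colirange.simulator import _empty_lattice, _seed_droplet

        lat = _empty_lattice(21, 25.0)
        with pytest.raises(ValueError):
            _seed_droplet(lat, (10, 10), 11 * 25.0, (1.0, 0.0, 0.0),
                          LagDistribution(0.0, 0.0), None,
                          np.random.default_rng(0))


class TestAssignToxic:
    def test_non_producers_never_toxic(self):
        rng = np.random.default_rng(0)
        p = ToxinParams(toxic_fraction=1.0)
        assert not any(assign_toxic(S, p, rng) for _ in range(100))
        assert not any(assign_toxic(R, p, rng) for _ in range(100))

    def test_three_percent_rule(self):
        rng = np.random.default_rng(1)
        p = ToxinParams(toxic_fraction=0.03)
        n = sum(assign_toxic(C, p, rng) for _ in range(10_000))
        assert abs(n - 300) < 3 * math.sqrt(10_000 * 0.03 * 0.97)

    def test_zero_fraction(self):
        rng = np.random.default_rng(2)
        p = ToxinParams(toxic_fraction=0.0)
        assert not any(assign_toxic(C, p, rng) for _ in range(100))


class TestStepSemantics:
    """Exact single-event checks on micro-instances (reference driver)."""

    def test_uniform_neighbour_choice(self, micro_lattice):
        counts = np.zeros(9)
        for trial in range(4000):
            lat = micro_lattice(mu_s=1.0)
            lat.state[1, 1] = S
            lat.act_time[1, 1] = 0.0
            rng = np.random.default_rng(trial)
            rec = step(lat, rng)
            assert rec["type"] == "colonize"
            ti, tj = rec["target"]
            counts[ti * 3 + tj] += 1
        counts = np.delete(counts, 4)  # centre cannot be a target
        chi2 = ((counts - 500.0) ** 2 / 500.0).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=7)

    def test_lag_gates_first_event(self, micro_lattice):
        lat = micro_lattice()
        lat.state[1, 1] = S
        lat.act_time[1, 1] = 5.0
        rec = step(lat, np.random.default_rng(0))
        assert rec["type"] == "activation"
        assert rec["time"] == 5.0
        rec2 = step(lat, np.random.default_rng(0))
        assert rec2["type"] == "colonize" and rec2["time"] > 5.0

    def test_first_event_type_matches_propensity_ratio(self, micro_lattice):
        # two competing colonizers with rates 1 and 2, 5 open neighbours each:
        # P(B first) = 2/3 exactly
        wins_b = 0
        n = 4000
        for trial in range(n):
            lat = micro_lattice(mu_s=1.0, mu_r=2.0)
            lat.state[1, 0] = S
            lat.state[1, 2] = R
            lat.act_time[1, 0] = lat.act_time[1, 2] = 0.0
            rec = step(lat, np.random.default_rng(trial))
            assert rec["type"] == "colonize"
            wins_b += rec["strain"] == "R"
        p = 2.0 / 3.0
        assert abs(wins_b - n * p) < 3 * math.sqrt(n * p * (1 - p))

    def test_lysis_vs_rejected_colonization_exact_odds(self, micro_lattice):
        # inhibited S source: colonization attempts are all rejected (thinned)
        # and compete with lysis; P(lysis) = L / (L + mu)
        L, mu = 3.0, 1.0
        lys = 0
        n = 2000
        for trial in range(n):
            lat = micro_lattice(mu_s=mu, toxin=ToxinParams(kappa=5.0), lysis_rate=L)
            lat.state[1, 1] = S
            lat.act_time[1, 1] = 0.0
            lat.conc[:] = 2.0
            rec = step(lat, np.random.default_rng(trial))
            assert rec["type"] in ("lysis", "rejected")
            lys += rec["type"] == "lysis"
        p = L / (L + mu)
        assert abs(lys - n * p) < 3 * math.sqrt(n * p * (1 - p))

    def test_stall_without_events(self, micro_lattice):
        lat = micro_lattice()
        rec = step(lat, np.random.default_rng(0))
        assert rec["type"] == "stall"


class TestRunExpansion:
    def test_single_strain_run(self, tiny_scenario):
        cfg = replace(tiny_scenario,
                      inoculum=InoculumSpec((1.0, 0.0, 0.0), "null_model"))
        res = run_expansion(cfg, 1)
        assert res.stop_reason == "radius_reached"
        assert res.max_radius_um() >= cfg.lattice.stop_radius
        fr = res.strain_fractions()
        assert fr["S"] == 1.0 and fr["R"] == 0.0 and fr["C"] == 0.0

    def test_deterministic_replay(self, tiny_scenario):
        a = run_expansion(tiny_scenario, 9)
        b = run_expansion(tiny_scenario, 9)
        assert np.array_equal(a.state, b.state)
        assert a.time == b.time
        c = run_expansion(tiny_scenario, 10)
        assert not np.array_equal(a.state, c.state)

    def test_state_legality_and_toxic_flags(self, small_scenario_I):
        res = run_expansion(small_scenario_I, 4)
        assert set(np.unique(res.state)) <= {FREE, S, R, C, LYSED}
        # toxic flags only ever on C-colonized ground (C patches persist)
        assert np.all(res.state[res.lattice.toxic == 1] == C)

    def test_no_lysis_without_toxin(self, tiny_scenario):
        res = run_expansion(tiny_scenario, 2)
        assert int((res.state == LYSED).sum()) == 0

    def test_colony_growth_is_monotone(self, tiny_scenario):
        times = np.linspace(0.0, 40.0, 15)
        res = run_expansion(tiny_scenario, 3, record_times=times)
        assert np.all(np.diff(res.record_radii) >= 0)

    def test_neutral_two_strain_symmetry(self, tiny_scenario):
        cfg = replace(tiny_scenario,
                      inoculum=InoculumSpec((1.0, 1.0, 0.0), "null_model"))
        fracs = [run_expansion(cfg, sd).strain_fractions()["S"] for sd in range(40)]
        m = float(np.mean(fracs))
        se = float(np.std(fracs, ddof=1) / math.sqrt(len(fracs)))
        assert abs(m - 0.5) < 3.5 * se + 0.01

    def test_fully_inhibited_sensitive_colony_stalls(self):
        from colirange.simulator import run_lattice, seed_inoculum

        cfg = LatticeConfig(patch_size=25.0, inoculum_radius=200.0, stop_radius=600.0)
        lat = seed_inoculum(InoculumSpec((1.0, 0.0, 0.0)), cfg, {"S": 1.0}, 0,
                            toxin=ToxinParams(kappa=5.0),
                            lag=LagDistribution(1.0, 0.5))
        lat.conc[:] = 2.0  # blanket inhibition: S cannot colonize and lyses
        info, _ = run_lattice(lat, cfg.stop_radius, math.inf, 1)
        assert info["stop_reason"] == "stalled"
        assert np.all(lat.state[lat.state != FREE] == LYSED)


def test_scenario_presets_velocity_hierarchies():
    from colirange.params import scenario_velocities

    v1 = scenario_velocities("I")
    assert v1["S"] > v1["R"] > v1["C"]
    v2 = scenario_velocities("II")
    assert v2["R"] > v2["S"] >= v2["C"]
    v3 = scenario_velocities("III")
    assert abs(v3["S"] - v3["R"]) / v3["S"] < 0.06 and v3["C"] < 0.8 * v3["R"]
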