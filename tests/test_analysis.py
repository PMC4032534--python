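"""Survivor classification, coexistence aggregation, ridges and law fits."""

import numpy as np
import pytest

from colirange.analysis import (
    CoexistenceMatrix,
    SectorConfig,
    classify_survivors,
    coexistence_level,
    extract_ridge,
    fit_law,
    replicate_seed,
    sweep_diagram,
)
from colirange.simulator import run_expansion

from conftest import paint_disc_result


def three_wedges(r, theta):
    return "S" if theta < 120 else ("R" if theta < 240 else "C")


class TestClassifySurvivors:
    def test_single_strain_colony(self):
        res = paint_disc_result(lambda r, a: "S")
        assert classify_survivors(res) == {"S"}

    def test_three_wedges_all_survive(self):
        res = paint_disc_result(three_wedges)
        assert classify_survivors(res) == {"S", "R", "C"}

    def test_interior_strain_is_not_a_survivor(self):
        def painter(r, theta):
            if r <= 20:
                return "S"
            return "R" if theta < 180 else "C"

        res = paint_disc_result(painter)
        assert classify_survivors(res) == {"R", "C"}

    def test_sliver_below_min_angle_dies(self):
        def painter(r, theta):
            return "C" if theta < 2.0 else "R"

        res = paint_disc_result(painter)
        assert classify_survivors(res, SectorConfig(min_angle=5.0)) == {"R"}

    def test_shallow_sector_fails_depth_criterion(self):
        # a C pocket reaching only ~40% of the expansion distance, exposed to
        # the outside through a notch, is not a stable front sector
        def painter(r, theta):
            if 350.0 <= theta or theta < 10.0:
                return "C" if r <= 24 else None
            return "R"

        res = paint_disc_result(painter)
        assert classify_survivors(res) == {"R"}

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_rotation_invariance(self, k):
        res = paint_disc_result(three_wedges)
        rotated = paint_disc_result(three_wedges)
        rotated.lattice.state = np.rot90(res.lattice.state, k).copy()
        assert classify_survivors(rotated) == classify_survivors(res)

    def test_empty_colony(self):
        res = paint_disc_result(lambda r, a: None)
        assert classify_survivors(res) == set()


class TestCoexistenceLevel:
    def test_all_three_strain(self):
        mean, sem, frac3 = coexistence_level([{"S", "R", "C"}] * 5)
        assert (mean, sem, frac3) == (3.0, 0.0, 1.0)

    def test_alternating_sets(self):
        sets = [{"R"}, {"R", "C"}] * 10
        mean, sem, frac3 = coexistence_level(sets)
        assert mean == pytest.approx(1.5)
        assert frac3 == 0.0
        assert sem == pytest.approx(np.std([1, 2] * 10, ddof=1) / np.sqrt(20))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            coexistence_level([])


class TestSweep:
    def test_single_cell_matches_direct_runs(self, tiny_scenario):
        m = sweep_diagram("r_C", "r_R", [1.0], [1.0], tiny_scenario,
                          n_reps=5, seed=3)
        direct = [classify_survivors(run_expansion(tiny_scenario, replicate_seed(3, 0, 0, r)))
                  for r in range(5)]
        mean, sem, frac3 = coexistence_level(direct)
        assert m.mean_level[0, 0] == pytest.approx(mean)
        assert m.frac3[0, 0] == pytest.approx(frac3)

    def test_replicate_seeds_are_order_free_and_distinct(self):
        s = {replicate_seed(1, i, j, r) for i in range(3) for j in range(3) for r in range(3)}
        assert len(s) == 27
        assert replicate_seed(1, 2, 1, 0) == replicate_seed(1, 2, 1, 0)

    def test_invalid_param_name(self, tiny_scenario):
        with pytest.raises(ValueError):
            sweep_diagram("r_X", "r_R", [1.0], [1.0], tiny_scenario, 1, 0)

    def test_long_format_frame(self, tiny_scenario):
        m = sweep_diagram("r_C", "r_R", [0.5, 1.0], [1.0], tiny_scenario,
                          n_reps=2, seed=0)
        df = m.to_frame()
        assert list(df.columns) == ["r_C", "r_R", "mean_level", "sem", "frac3", "n"]
        assert len(df) == 2


def make_matrix(frac3):
    frac3 = np.asarray(frac3, dtype=float)
    ny, nx = frac3.shape
    return CoexistenceMatrix("x", np.arange(nx, dtype=float),
                             "y", np.arange(ny, dtype=float),
                             mean_level=frac3 * 3.0, sem=np.zeros_like(frac3),
                             frac3=frac3, n=1)


class TestRidge:
    def test_single_peak_argmax(self):
        m = make_matrix([[0.1, 0.0], [0.9, 0.2], [0.3, 0.8], [0.0, 0.1]])
        ridge = extract_ridge(m, axis="x")
        assert ridge.tolist() == [[0.0, 1.0], [1.0, 2.0]]

    def test_plateau_resolves_to_middle(self):
        m = make_matrix([[0.0], [0.7], [0.7], [0.7], [0.1]])
        ridge = extract_ridge(m, axis="x")
        assert ridge.tolist() == [[0.0, 2.0]]

    def test_flat_column_skipped_with_warning(self):
        m = make_matrix([[0.5, 0.1], [0.5, 0.9]])
        with pytest.warns(UserWarning):
            ridge = extract_ridge(m, axis="x")
        assert ridge.tolist() == [[1.0, 1.0]]

    def test_ridge_recovers_generating_curve(self):
        # construction oracle: unimodal kernel centred on a known line
        xs = np.linspace(1.0, 4.0, 7)
        ys = np.linspace(0.0, 4.0, 21)
        centre = 0.5 + 0.6 * xs
        frac3 = np.exp(-((ys[:, None] - centre[None, :]) / 0.8) ** 2)
        m = CoexistenceMatrix("x", xs, "y", ys, frac3 * 3, np.zeros_like(frac3), frac3, 1)
        ridge = extract_ridge(m, axis="x")
        assert np.all(np.abs(ridge[:, 1] - centre) <= (ys[1] - ys[0]) + 1e-9)


class TestFitLaw:
    def test_saturation_exact_recovery(self):
        from colirange.synthetic import gen_ridge_points

        pts = gen_ridge_points("saturation", (0.01, 0.14, 0.24), np.linspace(0.2, 4, 12))
        fit = fit_law(pts, "saturation")
        assert np.allclose(fit.coefficients, (0.01, 0.14, 0.24), rtol=1e-6)
        assert fit.rss < 1e-12

    def test_linear_exact_recovery(self):
        from colirange.synthetic import gen_ridge_points

        pts = gen_ridge_points("linear", (0.17, 0.49), np.linspace(0, 1.2, 8))
        fit = fit_law(pts, "linear")
        assert fit.coefficients == pytest.approx((0.17, 0.49), abs=1e-12)

    def test_power_exact_recovery(self):
        from colirange.synthetic import gen_ridge_points

        pts = gen_ridge_points("power", (3.0, 2.46), np.geomspace(0.3, 3, 9))
        fit = fit_law(pts, "power")
        assert fit.coefficients == pytest.approx((3.0, 2.46), rel=1e-10)

    def test_noisy_power_exponent_within_quarter(self):
        # Monte-Carlo recovery oracle over independently seeded noisy ridges
        from colirange.synthetic import gen_ridge_points

        errs = []
        for s in range(20):
            pts = gen_ridge_points("power", (1.0, 2.46), np.geomspace(0.5, 2, 10),
                                   noise_sd=0.02, seed=s)
            errs.append(fit_law(pts, "power").coefficients[1] - 2.46)
        assert max(abs(e) for e in errs) < 0.25

    def test_predict_and_summary(self):
        fit = fit_law(np.array([[0.0, 0.17], [1.0, 0.66]]), "linear")
        assert fit.predict([2.0])[0] == pytest.approx(1.15)
        assert "slope" in fit.summary()

    @pytest.mark.parametrize("form,pts", [
        ("linear", [[1.0, 2.0]]),
        ("saturation", [[1.0, 2.0], [2.0, 3.0]]),
        ("circle", [[1.0, 2.0], [2.0, 3.0]]),
        ("linear", [[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]]),
        ("power", [[-1.0, 2.0], [2.0, 3.0]]),
    ])
    def test_degenerate_inputs_rejected(self, form, pts):
        with pytest.raises(ValueError):
            fit_law(np.array(pts, dtype=float), form)
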