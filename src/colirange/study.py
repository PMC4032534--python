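"""Predefined study designs: the rescue window, the three coexistence
diagrams behind the biodiversity laws, and their 1-D profiles.

These bundle the package's headline computations with fixed grids so that
replicate counts and seeds are the only knobs: the fraction of replicates
with full three-strain coexistence at the rescue inoculum S:R:C = 1:1:0.1,
the inoculum-ratio diagram (saturation law), the relative-growth-rate
diagram (linear law) and the toxin-range diagram (power law).
"""

from __future__ import annotations

import warnings

import numpy as np

from .analysis import (
    CoexistenceMatrix,
    LawFit,
    classify_survivors,
    coexistence_level,
    extract_ridge,
    fit_law,
    replicate_seed,
    sweep_diagram,
)
from .params import ScenarioConfig, make_scenario
from .simulator import run_expansion

__all__ = [
    "rescue_window_fraction",
    "ratio_profile",
    "lambda_profile",
    "saturation_sweep",
    "linear_sweep",
    "power_sweep",
    "survivor_tally",
    "RC_PROFILE_GRID",
    "LAMBDA_PROFILE_GRID",
]

RC_PROFILE_GRID = (0.03, 0.05, 0.07, 0.1, 0.15, 0.2, 0.3, 0.5, 1.0)
LAMBDA_PROFILE_GRID = (25.0, 50.0, 75.0, 100.0, 125.0, 150.0)

SATURATION_GRID = (np.geomspace(0.25, 4.0, 8), np.geomspace(0.03, 0.8, 9))  # r_R, r_C
LINEAR_GRID = (np.linspace(0.25, 1.05, 7), np.linspace(0.25, 1.25, 9))  # g_C, g_R
POWER_GRID = (np.geomspace(60.0, 240.0, 7), np.geomspace(0.03, 1.0, 9))  # lambda, r_C


def _replicate_sets(cfg: ScenarioConfig, n_reps: int, seed: int) -> list[set]:
    return [classify_survivors(run_expansion(cfg, replicate_seed(seed, 0, 0, r)))
            for r in range(n_reps)]


def rescue_window_fraction(n_reps: int = 250, seed: int = 0,
                           ratios=(1.0, 1.0, 0.1)) -> tuple[float, float]:
    """Three-strain coexistence fraction at the rescue inoculum (scenario I).

    Returns (fraction, s.e.m. of the fraction).
    """
    sets = _replicate_sets(make_scenario("I", ratios), n_reps, seed)
    hits = np.array([len(s) == 3 for s in sets], dtype=float)
    return float(hits.mean()), float(hits.std(ddof=1) / np.sqrt(n_reps))


def survivor_tally(scenario: str, ratios, n_reps: int = 50, seed: int = 0) -> dict[str, int]:
    """Survivor-set counts over replicates for a scenario preset."""
    tally: dict[str, int] = {}
    for s in _replicate_sets(make_scenario(scenario, ratios), n_reps, seed):
        key = "".join(sorted(s)) or "none"
        tally[key] = tally.get(key, 0) + 1
    return tally


def _profile(param: str, values, base: ScenarioConfig, n_reps: int, seed: int):
    m = sweep_diagram(param, "r_S", values, [1.0], base, n_reps=n_reps, seed=seed)
    return np.asarray(values, float), m.frac3[0, :], m.mean_level[0, :]


def ratio_profile(n_reps: int = 40, seed: int = 0, values=RC_PROFILE_GRID):
    """frac3 vs r_C at r_R = r_S = 1 (scenario I); returns (r_C, frac3, mean)."""
    return _profile("r_C", values, make_scenario("I", (1.0, 1.0, 1.0)), n_reps, seed)


def lambda_profile(n_reps: int = 40, seed: int = 0, values=LAMBDA_PROFILE_GRID):
    """frac3 vs colicin range at equal ratios 1:1:1 (scenario I)."""
    return _profile("lambda_", values, make_scenario("I", (1.0, 1.0, 1.0)), n_reps, seed)


def _ridge_and_fit(matrix: CoexistenceMatrix, form: str) -> tuple[np.ndarray, LawFit]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ridge = extract_ridge(matrix, axis="x", metric="frac3")
    return ridge, fit_law(ridge, form)


def saturation_sweep(n_reps: int = 30, seed: int = 0,
                     grids=SATURATION_GRID) -> tuple[CoexistenceMatrix, np.ndarray, LawFit]:
    """Inoculum-ratio diagram r_R x r_C; ridge fitted by the saturation law."""
    base = make_scenario("I", (1.0, 1.0, 0.1))
    m = sweep_diagram("r_R", "r_C", grids[0], grids[1], base, n_reps=n_reps, seed=seed)
    ridge, fit = _ridge_and_fit(m, "saturation")
    return m, ridge, fit


def linear_sweep(n_reps: int = 30, seed: int = 0,
                 grids=LINEAR_GRID) -> tuple[CoexistenceMatrix, np.ndarray, LawFit]:
    """Relative-growth-rate diagram g_C x g_R at 1:1:0.1; linear-law ridge."""
    base = make_scenario("I", (1.0, 1.0, 0.1))
    m = sweep_diagram("g_C", "g_R", grids[0], grids[1], base, n_reps=n_reps, seed=seed)
    ridge, fit = _ridge_and_fit(m, "linear")
    return m, ridge, fit


def power_sweep(n_reps: int = 30, seed: int = 0,
                grids=POWER_GRID) -> tuple[CoexistenceMatrix, np.ndarray, LawFit]:
    """Toxin-range diagram lambda x r_C (scenario I); power-law ridge."""
    base = make_scenario("I", (1.0, 1.0, 0.1))
    m = sweep_diagram("lambda_", "r_C", grids[0], grids[1], base, n_reps=n_reps, seed=seed)
    ridge, fit = _ridge_and_fit(m, "power")
    return m, ridge, fit
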