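"""Synthetic inputs for the calibration and law-fitting stages.

Real inputs to the pipeline are (a) single-strain radial growth curves
(colony radius vs time per strain/marker/condition), (b) colony-collision
observations (final gap between a colicin-producer front and a neighbouring
sensitive front), and (c) ridge points for biodiversity-law fitting.  This
module generates all three with the statistical structure the analysis
assumes, so the package builds, tests and demonstrates itself without any
external data.

Growth curves follow a lag / acceleration / linear-expansion shape:
``r(t) = r0`` until the lag, then a quadratic C1 ramp over ``accel_span``
reaching the asymptotic slope (the radial expansion velocity), with additive
i.i.d. Gaussian noise on the radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import CollisionGeometry

__all__ = [
    "GrowthCurve",
    "CollisionObservation",
    "gen_growth_curve",
    "gen_collision_observation",
    "gen_ridge_points",
    "growth_curves_to_csv",
    "growth_curves_from_csv",
    "collisions_to_csv",
]

_STRAINS = ("S", "R", "C")
_MARKERS = ("GFP", "mCh", "nfp")
_CONDITIONS = ("slow", "fast")


@dataclass(frozen=True)
class GrowthCurve:
    """Radius-vs-time record of a single-strain colony expansion."""

    times: np.ndarray  # h, strictly increasing
    radii: np.ndarray  # µm
    strain_id: str = "S"
    marker: str = "nfp"
    condition: str = "slow"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "radii", radii)
        if times.ndim != 1 or len(times) != len(radii):
            raise ValueError("times and radii must be 1-D and equally long")
        if len(times) and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if len(radii) and radii[0] < 0:
            raise ValueError("initial radius must be non-negative")
        if self.strain_id not in _STRAINS:
            raise ValueError(f"strain_id must be one of {_STRAINS}")
        if self.marker not in _MARKERS:
            raise ValueError(f"marker must be one of {_MARKERS}")
        if self.condition not in _CONDITIONS:
            raise ValueError(f"condition must be one of {_CONDITIONS}")


@dataclass(frozen=True)
class CollisionObservation:
    """Final front-to-front gap from a C-vs-S colony collision."""

    initial_center_separation: float  # µm
    final_gap: float  # µm
    observation_time: float  # h

    def __post_init__(self):
        if self.final_gap < 0:
            raise ValueError("final_gap must be non-negative")
        if self.initial_center_separation <= 0:
            raise ValueError("initial_center_separation must be positive")


def ramp_radius(times, r0: float, velocity: float, lag: float, accel_span: float) -> np.ndarray:
    """Noiseless lag / quadratic-ramp / linear growth-curve shape."""
    t = np.asarray(times, dtype=float)
    r = np.full_like(t, float(r0))
    if accel_span > 0:
        ramp = (t > lag) & (t < lag + accel_span)
        r[ramp] = r0 + velocity * (t[ramp] - lag) ** 2 / (2 * accel_span)
        lin = t >= lag + accel_span
        r[lin] = r0 + velocity * (t[lin] - lag - accel_span / 2)
    else:
        lin = t >= lag
        r[lin] = r0 + velocity * (t[lin] - lag)
    return r


def gen_growth_curve(velocity: float, lag_mean: float, lag_sd: float = 0.0,
                     accel_span: float = 0.0, noise_sd: float = 0.0,
                     times=None, seed: int = 0, r0: float = 500.0,
                     strain_id: str = "S", marker: str = "nfp",
                     condition: str = "slow") -> GrowthCurve:
    """Generate one synthetic radial growth curve.

    The per-curve lag is a single truncated-Gaussian draw (mean ``lag_mean``,
    sd ``lag_sd``), mirroring per-site lag sampling in the lattice model;
    measurement noise is additive i.i.d. Gaussian on the radius.  Identical
    arguments and seed give an identical curve.
    """
    if velocity < 0:
        raise ValueError("velocity must be non-negative")
    if lag_sd < 0 or accel_span < 0 or noise_sd < 0:
        raise ValueError("lag_sd, accel_span and noise_sd must be non-negative")
    if times is None:
        times = np.arange(0.0, 49.0, 2.0)
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 1 or not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    lag = float(lag_mean)
    if lag_sd > 0:
        lag = float(rng.normal(lag_mean, lag_sd))
        while lag < 0:
            lag = float(rng.normal(lag_mean, lag_sd))
    r = ramp_radius(t, r0, velocity, lag, accel_span)
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, len(t))
    return GrowthCurve(times=t, radii=r, strain_id=strain_id, marker=marker,
                       condition=condition)


def gen_collision_observation(kappa: float, lambda_: float,
                              geometry: CollisionGeometry | None = None,
                              seed: int = 0, patch_size: float = 25.0) -> CollisionObservation:
    """Forward-simulate a C-vs-S colony collision and report the final gap.

    Runs the two-droplet lattice expansion (one pure-C, one pure-S droplet)
    to the observation time; the reported gap is the smallest front-to-front
    distance.  At ``kappa = 0`` the fronts meet (gap 0); the gap grows with
    the colicin decay length.
    """
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    from .simulator import simulate_collision

    if geometry is None:
        geometry = CollisionGeometry(observation_time=30.0)
    gap, _ = simulate_collision(kappa, lambda_, geometry, seed=seed, patch_size=patch_size)
    return CollisionObservation(
        initial_center_separation=geometry.center_separation,
        final_gap=gap,
        observation_time=geometry.observation_time,
    )


_FORMS = {
    "saturation": (3, lambda x, c: (c[0] + c[1] * x) / (c[2] + x)),
    "linear": (2, lambda x, c: c[0] + c[1] * x),
    "power": (2, lambda x, c: c[0] * np.power(x, -c[1])),
}


def gen_ridge_points(form: str, coeffs, x_values, noise_sd: float = 0.0,
                     seed: int = 0) -> np.ndarray:
    """Noisy points on a biodiversity-law curve; (n, 2) array of (x, y)."""
    if form not in _FORMS:
        raise ValueError(f"unknown form {form!r}; choose from {sorted(_FORMS)}")
    arity, fn = _FORMS[form]
    coeffs = tuple(float(c) for c in coeffs)
    if len(coeffs) != arity:
        raise ValueError(f"{form} law takes {arity} coefficients, got {len(coeffs)}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    x = np.asarray(list(x_values), dtype=float)
    y = fn(x, coeffs)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, len(x))
    return np.column_stack([x, y])


def growth_curves_to_csv(curves: list[GrowthCurve], path) -> None:
    rows = []
    for c in curves:
        for t, r in zip(c.times, c.radii):
            rows.append({"strain": c.strain_id, "marker": c.marker,
                         "condition": c.condition, "time_h": t, "radius_um": r})
    pd.DataFrame(rows).to_csv(path, index=False)


def growth_curves_from_csv(path) -> list[GrowthCurve]:
    df = pd.read_csv(path)
    out = []
    for (s, m, c), grp in df.groupby(["strain", "marker", "condition"], sort=False):
        grp = grp.sort_values("time_h")
        out.append(GrowthCurve(times=grp["time_h"].to_numpy(),
                               radii=grp["radius_um"].to_numpy(),
                               strain_id=s, marker=m, condition=c))
    return out


def collisions_to_csv(observations: list[CollisionObservation], path,
                      seeds: list[int] | None = None) -> None:
    rows = [{"sep_um": o.initial_center_separation, "gap_um": o.final_gap,
             "time_h": o.observation_time,
             "seed": seeds[i] if seeds else i}
            for i, o in enumerate(observations)]
    pd.DataFrame(rows).to_csv(path, index=False)
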