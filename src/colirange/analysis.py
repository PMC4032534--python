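"""Survivor classification, coexistence levels, phase-diagram sweeps and
biodiversity-law fitting.

A strain *survives* a range expansion if it still holds at least one stable
sector touching the expanding front: operationally, a connected cluster of
front patches of sufficient angular extent whose tip has expanded at least a
set fraction of the leading strain's expansion distance out of the inoculum.
The *coexistence level* of a parameter point is the mean number of surviving
strains over replicate simulations.  Sweeping two parameters yields a
coexistence diagram whose ridge of maximal three-strain coexistence is
summarized by fitted phenomenological laws (saturation, linear, power).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .params import C, R, S, STRAIN_CODES, ScenarioConfig, apply_sweep_param
from .simulator import SimResult, run_expansion

__all__ = [
    "SectorConfig",
    "CoexistenceMatrix",
    "LawFit",
    "classify_survivors",
    "coexistence_level",
    "sweep_diagram",
    "extract_ridge",
    "fit_law",
    "replicate_seed",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SectorConfig:
    """Operational definition of a stable front sector."""

    front_band: int = 2  # patches: front depth behind the outer boundary
    min_angle: float = 5.0  # degrees of angular extent
    min_depth_fraction: float = 0.5  # of the leading strain's expansion distance

    def __post_init__(self):
        if self.front_band <= 0 or self.min_angle <= 0 or self.min_depth_fraction <= 0:
            raise ValueError("all sector-criterion parameters must be positive")


def _front_mask(state: np.ndarray, band: int) -> np.ndarray:
    """Colonized patches within ``band`` patches of the outer colony boundary.

    The outside region is the free space connected to the grid border, so
    interior enclaves (e.g. lysis holes) do not count as front.
    """
    free = state == 0
    lab, n = ndimage.label(free, structure=_EIGHT)
    border_labels = np.unique(np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]))
    border_labels = border_labels[border_labels > 0]
    outside = np.isin(lab, border_labels)
    near = outside.copy()
    for _ in range(band):
        near = ndimage.binary_dilation(near, structure=_EIGHT)
    return near & (state >= S) & (state <= C)


def classify_survivors(result: SimResult, cfg: SectorConfig | None = None) -> set[str]:
    """Strains holding at least one stable sector on the expanding front."""
    if cfg is None:
        cfg = SectorConfig()
    state = result.state
    if not ((state >= S) & (state <= C)).any():
        return set()
    G = state.shape[0]
    cy = cx = G // 2
    ii, jj = np.nonzero((state >= S) & (state <= 4))
    r_all = np.sqrt((ii - cy) ** 2.0 + (jj - cx) ** 2.0)
    r_final = float(r_all.max())
    r_inoc = result.inoculum_radius / result.lattice.patch_size
    min_tip = r_inoc + cfg.min_depth_fraction * max(0.0, r_final - r_inoc)

    front = _front_mask(state, cfg.front_band)
    survivors: set[str] = set()
    yy, xx = np.mgrid[0:G, 0:G]
    theta = np.degrees(np.arctan2(yy - cy, xx - cx))
    rr = np.sqrt((yy - cy) ** 2.0 + (xx - cx) ** 2.0)
    for name, code in STRAIN_CODES.items():
        mask = front & (state == code)
        if not mask.any():
            continue
        lab, n = ndimage.label(mask, structure=_EIGHT)
        for k in range(1, n + 1):
            cluster = lab == k
            if float(rr[cluster].max()) < min_tip:
                continue
            if _angular_extent(theta[cluster]) >= cfg.min_angle:
                survivors.add(name)
                break
    return survivors


def _angular_extent(angles_deg: np.ndarray) -> float:
    """Circular span of a set of angles: 360 minus the largest angular gap."""
    a = np.sort(np.asarray(angles_deg, dtype=float))
    if len(a) == 1:
        return 0.0
    gaps = np.diff(a)
    wrap = 360.0 - (a[-1] - a[0])
    return 360.0 - max(float(gaps.max()), wrap)


def coexistence_level(survivor_sets: list[set[str]]) -> tuple[float, float, float]:
    """Mean survivor count, its s.e.m., and the three-strain fraction."""
    if not survivor_sets:
        raise ValueError("need at least one replicate")
    sizes = np.array([len(s) for s in survivor_sets], dtype=float)
    n = len(sizes)
    sem = float(sizes.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return float(sizes.mean()), sem, float((sizes == 3).mean())


def replicate_seed(base_seed: int, i: int, j: int, rep: int) -> int:
    """Deterministic per-cell, per-replicate seed (order-independent)."""
    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, i, j, rep])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class CoexistenceMatrix:
    """Replicate-averaged coexistence levels over a 2-parameter grid."""

    x_name: str
    x_values: np.ndarray
    y_name: str
    y_values: np.ndarray
    mean_level: np.ndarray  # (ny, nx)
    sem: np.ndarray
    frac3: np.ndarray
    n: int
    tallies: list = field(default_factory=list)  # per-cell survivor-set counters

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iy, y in enumerate(self.y_values):
            for ix, x in enumerate(self.x_values):
                rows.append({
                    self.x_name: x, self.y_name: y,
                    "mean_level": self.mean_level[iy, ix],
                    "sem": self.sem[iy, ix],
                    "frac3": self.frac3[iy, ix],
                    "n": self.n,
                })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        """Long-format CSV plus a JSON metadata sidecar."""
        import json
        from pathlib import Path

        self.to_frame().to_csv(path, index=False)
        meta = {
            "x": {"name": self.x_name, "values": list(map(float, self.x_values))},
            "y": {"name": self.y_name, "values": list(map(float, self.y_values))},
            "n_reps": self.n,
            "tallies": self.tallies,
        }
        Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=2))

    def plot(self, ax=None, metric: str = "mean_level"):
        """Heat-map of the diagram (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        z = getattr(self, metric)
        im = ax.pcolormesh(self.x_values, self.y_values, z, shading="nearest",
                           cmap="viridis", vmin=0, vmax=3 if metric == "mean_level" else 1)
        ax.set_xlabel(self.x_name)
        ax.set_ylabel(self.y_name)
        plt.colorbar(im, ax=ax, label=metric)
        return ax


def sweep_diagram(x_param: str, y_param: str, x_values, y_values,
                  base_scenario: ScenarioConfig, n_reps: int, seed: int,
                  sector_cfg: SectorConfig | None = None,
                  progress: bool = False) -> CoexistenceMatrix:
    """Fill a coexistence diagram over a 2-parameter grid.

    Each cell runs ``n_reps`` independent expansions with per-cell derived
    seeds, so results are reproducible and independent of execution order.
    """
    x_values = np.asarray(list(x_values), dtype=float)
    y_values = np.asarray(list(y_values), dtype=float)
    if len(x_values) == 0 or len(y_values) == 0:
        raise ValueError("sweep grids must be non-empty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    mean = np.zeros((len(y_values), len(x_values)))
    sem = np.zeros_like(mean)
    frac3 = np.zeros_like(mean)
    tallies = []
    for iy, y in enumerate(y_values):
        for ix, x in enumerate(x_values):
            cfg = apply_sweep_param(apply_sweep_param(base_scenario, x_param, x), y_param, y)
            sets = [
                classify_survivors(run_expansion(cfg, replicate_seed(seed, ix, iy, r)), sector_cfg)
                for r in range(n_reps)
            ]
            mean[iy, ix], sem[iy, ix], frac3[iy, ix] = coexistence_level(sets)
            tally: dict[str, int] = {}
            for s in sets:
                key = "".join(sorted(s)) or "none"
                tally[key] = tally.get(key, 0) + 1
            tallies.append({"ix": ix, "iy": iy, "tally": tally})
            if progress:
                print(f"  cell ({x_param}={x:g}, {y_param}={y:g}): "
                      f"level={mean[iy, ix]:.2f} frac3={frac3[iy, ix]:.2f}")
    return CoexistenceMatrix(x_param, x_values, y_param, y_values, mean, sem, frac3, n_reps, tallies)


def extract_ridge(matrix: CoexistenceMatrix, axis: str = "x",
                  metric: str = "frac3") -> np.ndarray:
    """Ridge of maximal coexistence: for each value along ``axis``, the
    other-axis value maximizing the chosen metric.

    Ties within a contiguous plateau resolve to the plateau midpoint.  Slices
    with no distinct maximum are skipped with a warning.  Falls back to
    ``mean_level`` where the three-strain fraction is flat zero.
    Returns an (n, 2) array of (x, y) points.
    """
    pts = []
    z = getattr(matrix, metric)
    zfall = matrix.mean_level
    n_along = len(matrix.x_values) if axis == "x" else len(matrix.y_values)
    for i in range(n_along):
        col = z[:, i] if axis == "x" else z[i, :]
        other = matrix.y_values if axis == "x" else matrix.x_values
        if col.max() <= 0 and metric == "frac3":
            col = zfall[:, i] if axis == "x" else zfall[i, :]
        if math.isclose(float(col.max()), float(col.min())):
            warnings.warn(f"slice {i}: no distinct maximum; skipped", stacklevel=2)
            continue
        best = np.flatnonzero(col == col.max())
        runs = np.split(best, np.flatnonzero(np.diff(best) > 1) + 1)
        run = max(runs, key=len)
        yv = float(other[run[len(run) // 2]])
        xv = float((matrix.x_values if axis == "x" else matrix.y_values)[i])
        pts.append((xv, yv))
    return np.array(pts).reshape(-1, 2)


def _saturation(x, a, b, c):
    return (a + b * x) / (c + x)


def _power(x, amp, p):
    return amp * np.power(x, -p)


@dataclass
class LawFit:
    """Fitted biodiversity law: functional form, coefficients, diagnostics."""

    form: str
    coefficients: tuple
    rss: float
    points: np.ndarray

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "saturation":
            return _saturation(x, *self.coefficients)
        if self.form == "linear":
            a, b = self.coefficients
            return a + b * x
        if self.form == "power":
            return _power(x, *self.coefficients)
        raise ValueError(f"unknown form {self.form!r}")

    def summary(self) -> str:
        names = {
            "saturation": ("a", "b", "c"),
            "linear": ("intercept", "slope"),
            "power": ("amplitude", "exponent"),
        }[self.form]
        formula = {
            "saturation": "y = (a + b*x) / (c + x)",
            "linear": "y = intercept + slope * x",
            "power": "y = amplitude / x**exponent",
        }[self.form]
        lines = [
            f"Biodiversity law fit: {self.form}",
            f"  model: {formula}",
            f"  n points: {len(self.points)}",
            f"  RSS: {self.rss:.4g}",
        ]
        for nm, v in zip(names, self.coefficients):
            lines.append(f"  {nm:>10s} = {v:.4f}")
        return "\n".join(lines)


def fit_law(points: np.ndarray, form: str) -> LawFit:
    """Fit a biodiversity law to ridge points.

    ``saturation``: y = (a + b x)/(c + x), nonlinear least squares;
    ``linear``: ordinary least squares; ``power``: y = A x^-p, least squares
    on log-log coordinates (both x and y must be positive).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    x, y = points[:, 0], points[:, 1]
    arity = {"saturation": 3, "linear": 2, "power": 2}
    if form not in arity:
        raise ValueError(f"unknown law form {form!r}")
    if len(points) < arity[form]:
        raise ValueError(f"{form} law needs at least {arity[form]} points")
    if form == "linear":
        if np.allclose(x, x[0]):
            raise ValueError("degenerate point set: all x equal")
        b, a = np.polyfit(x, y, 1)
        resid = y - (a + b * x)
        return LawFit("linear", (float(a), float(b)), float(resid @ resid), points)
    if form == "power":
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("power-law fit needs positive x and y")
        slope, logA = np.polyfit(np.log(x), np.log(y), 1)
        amp, p = float(math.exp(logA)), float(-slope)
        resid = y - _power(x, amp, p)
        return LawFit("power", (amp, p), float(resid @ resid), points)
    # saturation
    p0 = (max(y.min(), 1e-3) * np.median(x), y.max(), np.median(x))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(_saturation, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise ValueError(f"saturation fit failed to converge: {exc}") from exc
    resid = y - _saturation(x, *popt)
    return LawFit("saturation", tuple(float(v) for v in popt), float(resid @ resid), points)
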