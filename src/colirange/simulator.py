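"""Lattice Gillespie engine for competitive range expansions.

A colony is a square lattice of mesoscopic patches (default 25 µm).  A
colonized patch hops its strain onto uniformly chosen open 8-neighbours at
rate ``hop_rate * n_open / 8`` once its lag has expired.  Toxic C patches
(3% of C colonizations) deposit a stationary exponential colicin kernel;
sensitive patches at super-threshold concentration are blocked from
colonizing in and lyse.  Lysed ground can be re-colonized by R and C.

Two interchangeable drivers share these semantics:

* :func:`step` — a transparent pure-Python single-event reference used for
  exactness tests on micro-instances,
* :func:`run_expansion` — the compiled whole-colony driver.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _core
from .params import (
    C,
    FREE,
    LYSED,
    R,
    S,
    STRAIN_CODES,
    STRAIN_NAMES,
    CollisionGeometry,
    InoculumSpec,
    LagDistribution,
    LatticeConfig,
    ScenarioConfig,
    ToxinParams,
)

__all__ = [
    "FRONT_FACTOR",
    "Lattice",
    "SimResult",
    "hop_rate_for_velocity",
    "velocity_for_hop_rate",
    "seed_inoculum",
    "assign_toxic",
    "step",
    "run_expansion",
    "run_lattice",
    "simulate_collision",
]

#: Measured front-speed constant of the 8-neighbour Eden-like lattice:
#: radial front velocity = FRONT_FACTOR * hop_rate * patch_size.  Obtained
#: from reference single-strain runs (see calibration.measure_front_factor);
#: direction-averaged, the octagonal anisotropy of the lattice is ~5%.
FRONT_FACTOR = 0.80

_NB = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def hop_rate_for_velocity(velocity: float, patch_size: float, front_factor: float = FRONT_FACTOR) -> float:
    """Hop rate (events/h) giving the requested front velocity (µm/h)."""
    return velocity / (front_factor * patch_size)


def velocity_for_hop_rate(hop_rate: float, patch_size: float, front_factor: float = FRONT_FACTOR) -> float:
    return hop_rate * front_factor * patch_size


def _truncated_gaussian(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Gaussian draws resampled to be non-negative."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


@dataclass
class Lattice:
    """Mutable simulation state shared by both engine drivers."""

    state: np.ndarray  # int8 (G, G)
    act_time: np.ndarray  # float64, activation (lag-expiry) time
    col_time: np.ndarray  # float64, colonization time (nan if never)
    conc: np.ndarray  # float64, colicin concentration
    toxic: np.ndarray  # uint8
    patch_size: float
    clock: float = 0.0
    mu: np.ndarray = field(default_factory=lambda: np.zeros(5))  # hop rate per state code
    new_lag: np.ndarray = field(default_factory=lambda: np.zeros(5))
    toxin: ToxinParams | None = None
    lysis_rate: float = 0.0
    lysed_recolonizable: bool = True
    lysis_enabled: bool = True

    @property
    def extent(self) -> int:
        return self.state.shape[0]

    @property
    def center(self) -> tuple[int, int]:
        return (self.extent // 2, self.extent // 2)

    def colonized_mask(self) -> np.ndarray:
        return (self.state >= S) & (self.state <= C)

    def max_radius_um(self) -> float:
        """Distance from the grid centre to the farthest ever-colonized patch."""
        occupied = self.state >= S  # includes LYSED ground
        if not occupied.any():
            return 0.0
        ii, jj = np.nonzero(occupied)
        cy, cx = self.center
        r = np.sqrt((ii - cy) ** 2.0 + (jj - cx) ** 2.0)
        return float(r.max() * self.patch_size)


def _empty_lattice(extent: int, patch_size: float) -> Lattice:
    return Lattice(
        state=np.zeros((extent, extent), dtype=np.int8),
        act_time=np.full((extent, extent), np.inf),
        col_time=np.full((extent, extent), np.nan),
        conc=np.zeros((extent, extent)),
        toxic=np.zeros((extent, extent), dtype=np.uint8),
        patch_size=patch_size,
    )


def assign_toxic(strain: int, params: ToxinParams, rng: np.random.Generator) -> bool:
    """Bernoulli toxic-site draw: only C patches can be toxic."""
    if strain != C:
        return False
    return bool(rng.random() < params.toxic_fraction)


def _seed_droplet(lat: Lattice, center: tuple[int, int], radius_um: float,
                  fractions: tuple[float, float, float], lag: LagDistribution,
                  toxin: ToxinParams | None, rng: np.random.Generator) -> None:
    """Colonize a well-mixed droplet in place (strain, lag and toxic draws)."""
    G = lat.extent
    cy, cx = center
    r_p = radius_um / lat.patch_size
    ii, jj = np.nonzero(
        (np.arange(G)[:, None] - cy) ** 2.0 + (np.arange(G)[None, :] - cx) ** 2.0 <= r_p * r_p
    )
    if len(ii) == 0:
        raise ValueError("droplet radius smaller than one patch")
    if ii.min() == 0 or jj.min() == 0 or ii.max() == G - 1 or jj.max() == G - 1:
        raise ValueError("inoculum droplet does not fit on the grid")
    strains = rng.choice([S, R, C], size=len(ii), p=np.asarray(fractions))
    lat.state[ii, jj] = strains
    lat.col_time[ii, jj] = 0.0
    lat.act_time[ii, jj] = _truncated_gaussian(rng, lag.mean, lag.sd, len(ii))
    if toxin is not None and toxin.kappa > 0 and toxin.toxic_fraction > 0:
        is_c = strains == C
        tox = is_c & (rng.random(len(ii)) < toxin.toxic_fraction)
        lam_p = toxin.lambda_ / lat.patch_size
        cutoff_p = toxin.cutoff_factor * lam_p
        dummy_list = np.empty(1, dtype=np.int64)
        dummy_pos = np.full((1, 1), -1, dtype=np.int64)
        for i, j in zip(ii[tox], jj[tox]):
            lat.toxic[i, j] = 1
            _core.add_source_kernel(lat.conc, lat.state, int(i), int(j),
                                    toxin.kappa, lam_p, cutoff_p,
                                    toxin.threshold, dummy_list, dummy_pos,
                                    0, False)


def seed_inoculum(spec: InoculumSpec, cfg: LatticeConfig, strain_params: dict,
                  seed, toxin: ToxinParams | None = None,
                  lag: LagDistribution | None = None) -> Lattice:
    """Seed a well-mixed droplet inoculum at the grid centre.

    ``strain_params`` maps strain ids ("S"/"R"/"C") to hop rates (events/h)
    or to objects with a ``hop_rate`` attribute.
    """
    rng = np.random.default_rng(seed)
    lat = _empty_lattice(cfg.extent, cfg.patch_size)
    lat.toxin = toxin
    for sid, sp in strain_params.items():
        rate = getattr(sp, "hop_rate", sp)
        lat.mu[STRAIN_CODES[sid]] = float(rate)
        lat.new_lag[STRAIN_CODES[sid]] = float(getattr(sp, "new_site_lag", 0.0))
    if lag is None:
        lags = [getattr(sp, "initial_lag", None) for sp in strain_params.values()]
        lag = next((l for l in lags if l is not None), LagDistribution())
    _seed_droplet(lat, lat.center, cfg.inoculum_radius, spec.fractions, lag, toxin, rng)
    lat.lysis_rate = 10.0 * float(lat.mu.max())
    return lat


def _open_neighbours(lat: Lattice, i: int, j: int, s: int) -> list[tuple[int, int]]:
    G = lat.extent
    out = []
    for di, dj in _NB:
        ii, jj = i + di, j + dj
        if 0 <= ii < G and 0 <= jj < G:
            st = lat.state[ii, jj]
            if st == FREE or (st == LYSED and lat.lysed_recolonizable and s != S):
                out.append((ii, jj))
    return out


def step(lat: Lattice, rng: np.random.Generator) -> dict:
    """Execute one exact Gillespie event on the lattice (reference driver).

    Recomputes every propensity from scratch, so it is transparent but only
    suited to small lattices.  Returns an event record.  Lag expiries are
    handled as deterministic barriers: if the drawn waiting time would jump
    past the next expiry, the clock advances to the expiry instead and an
    ``activation`` record is returned (exact by memorylessness).
    """
    thr = lat.toxin.threshold if lat.toxin is not None else math.inf
    active: list[tuple[int, int, float]] = []
    for i, j in zip(*np.nonzero(lat.colonized_mask())):
        if lat.act_time[i, j] <= lat.clock:
            s = int(lat.state[i, j])
            n_open = len(_open_neighbours(lat, i, j, s))
            if n_open > 0:
                active.append((int(i), int(j), lat.mu[s] * n_open / 8.0))
    lysable: list[tuple[int, int]] = []
    if lat.lysis_enabled and lat.toxin is not None:
        for i, j in zip(*np.nonzero((lat.state == S) & (lat.conc >= thr))):
            lysable.append((int(i), int(j)))
    total = sum(p for _, _, p in active) + len(lysable) * lat.lysis_rate

    pending = lat.act_time[lat.colonized_mask() & (lat.act_time > lat.clock)]
    next_act = float(pending.min()) if pending.size else math.inf

    if total <= 0:
        if math.isinf(next_act):
            return {"type": "stall", "time": lat.clock}
        lat.clock = next_act
        return {"type": "activation", "time": lat.clock}
    dt = rng.exponential(1.0 / total)
    if lat.clock + dt >= next_act:
        lat.clock = next_act
        return {"type": "activation", "time": lat.clock}
    lat.clock += dt

    x = rng.random() * total
    lys_tot = len(lysable) * lat.lysis_rate
    if x < lys_tot:
        i, j = lysable[min(int(x / lat.lysis_rate), len(lysable) - 1)]
        lat.state[i, j] = LYSED
        return {"type": "lysis", "time": lat.clock, "site": (i, j)}
    x -= lys_tot
    acc = 0.0
    sel = active[-1]
    for entry in active:
        acc += entry[2]
        if x < acc:
            sel = entry
            break
    i, j, _ = sel
    s = int(lat.state[i, j])
    opens = _open_neighbours(lat, i, j, s)
    ti, tj = opens[rng.integers(len(opens))]
    if s == S and lat.conc[ti, tj] >= thr:
        return {"type": "rejected", "time": lat.clock, "site": (i, j), "target": (ti, tj)}
    lat.state[ti, tj] = s
    lat.col_time[ti, tj] = lat.clock
    lat.act_time[ti, tj] = lat.clock + lat.new_lag[s]
    if s == C and lat.toxin is not None and assign_toxic(s, lat.toxin, rng):
        lat.toxic[ti, tj] = 1
        lam_p = lat.toxin.lambda_ / lat.patch_size
        dummy_list = np.empty(1, dtype=np.int64)
        dummy_pos = np.full((1, 1), -1, dtype=np.int64)
        _core.add_source_kernel(lat.conc, lat.state, ti, tj, lat.toxin.kappa,
                                lam_p, lat.toxin.cutoff_factor * lam_p,
                                thr, dummy_list, dummy_pos, 0, False)
    return {"type": "colonize", "time": lat.clock, "site": (i, j),
            "target": (ti, tj), "strain": STRAIN_NAMES[s]}


_STOP_REASONS = {
    _core.REASON_RADIUS: "radius_reached",
    _core.REASON_STALLED: "stalled",
    _core.REASON_TIME: "time_reached",
    _core.REASON_MAX_EVENTS: "max_events",
}


@dataclass
class SimResult:
    """Outcome of one range-expansion run."""

    lattice: Lattice
    stop_reason: str
    time: float  # h
    seed: int
    config: dict
    inoculum_radius: float  # µm
    n_events: int = 0
    record_times: np.ndarray | None = None  # h
    record_radii: np.ndarray | None = None  # µm, area-equivalent front radius

    @property
    def state(self) -> np.ndarray:
        return self.lattice.state

    def max_radius_um(self) -> float:
        return self.lattice.max_radius_um()

    def strain_fractions(self) -> dict[str, float]:
        """Fraction of ever-colonized patches currently owned per strain."""
        tot = int((self.state >= S).sum())
        if tot == 0:
            return {k: 0.0 for k in STRAIN_CODES}
        return {k: float((self.state == v).sum()) / tot for k, v in STRAIN_CODES.items()}

    def save(self, path) -> None:
        """Persist as a compressed label grid plus a JSON sidecar."""
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            state=self.lattice.state,
            toxic=self.lattice.toxic,
            col_time=self.lattice.col_time,
            conc=self.lattice.conc,
        )
        meta = {
            "stop_reason": self.stop_reason,
            "time": self.time,
            "seed": int(self.seed),
            "patch_size": self.lattice.patch_size,
            "inoculum_radius": self.inoculum_radius,
            "n_events": int(self.n_events),
            "config": _jsonable(self.config),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "SimResult":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        lat = _empty_lattice(arrays["state"].shape[0], meta["patch_size"])
        lat.state = arrays["state"]
        lat.toxic = arrays["toxic"]
        lat.col_time = arrays["col_time"]
        lat.conc = arrays["conc"]
        return cls(
            lattice=lat,
            stop_reason=meta["stop_reason"],
            time=meta["time"],
            seed=meta["seed"],
            config=meta["config"],
            inoculum_radius=meta["inoculum_radius"],
            n_events=meta["n_events"],
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    return obj


def run_lattice(lat: Lattice, stop_radius_um: float, stop_time: float,
                core_seed: int, record_times=None,
                max_events: int | None = None) -> tuple[dict, np.ndarray]:
    """Drive a seeded lattice with the compiled engine until stop."""
    if record_times is None:
        record_times = np.empty(0)
    record_times = np.asarray(record_times, dtype=float)
    record_area = np.zeros(len(record_times), dtype=np.int64)
    if lat.toxin is not None:
        tox = lat.toxin
        kappa, lam_p = tox.kappa, tox.lambda_ / lat.patch_size
        cutoff_p, thr, p_tox = tox.cutoff_factor * lam_p, tox.threshold, tox.toxic_fraction
    else:
        kappa = lam_p = cutoff_p = p_tox = 0.0
        lam_p, cutoff_p, thr = 1.0, 0.0, math.inf
    if max_events is None:
        max_events = 80 * lat.extent * lat.extent
    stop_r_p = stop_radius_um / lat.patch_size if math.isfinite(stop_radius_um) else 1e9
    t, reason, max_r2, ev, n_col = _core.run_core(
        lat.state, lat.act_time, lat.col_time, lat.conc, lat.toxic,
        lat.mu, lat.new_lag, p_tox, kappa, lam_p, cutoff_p, thr,
        lat.lysis_rate if lat.lysis_enabled else 0.0,
        stop_r_p, stop_time, record_times, record_area,
        int(core_seed), lat.lysed_recolonizable, lat.lysis_enabled, max_events)
    lat.clock = t
    info = {
        "time": t,
        "stop_reason": _STOP_REASONS[int(reason)],
        "max_radius_um": math.sqrt(max_r2) * lat.patch_size,
        "n_events": int(ev),
        "n_colonized": int(n_col),
    }
    return info, record_area


def run_expansion(cfg: ScenarioConfig, seed: int, record_times=None) -> SimResult:
    """Run one competitive range expansion to the stop radius.

    Identical ``cfg`` and ``seed`` reproduce the run exactly.
    """
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 2718])
    seed_py, seed_core = (int(s) % 2**31 for s in ss.generate_state(2))
    velocities = cfg.strain_velocities()
    mu = {sid: hop_rate_for_velocity(v, cfg.lattice.patch_size) for sid, v in velocities.items()}
    toxin = cfg.toxin if (cfg.toxin_enabled and cfg.toxin.kappa > 0) else None
    lat = seed_inoculum(cfg.inoculum, cfg.lattice, mu, seed_py, toxin=toxin, lag=cfg.lag)
    lat.new_lag[:] = cfg.new_site_lag
    lat.lysed_recolonizable = cfg.lysed_recolonizable
    lat.lysis_enabled = cfg.lysis_enabled
    if cfg.lysis_rate is not None:
        lat.lysis_rate = cfg.lysis_rate
    info, record_area = run_lattice(
        lat, cfg.lattice.stop_radius, cfg.stop_time, seed_core, record_times)
    record = None
    if record_times is not None:
        record = np.sqrt(np.asarray(record_area) / math.pi) * cfg.lattice.patch_size
    return SimResult(
        lattice=lat,
        stop_reason=info["stop_reason"],
        time=info["time"],
        seed=int(seed),
        config=cfg.to_dict(),
        inoculum_radius=cfg.lattice.inoculum_radius,
        n_events=info["n_events"],
        record_times=None if record_times is None else np.asarray(record_times, float),
        record_radii=record,
    )


def simulate_collision(kappa: float, lambda_: float, geometry: CollisionGeometry,
                       seed: int, patch_size: float = 25.0,
                       v_s: float = 30.0, v_c: float = 20.4,
                       lag: LagDistribution | None = None,
                       toxic_fraction: float = 0.03) -> tuple[float, Lattice]:
    """Forward model of a C colony growing next to an S colony.

    Seeds one pure-C and one pure-S droplet separated along the x axis, runs
    to the observation time and returns the final front-to-front gap (µm):
    the smallest centre-to-centre distance between S- and C-owned patches
    minus one diagonal patch width (0 when the colonies touch).
    """
    if lag is None:
        lag = LagDistribution()
    geom = geometry
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 3141])
    seed_py, seed_core = (int(s) % 2**31 for s in ss.generate_state(2))
    rng = np.random.default_rng(seed_py)
    growth = max(v_s, v_c) * max(0.0, geom.observation_time - max(0.0, lag.mean - 2 * lag.sd))
    reach = geom.droplet_radius + growth
    half_w = (geom.center_separation / 2 + reach) / patch_size + 4
    G = 2 * int(math.ceil(half_w)) + 1
    lat = _empty_lattice(G, patch_size)
    toxin = ToxinParams(kappa=kappa, lambda_=lambda_, toxic_fraction=toxic_fraction)
    lat.toxin = toxin if kappa > 0 else None
    lat.mu[S] = hop_rate_for_velocity(v_s, patch_size)
    lat.mu[C] = hop_rate_for_velocity(v_c, patch_size)
    lat.lysis_rate = 10.0 * float(lat.mu.max())
    cy = cx = G // 2
    off = int(round(geom.center_separation / 2 / patch_size))
    _seed_droplet(lat, (cy, cx - off), geom.droplet_radius, (0.0, 0.0, 1.0), lag, lat.toxin, rng)
    _seed_droplet(lat, (cy, cx + off), geom.droplet_radius, (1.0, 0.0, 0.0), lag, lat.toxin, rng)
    run_lattice(lat, math.inf, geom.observation_time, seed_core)
    gap = final_gap(lat)
    return gap, lat


def final_gap(lat: Lattice) -> float:
    """Smallest S-front-to-C-front distance on a collision lattice (µm)."""
    from scipy.spatial import cKDTree

    s_pts = np.argwhere(lat.state == S)
    c_pts = np.argwhere(lat.state == C)
    if len(s_pts) == 0 or len(c_pts) == 0:
        return math.nan
    tree = cKDTree(c_pts)
    dmin, _ = tree.query(s_pts, k=1)
    return float(max(0.0, (dmin.min() - math.sqrt(2.0)) * lat.patch_size))
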