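"""Parameter containers and scenario presets.

The model describes a three-strain *E. coli* colicin E2 system expanding on an
agar plate: a colicin producer (C), a colicin-sensitive strain (S) and a
resistant strain (R).  Each strain carries one of three fluorescent markers
(GFP, mCherry, or none), and mCherry expression carries a measurable growth
cost.  Permuting the marker assignment therefore creates distinct ecological
scenarios:

* scenario I   (mCherry on R): cyclic dominance, v_S > v_R > v_C
  (C kills S, S outgrows R, R outgrows C — rock–paper–scissors),
* scenario II  (mCherry on S): strictly hierarchical, v_R > v_S >= v_C,
* scenario III (mCherry on C): intermediate, v_S ~= v_R >> v_C,
* null_model: three selectively neutral, non-interacting strains.

Velocities are maximal radial expansion velocities of single-strain colonies
in µm/h.  The mesoscopic engine represents the colony as a square lattice of
patches; a patch hosts the strain that locally dominates that area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "FREE",
    "S",
    "R",
    "C",
    "LYSED",
    "STRAIN_CODES",
    "STRAIN_NAMES",
    "LagDistribution",
    "StrainParams",
    "ToxinParams",
    "LatticeConfig",
    "InoculumSpec",
    "ScenarioConfig",
    "CollisionGeometry",
    "SCENARIO_MARKERS",
    "BASE_VELOCITY_UMH",
    "RELATIVE_VELOCITY_NFP",
    "MCHERRY_MULTIPLIER",
    "strain_velocity",
    "scenario_velocities",
    "make_scenario",
    "apply_sweep_param",
]

# Lattice site states (shared with the numba kernels).
FREE, S, R, C, LYSED = 0, 1, 2, 3, 4
STRAIN_CODES = {"S": S, "R": R, "C": C}
STRAIN_NAMES = {v: k for k, v in STRAIN_CODES.items()}

#: Absolute radial expansion velocity of the fastest (non-fluorescent S)
#: strain under slow growth, µm/h.  Only sets the time unit; competition
#: outcomes depend on velocity ratios.
BASE_VELOCITY_UMH = 30.0

#: Non-fluorescent relative radial velocities, v_S : v_R : v_C.
RELATIVE_VELOCITY_NFP = {"S": 1.00, "R": 0.95, "C": 0.68}

#: Growth-rate retained under mCherry expression (1 - printed percent cost),
#: per strain and growth condition.  GFP and nfp carry no measurable cost.
MCHERRY_MULTIPLIER = {
    "slow": {"C": 1 - 0.215, "R": 1 - 0.226, "S": 1 - 0.243},
    "fast": {"C": 1 - 0.130, "R": 1 - 0.164, "S": 1 - 0.157},
}

#: Marker assignment defining each ecological scenario.
SCENARIO_MARKERS = {
    "I": {"S": "GFP", "R": "mCh", "C": "nfp"},
    "II": {"S": "mCh", "R": "GFP", "C": "nfp"},
    "III": {"S": "GFP", "R": "nfp", "C": "mCh"},
    "null_model": {"S": "GFP", "R": "mCh", "C": "nfp"},
}


def strain_velocity(strain: str, marker: str, condition: str = "slow") -> float:
    """Radial expansion velocity (µm/h) of a strain/marker/condition combo."""
    if strain not in RELATIVE_VELOCITY_NFP:
        raise ValueError(f"unknown strain {strain!r}")
    if condition not in MCHERRY_MULTIPLIER:
        raise ValueError(f"unknown growth condition {condition!r}")
    v = BASE_VELOCITY_UMH * RELATIVE_VELOCITY_NFP[strain]
    if marker == "mCh":
        v *= MCHERRY_MULTIPLIER[condition][strain]
    elif marker not in ("GFP", "nfp"):
        raise ValueError(f"unknown marker {marker!r}")
    return v


def scenario_velocities(scenario: str, condition: str = "slow") -> dict[str, float]:
    """Per-strain radial velocities (µm/h) for a named scenario."""
    if scenario not in SCENARIO_MARKERS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "null_model":
        return {s: BASE_VELOCITY_UMH for s in ("S", "R", "C")}
    markers = SCENARIO_MARKERS[scenario]
    return {s: strain_velocity(s, markers[s], condition) for s in ("S", "R", "C")}


@dataclass(frozen=True)
class LagDistribution:
    """Gaussian (truncated at zero) distribution of mesoscopic lag times.

    Initially colonized patches only start hopping after an individual lag
    drawn from this distribution; the spread reproduces the gradual
    acceleration of colony expansion after inoculation.
    """

    mean: float = 10.0  # h
    sd: float = 3.0  # h
    kind: str = "gaussian_truncated_at_zero"

    def __post_init__(self):
        if self.mean < 0 or self.sd < 0:
            raise ValueError("lag mean and sd must be non-negative")


@dataclass(frozen=True)
class StrainParams:
    """Calibrated mesoscopic parameters of one strain/marker/condition.

    ``hop_rate`` is the Gillespie rate (events/h) at which a fully
    surrounded-by-free colonized patch spawns offspring; the resulting front
    velocity is ``front_factor * hop_rate * patch_size``.
    """

    strain_id: str
    marker: str = "nfp"
    condition: str = "slow"
    hop_rate: float = 1.0  # events/h at full free neighbourhood
    initial_lag: LagDistribution = field(default_factory=LagDistribution)
    new_site_lag: float = 0.0  # h, fixed lag of newly colonized patches
    target_velocity: float = BASE_VELOCITY_UMH  # µm/h

    def __post_init__(self):
        if self.hop_rate < 0 or self.target_velocity < 0:
            raise ValueError("hop_rate and target_velocity must be non-negative")
        if self.new_site_lag < 0:
            raise ValueError("new_site_lag must be non-negative")


@dataclass(frozen=True)
class ToxinParams:
    """Stationary colicin field parameters.

    Each toxic C patch is a source of an exponentially decaying concentration
    profile ``kappa * exp(-d / lambda_)``; profiles superpose.  A sensitive
    patch at concentration >= ``threshold`` is inhibited (cannot be colonized
    by S) and lyses.  Only ``kappa / threshold`` is identifiable, so the
    threshold is normalized to 1.
    """

    kappa: float = 7.389  # e^2: single-source inhibition halo = 2 * lambda_ = 250 µm
    lambda_: float = 125.0  # µm
    toxic_fraction: float = 0.03
    threshold: float = 1.0
    cutoff_factor: float = 6.0

    def __post_init__(self):
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if not 0 <= self.toxic_fraction <= 1:
            raise ValueError("toxic_fraction must be a probability")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class LatticeConfig:
    """Physical geometry of the simulation lattice."""

    patch_size: float = 25.0  # µm per lattice site
    inoculum_radius: float = 1000.0  # µm
    stop_radius: float = 3000.0  # µm
    grid_extent: int | None = None  # patches per side; auto if None
    neighbourhood: str = "8"

    def __post_init__(self):
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if not self.stop_radius > self.inoculum_radius > 0:
            raise ValueError("need stop_radius > inoculum_radius > 0")
        if self.neighbourhood != "8":
            raise ValueError("only the 8-neighbour lattice is implemented")
        if self.grid_extent is not None and self.grid_extent * self.patch_size <= 2 * self.stop_radius:
            raise ValueError("grid_extent * patch_size must exceed 2 * stop_radius")

    @property
    def extent(self) -> int:
        """Grid side length in patches (auto-sized to hold the stop radius)."""
        if self.grid_extent is not None:
            return self.grid_extent
        return 2 * (int(math.ceil(self.stop_radius / self.patch_size)) + 3) + 1


@dataclass(frozen=True)
class InoculumSpec:
    """Initial well-mixed droplet composition, ratios r_S : r_R : r_C."""

    ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    scenario: str = "I"

    def __post_init__(self):
        if len(self.ratios) != 3 or any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be three non-negative numbers")
        if sum(self.ratios) <= 0:
            raise ValueError("at least one inoculum ratio must be positive")

    @property
    def fractions(self) -> tuple[float, float, float]:
        tot = sum(self.ratios)
        return tuple(r / tot for r in self.ratios)


@dataclass(frozen=True)
class CollisionGeometry:
    """Two-droplet layout for C-vs-S colony collision experiments."""

    center_separation: float = 900.0  # µm
    droplet_radius: float = 200.0  # µm
    observation_time: float = 16.0  # h

    def __post_init__(self):
        if self.center_separation <= 0 or self.droplet_radius <= 0:
            raise ValueError("separation and droplet radius must be positive")
        if self.center_separation <= 2 * self.droplet_radius:
            raise ValueError("droplets overlap: separation must exceed 2 * droplet_radius")
        if self.observation_time <= 0:
            raise ValueError("observation_time must be positive")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete configuration of one competitive range-expansion run."""

    inoculum: InoculumSpec = field(default_factory=InoculumSpec)
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    toxin: ToxinParams = field(default_factory=ToxinParams)
    condition: str = "slow"
    velocities: dict | None = None  # strain -> µm/h; scenario defaults if None
    lag: LagDistribution = field(default_factory=LagDistribution)
    new_site_lag: float = 0.0  # h
    toxin_enabled: bool = True
    lysis_rate: float | None = None  # events/h; 10x max hop rate if None
    lysed_recolonizable: bool = True
    lysis_enabled: bool = True
    stop_time: float = math.inf  # h

    def strain_velocities(self) -> dict[str, float]:
        if self.velocities is not None:
            return dict(self.velocities)
        return scenario_velocities(self.inoculum.scenario, self.condition)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["velocities"] = self.strain_velocities()
        return d


def make_scenario(
    scenario: str = "I",
    ratios: tuple[float, float, float] = (1.0, 1.0, 1.0),
    condition: str = "slow",
    **overrides,
) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a scenario preset id."""
    if scenario not in SCENARIO_MARKERS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(SCENARIO_MARKERS)}")
    cfg = ScenarioConfig(
        inoculum=InoculumSpec(ratios=tuple(float(r) for r in ratios), scenario=scenario),
        condition=condition,
        toxin_enabled=(scenario != "null_model"),
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def apply_sweep_param(cfg: ScenarioConfig, name: str, value: float) -> ScenarioConfig:
    """Return a config with one sweep parameter applied.

    Supported names: initial ratios ``r_S``/``r_R``/``r_C``, relative growth
    rates ``g_R``/``g_C`` (velocity of R or C as a fraction of S's velocity),
    and the colicin decay length ``lambda_`` (µm).
    """
    if name in ("r_S", "r_R", "r_C"):
        idx = ("r_S", "r_R", "r_C").index(name)
        ratios = list(cfg.inoculum.ratios)
        ratios[idx] = float(value)
        return replace(cfg, inoculum=replace(cfg.inoculum, ratios=tuple(ratios)))
    if name in ("g_R", "g_C"):
        v = cfg.strain_velocities()
        v[name[-1]] = float(value) * v["S"]
        return replace(cfg, velocities=v)
    if name == "lambda_":
        return replace(cfg, toxin=replace(cfg.toxin, lambda_=float(value)))
    raise ValueError(f"unknown sweep parameter {name!r}")
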