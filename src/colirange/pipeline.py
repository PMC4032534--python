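"""Configuration-driven pipeline: simulate -> classify -> sweep -> fit -> render.

A run is described by a YAML or JSON config (see ``config_schema`` below for
the accepted keys).  Stages execute in dependency order, every stochastic
stage records its seed, and the run directory receives a ``manifest.json``
inventory, so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .analysis import (
    classify_survivors,
    coexistence_level,
    extract_ridge,
    fit_law,
    sweep_diagram,
)
from .params import (
    SCENARIO_MARKERS,
    LatticeConfig,
    ScenarioConfig,
    ToxinParams,
    make_scenario,
)
from .simulator import SimResult, run_expansion

__all__ = ["RunManifest", "run_pipeline", "render_pattern", "load_config", "config_schema"]

_PALETTE = {
    "GFP": (40, 170, 40),
    "mCh": (205, 45, 45),
    "nfp": (15, 15, 15),
    "lysed": (105, 105, 105),
    "background": (255, 255, 255),
}

_SCHEMA_KEYS = {"seed", "outdir", "stages", "scenario", "reps", "sweep", "record", "sector"}
_SCENARIO_KEYS = {"id", "ratios", "condition", "stop_radius", "inoculum_radius",
                  "patch_size", "kappa", "lambda", "toxic_fraction", "toxin_enabled",
                  "lag_mean", "lag_sd", "stop_time"}
_STAGES = ("simulate", "render", "sweep", "ridge", "fitlaw")


def config_schema() -> dict:
    """Documented config keys (values show defaults or expected types)."""
    return {
        "seed": 0,
        "outdir": "runs/out",
        "stages": list(_STAGES),
        "reps": 20,
        "scenario": {
            "id": "I | II | III | null_model",
            "ratios": [1.0, 1.0, 0.1],
            "condition": "slow | fast",
            "stop_radius": 3000.0,
            "inoculum_radius": 1000.0,
            "patch_size": 25.0,
            "kappa": ToxinParams().kappa,
            "lambda": ToxinParams().lambda_,
            "toxic_fraction": 0.03,
            "toxin_enabled": True,
        },
        "sweep": {
            "x": {"param": "r_R | r_C | g_R | g_C | lambda_", "values": []},
            "y": {"param": "...", "values": []},
            "law": "saturation | linear | power",
            "ridge_axis": "x",
        },
    }


@dataclass
class RunManifest:
    """Inventory of a pipeline run: config, seeds, outputs, wall times."""

    config: dict
    seed: int
    version: str = __version__
    outputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "outputs": self.outputs,
            "stage_seconds": self.stage_seconds,
            "results": self.results,
        }, indent=2, default=str))


class ConfigError(ValueError):
    """Raised when a pipeline config violates the documented schema."""


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        text = Path(path_or_dict).read_text()
        if str(path_or_dict).endswith((".yaml", ".yml")):
            import yaml

            cfg = yaml.safe_load(text)
        else:
            cfg = json.loads(text)
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    bad = set(cfg) - _SCHEMA_KEYS
    if bad:
        raise ConfigError(f"unknown config keys: {sorted(bad)}")
    sc = cfg.get("scenario", {})
    bad = set(sc) - _SCENARIO_KEYS
    if bad:
        raise ConfigError(f"unknown scenario keys: {sorted(bad)}")
    sid = sc.get("id", "I")
    if sid not in SCENARIO_MARKERS:
        raise ConfigError(f"unknown scenario id {sid!r}; choose from {sorted(SCENARIO_MARKERS)}")
    for stage in cfg.get("stages", []):
        if stage not in _STAGES:
            raise ConfigError(f"unknown stage {stage!r}; choose from {_STAGES}")
    if "sweep" in cfg:
        sw = cfg["sweep"]
        for ax in ("x", "y"):
            if ax not in sw or "param" not in sw[ax] or "values" not in sw[ax]:
                raise ConfigError(f"sweep.{ax} needs 'param' and 'values'")


def scenario_from_config(sc: dict) -> ScenarioConfig:
    lattice = LatticeConfig(
        patch_size=float(sc.get("patch_size", 25.0)),
        inoculum_radius=float(sc.get("inoculum_radius", 1000.0)),
        stop_radius=float(sc.get("stop_radius", 3000.0)),
    )
    toxin = ToxinParams(
        kappa=float(sc.get("kappa", ToxinParams().kappa)),
        lambda_=float(sc.get("lambda", ToxinParams().lambda_)),
        toxic_fraction=float(sc.get("toxic_fraction", 0.03)),
    )
    cfg = make_scenario(sc.get("id", "I"), tuple(sc.get("ratios", (1.0, 1.0, 1.0))),
                        sc.get("condition", "slow"), lattice=lattice, toxin=toxin)
    if "toxin_enabled" in sc:
        cfg = replace(cfg, toxin_enabled=bool(sc["toxin_enabled"]))
    if "lag_mean" in sc or "lag_sd" in sc:
        from .params import LagDistribution

        cfg = replace(cfg, lag=LagDistribution(float(sc.get("lag_mean", 10.0)),
                                               float(sc.get("lag_sd", 3.0))))
    if "stop_time" in sc:
        cfg = replace(cfg, stop_time=float(sc["stop_time"]))
    return cfg


def run_pipeline(config, outdir=None) -> RunManifest:
    """Execute the stages requested by a config; returns the run manifest."""
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    outdir = Path(outdir or cfg.get("outdir", "runs/out"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", ["simulate", "render"])
    scen = scenario_from_config(cfg.get("scenario", {}))
    reps = int(cfg.get("reps", 20))
    manifest = RunManifest(config=cfg, seed=seed)

    first_result: SimResult | None = None
    if "simulate" in stages:
        t0 = time.perf_counter()
        tallies: dict[str, int] = {}
        sets = []
        for rep in range(reps):
            res = run_expansion(scen, seed + rep)
            surv = classify_survivors(res)
            sets.append(surv)
            key = "".join(sorted(surv)) or "none"
            tallies[key] = tallies.get(key, 0) + 1
            if rep == 0:
                first_result = res
                res.save(outdir / "replicate0")
                manifest.outputs["replicate0"] = str(outdir / "replicate0.npz")
        mean, sem, frac3 = coexistence_level(sets)
        manifest.results["simulate"] = {
            "reps": reps, "survivor_tallies": tallies,
            "mean_coexistence": mean, "sem": sem, "three_strain_fraction": frac3,
            "seeds": [seed + r for r in range(reps)],
        }
        manifest.stage_seconds["simulate"] = round(time.perf_counter() - t0, 3)

    if "render" in stages:
        t0 = time.perf_counter()
        if first_result is None:
            first_result = run_expansion(scen, seed)
        png = outdir / "pattern.png"
        render_pattern(first_result, scen.inoculum.scenario, png)
        manifest.outputs["pattern"] = str(png)
        manifest.stage_seconds["render"] = round(time.perf_counter() - t0, 3)

    if "sweep" in stages:
        t0 = time.perf_counter()
        sw = cfg["sweep"]
        matrix = sweep_diagram(sw["x"]["param"], sw["y"]["param"],
                               sw["x"]["values"], sw["y"]["values"],
                               scen, n_reps=reps, seed=seed)
        matrix.to_csv(outdir / "sweep.csv")
        manifest.outputs["sweep"] = str(outdir / "sweep.csv")
        manifest.stage_seconds["sweep"] = round(time.perf_counter() - t0, 3)
        if "ridge" in stages or "fitlaw" in stages:
            ridge = extract_ridge(matrix, axis=sw.get("ridge_axis", "x"))
            np.savetxt(outdir / "ridge.csv", ridge, delimiter=",", header="x,y")
            manifest.outputs["ridge"] = str(outdir / "ridge.csv")
        if "fitlaw" in stages:
            law = fit_law(ridge, sw.get("law", "linear"))
            manifest.results["law"] = {
                "form": law.form,
                "coefficients": list(law.coefficients),
                "rss": law.rss,
            }
            (outdir / "law.json").write_text(json.dumps(manifest.results["law"], indent=2))
            manifest.outputs["law"] = str(outdir / "law.json")

    manifest.save(outdir / "manifest.json")
    manifest.outputs["manifest"] = str(outdir / "manifest.json")
    return manifest


def render_pattern(result: SimResult | str, scenario: str, out_path) -> None:
    """Render a label grid as a PNG in the fluorescence-image convention.

    GFP-carrying strains are green, mCherry red, non-fluorescent black,
    lysed ground grey and uncolonized agar white; one patch per pixel.
    """
    from PIL import Image

    from .params import LYSED, STRAIN_CODES

    if isinstance(result, (str, Path)):
        result = SimResult.load(result)
    if scenario not in SCENARIO_MARKERS:
        raise ValueError(f"unknown palette/scenario key {scenario!r}")
    markers = SCENARIO_MARKERS[scenario]
    state = result.state
    img = np.empty((*state.shape, 3), dtype=np.uint8)
    img[:] = _PALETTE["background"]
    for sid, code in STRAIN_CODES.items():
        img[state == code] = _PALETTE[markers[sid]]
    img[state == LYSED] = _PALETTE["lysed"]
    Image.fromarray(img).save(out_path)
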