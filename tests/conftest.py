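import math

import numpy as np
import pytest

from colirange.params import (
    STRAIN_CODES,
    InoculumSpec,
    LagDistribution,
    LatticeConfig,
    ToxinParams,
    make_scenario,
)
from colirange.simulator import Lattice, SimResult, _empty_lattice


@pytest.fixture(scope="session")
def tiny_scenario():
    """Small, fast null-model scenario (no toxin, neutral rates)."""
    return make_scenario(
        "null_model", (1.0, 1.0, 1.0),
        lattice=LatticeConfig(patch_size=25.0, inoculum_radius=250.0, stop_radius=800.0),
        lag=LagDistribution(2.0, 1.0),
    )


@pytest.fixture(scope="session")
def small_scenario_I():
    """Scenario I at reduced stop radius for mid-weight checks."""
    return make_scenario(
        "I", (1.0, 1.0, 0.1),
        lattice=LatticeConfig(patch_size=25.0, inoculum_radius=500.0, stop_radius=1500.0),
    )


def paint_disc_result(painter, extent=101, disc_radius=45, patch_size=25.0,
                      inoc_radius_patches=10.0) -> SimResult:
    """Build a SimResult whose state is painted by ``painter(radius, angle_deg)``.

    ``painter`` returns a strain id ("S"/"R"/"C"), "LYSED" or None per patch.
    """
    lat = _empty_lattice(extent, patch_size)
    c = extent // 2
    for i in range(extent):
        for j in range(extent):
            r = math.hypot(i - c, j - c)
            if r > disc_radius:
                continue
            theta = math.degrees(math.atan2(i - c, j - c)) % 360.0
            sid = painter(r, theta)
            if sid == "LYSED":
                lat.state[i, j] = 4
            elif sid is not None:
                lat.state[i, j] = STRAIN_CODES[sid]
    return SimResult(
        lattice=lat, stop_reason="radius_reached", time=48.0, seed=0,
        config={}, inoculum_radius=inoc_radius_patches * patch_size,
    )


@pytest.fixture
def micro_lattice():
    """3x3 empty lattice factory for exact single-event checks."""

    def build(mu_s=1.0, mu_r=1.0, mu_c=1.0, toxin=None, lysis_rate=0.0):
        lat = _empty_lattice(3, 25.0)
        lat.mu[1], lat.mu[2], lat.mu[3] = mu_s, mu_r, mu_c
        lat.toxin = toxin
        lat.lysis_rate = lysis_rate
        return lat

    return build
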