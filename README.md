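# colirange

Stochastic lattice simulation and analysis of **colicin-mediated competitive
bacterial range expansions**.

When a droplet containing three *Escherichia coli* strains — a colicin E2
producer (**C**), a colicin-sensitive strain (**S**) and a resistant strain
(**R**) — is inoculated on agar, the expanding colony front fragments into
monoclonal sectors, and which strains keep a sector decides who survives
the expansion. Survival hinges on three interdependent factors: the
inoculum composition r_S : r_R : r_C, the relative radial growth rates, and
the effective range of the toxin. `colirange` is for quantitative
ecologists and biophysicists who want to simulate this system, map
coexistence phase diagrams and extract the phenomenological "biodiversity
laws" that trace regimes of maximal three-strain coexistence.

## The model in brief

A colony is a 2-D square lattice of 25 µm patches, each owned by the strain
that locally dominates it. A Gillespie algorithm drives:

* **colonization** — an active patch claims a uniformly chosen open
  8-neighbour at rate `μ_m · n_open/8`; the mesoscopic rate μ_m is
  calibrated so each strain's front moves at its measured radial velocity
  (v_S : v_R : v_C = 1.00 : 0.95 : 0.68 non-fluorescent, with printed
  mCherry growth costs defining three ecological scenarios);
* **lag times** — initially colonized patches activate after a truncated
  Gaussian lag τ_m, reproducing colony lag/acceleration phases;
* **toxin action** — 3 % of C patches are toxic sources of a stationary
  colicin field `κ·e^(−d/λ)` (λ = 125 µm, κ = e², fields superpose);
  sensitive patches at field ≥ 1 cannot be colonized by S and lyse.

A strain *survives* if it holds a connected front sector of ≥ 5° angular
extent that expanded at least half the leading strain's distance out of the
inoculum. Replicate-averaged survivor counts over 2-parameter sweeps give
coexistence diagrams; the ridge of maximal three-strain coexistence is
fitted by a saturation law `r_C = (a + b·r_R)/(c + r_R)`, a linear law
`g_R = a + b·g_C`, and a power law `r_C ∝ λ^(−p)`.

## Worked example

The rescue window: the cyclic scenario (v_S > v_R > v_C, C kills S) at the
reduced producer ratio S : R : C = 1 : 1 : 0.1.

```python
import numpy as np
from colirange import make_scenario, run_expansion, classify_survivors, coexistence_level

cfg = make_scenario("I", ratios=(1, 1, 0.1))
sets = [classify_survivors(run_expansion(cfg, seed)) for seed in range(40)]
mean, sem, frac3 = coexistence_level(sets)
print(f"mean coexistence level: {mean:.2f} +/- {sem:.2f}")
print(f"three-strain fraction : {frac3:.2f}")
```

prints

```
mean coexistence level: 2.45 +/- 0.09
three-strain fraction : 0.50
```

i.e. on average ~2.5 strains keep a stable front sector and half of the
replicates retain all three — the sensitive strain, doomed at equal ratios
(where the survivor set is {C, R} almost surely), is rescued by diluting
its killer's inoculum share. At equal ratios the same rescue is achieved
by shortening the toxin range to λ ≈ 50 µm instead
(`colirange.study.lambda_profile`).

The same pipeline is scriptable from the shell:

```bash
colirange demo --seed 7 --outdir runs/demo        # 20 replicates + PNG pattern
colirange simulate --scenario II --ratios 1,1,1 --reps 50 --outdir runs/sII
colirange fitlaw --config examples/power_sweep.yaml --outdir runs/power
```

`render`/`demo` write label-grid PNGs in the fluorescence convention
(GFP-carrier green, mCherry red, non-fluorescent black, lysed ground grey).

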