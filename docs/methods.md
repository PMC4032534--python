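# Methods

## The model

`colirange` simulates competitive range expansions of three *Escherichia
coli* strains — a colicin E2 producer (C), a colicin-sensitive strain (S)
and a resistant strain (R) — spreading from a well-mixed droplet inoculum on
agar. The description is mesoscopic: a two-dimensional square lattice of
patches (default 25 µm wide) in which each colonized patch represents the
strain locally dominating that area. Bacterial cell counts are far too
large for cell-level agents; the patch is the smallest unit at which the
front's local founder dynamics matter.

Dynamics are an exact continuous-time Markov process driven by a Gillespie
algorithm:

* **Colonization ("hopping").** A colonized patch whose lag has expired
  claims a uniformly chosen open 8-neighbour at propensity
  `hop_rate × n_open / 8`. The strain-specific hop rate is calibrated so
  the emergent front velocity matches the strain's measured maximal radial
  expansion velocity: on this lattice `velocity = 0.80 × hop_rate ×
  patch_size` (the 0.80 was measured on reference single-strain runs and is
  re-measurable with `calibration.measure_front_factor`; the octagonal
  anisotropy of the 8-neighbour Eden-like front is ~5 % and is averaged
  over).
* **Lag times.** Initially colonized patches only activate after an
  individual lag drawn from a truncated Gaussian (default mean 10 h, sd
  3 h). This reproduces the lag and acceleration phases of colony growth
  curves and creates the founder inequality at the droplet rim from which
  sectors nucleate. Newly colonized patches activate immediately by
  default: the steady-state per-patch colonization time is already absorbed
  in the hop rate. (Giving new patches an extra fixed lag comparable to the
  initial lag would cap the front speed at `patch_size / lag` ≈ 3 µm/h,
  an order of magnitude below measured velocities, which is why the package
  departs from an equal-lag default; the knob remains configurable.)
  Lag expiries are deterministic rate changes, handled exactly as time
  barriers with waiting-time redraw (valid by memorylessness).
* **Toxicity.** 3 % of initially and newly colonized C patches are toxic.
  Colicin diffuses orders of magnitude faster than patches are colonized
  (colicin diffusion constant ~1e-7 cm²/s), so each toxic patch contributes
  a stationary source–degradation profile `κ·exp(−d/λ)`; profiles add, and
  sources never decay. Kernels are truncated beyond 6λ (discarding < e⁻⁶
  of a source). A sensitive patch at concentration ≥ 1 (the threshold is
  normalized to 1; only κ/threshold is identifiable) cannot be colonized by
  S — attempts are rejected by thinning, which preserves the exactness of
  the Gillespie clock — and lyses at rate `lysis_rate` (default 10× the
  largest hop rate: "fast kill"; outcomes are insensitive to this choice
  once lysis is faster than colonization). Lysed ground can be re-colonized
  by R and C (cleared ground), never by S (the field is cumulative). Both
  the lyse-vs-block behaviour and lysed-ground recolonization sit behind
  switches.
* A run stops when the farthest colonized patch reaches the stop radius
  (default 3 mm), when a stop time is reached (collision experiments), or
  when no event is possible (stall — a legal outcome, e.g. a sensitive
  colony ringed by toxin).

Two drivers share these semantics: a transparent pure-Python single-event
`step` used for exactness tests on micro-instances (uniform neighbour
choice, lag gating, competing-exponential odds, χ² against hand-computed
propensities), and a compiled (numba) whole-colony driver with incremental
propensity bookkeeping. A full 3 mm colony (~45 000 patches) runs in well
under a second, which is what makes 250-replicate statistics and 8×9-cell
phase diagrams tractable on one CPU.

## Parameters

| parameter | default | units | origin |
|---|---|---|---|
| patch size | 25 | µm | resolves λ (5 patches) and the 100–400 µm halos |
| inoculum radius | 1000 | µm | droplet-to-final-radius proportion of colony images |
| stop radius | 3000 | µm | simulation endpoint used for published patterns |
| base velocity v_S (nfp, slow) | 30 | µm/h | typical slow-growth radial velocity; sets the time unit only |
| relative velocities v_S : v_R : v_C | 1.00 : 0.95 : 0.68 | — | printed growth-rate hierarchy |
| mCherry velocity multipliers (slow) | 0.785 / 0.774 / 0.757 (C/R/S) | — | printed 21.5 / 22.6 / 24.3 % costs |
| mCherry velocity multipliers (fast) | 0.870 / 0.836 / 0.843 (C/R/S) | — | printed 13.0 / 16.4 / 15.7 % costs |
| initial lag | N(10, 3²) h, truncated ≥ 0 | h | broad per-patch lag reproducing colony lag phase |
| toxic fraction | 0.03 | — | 3 % of C patches lyse and release colicin |
| λ (colicin decay length) | 125 | µm | calibrated collision length scale |
| κ (colicin strength) | e² ≈ 7.39 | threshold units | single-source halo λ·ln κ = 250 µm, midpoint of the reported 100–400 µm inhibition zones; collision-gap forward sims then give gaps of 120–350 µm |
| lysis rate | 10 × max hop rate | /h | fast kill |

Scenario presets permute the marker assignment: I (mCherry on R) is cyclic
(v_S > v_R > v_C with C killing S), II (mCherry on S) strictly hierarchical
(v_R > v_S ≥ v_C), III (mCherry on C) intermediate (v_S ≈ v_R ≫ v_C), and
`null_model` is three neutral, non-interacting strains.

## Survivor classification

A strain survives a range expansion if it keeps at least one stable sector
touching the expanding front. Operationally: among colonized patches
adjacent to the outside region (free space connected to the grid border, so
interior enclaves do not count), a strain must own an 8-connected cluster
with angular extent ≥ 5° about the colony centre whose tip has expanded at
least half the expansion distance of the leading strain beyond the inoculum
radius. The half-distance depth rule follows the published survival
criterion; the 5° minimum (~3 front patches at the stop radius)
operationalizes "stable sector". Neither sector counts nor strain
frequencies enter. The *coexistence level* of a parameter point is the
mean number of survivors over replicates; the *three-strain fraction* is
the fraction of replicates with all three.

## Sweeps, ridges and biodiversity laws

`sweep_diagram` fills a 2-parameter grid with replicate-averaged
coexistence levels; per-cell seeds are derived from (base seed, cell
indices, replicate index) so results are independent of execution order.
`extract_ridge` returns, per column, the row maximizing the three-strain
fraction (plateau ties resolve to the plateau midpoint; all-flat columns
are skipped with a warning; columns with zero three-strain fraction fall
back to the mean level). Ridges are summarized by three fitted laws:
saturation `r_C = (a + b·r_R)/(c + r_R)` (nonlinear least squares), linear
`g_R = a + b·g_C` (ordinary least squares) and power `r_C = A·λ^(−p)`
(least squares in log–log coordinates; only the exponent is treated as an
acceptance quantity, the amplitude carries the arbitrary length unit).

The frozen study grids are: r_R ∈ [0.25, 4] × r_C ∈ [0.03, 0.8] (8×9,
geometric) for the saturation diagram; g_C ∈ [0.25, 1.05] × g_R ∈
[0.25, 1.25] (7×9, linear) at ratios 1:1:0.1 for the linear diagram; and
λ ∈ [60, 240] µm × r_C ∈ [0.03, 1] (7×9, geometric) for the power diagram.
Acceptance-scale sweeps use 30 replicates per cell (16 in the test suite);
these sizes keep a full acceptance run under ~10 min on one CPU while the
per-cell standard error of the three-strain fraction stays below ~0.1.

## Calibration

* **Growth.** `radial_velocity` is the largest sliding-window (default 5
  points) least-squares slope of a radius-vs-time curve.
  `calibrate_strain` fits (hop rate, lag mean, lag sd) by Nelder–Mead on
  the mean squared radius error between the input curves and forward
  single-colony simulations (6 replicates per evaluation, common random
  numbers, so the objective is deterministic); it is initialized from the
  curve's tail slope and intercept. On curves generated by the forward
  model itself it recovers the hop rate to ~1 % and the lag mean to ~0.2 h.
  The mean-squared-error loss is this package's choice; the original
  calibration's exact loss is unpublished.
* **Toxin.** `calibrate_toxin` matches the final front-to-front gap of
  forward two-droplet (C vs S) simulations to observed gaps. A final gap
  constrains κ and λ only jointly (approximately through the effective halo
  width), so the default fit holds κ at its configured value and fits λ by
  a coarse log-grid scan plus local refinement (the gap-vs-λ curve has a
  flat-zero onset that defeats naive unimodal search); a joint
  Nelder–Mead fit is available behind `fit_kappa=True` and warns about the
  ridge. With the default geometry, λ = 125 µm is recovered to ~6 %.
  All-zero gaps yield κ = 0 with a degeneracy flag.

## Synthetic data

The generator emulates (a) radial growth curves with a lag / quadratic-
acceleration / linear shape (the quadratic ramp is the simplest C¹ choice;
the published acceleration-phase shape is in supplementary material we do
not reproduce) plus additive i.i.d. Gaussian radius noise and one
truncated-Gaussian lag draw per curve; (b) collision observations produced
by the forward two-droplet model itself; (c) noisy points on the law
curves. It does not emulate fluorescence intensities, images, liquid-
culture growth, or nutrient depletion. Passing calibration tests therefore
demonstrate internal consistency (parameter recovery against the forward
model), not fidelity to any particular laboratory dataset.

## Numerical choices

Inclusive inhibition boundary (concentration exactly at threshold
inhibits; measure-zero effect). Propensity drift from incremental updates
is rebuilt every 8192 events. Per-run reproducibility: one seeded
generator for seeding and one for the event loop, both derived from the
user seed. Law fitting uses analytic least squares where possible and
`scipy.optimize.curve_fit` for the saturation form (tolerance well below
1e-8 on noiseless model-class data). Degenerate inputs (all-equal x,
non-positive values for the log–log fit, insufficient points) raise with
diagnostics rather than returning silently bad fits.

## Known limitations

* **Overall coexistence is higher than the published simulations.** The
  package reproduces every qualitative result: {C,R} at equal ratios in
  the cyclic scenario with S driven extinct; R dominance in the
  hierarchical scenarios; the rescue window at reduced r_C with its
  maximum in the 5–20 % range; the null-model triad (neutral coexistence,
  destroyed by toxin at equal ratios, restored at reduced r_C); the
  saturating rise of optimal r_C with r_R; the power-law fall of optimal
  r_C with λ (exponent ≈ 1.9); and the ~50 µm optimal toxin range at equal
  ratios. Quantitatively, however, its three-strain fraction at
  S:R:C = 1:1:0.1 is ≈ 0.4–0.5 versus the published 24 %, and its
  coexistence window sits at 2–4× larger r_C across the saturation
  diagram. The discrepancy traces to the strength of stochastic sector
  extinction (genetic drift at the front), which is controlled by
  unpublished supplementary parameters (exact patch size, lag breadth,
  propensity normalization). Exploration across patch sizes of 25–50 µm
  and halo-consistent κ values moved individual statistics onto the
  published numbers but never all of them at once; the shipped defaults
  favour the physically anchored choices (25 µm patches; 250 µm
  single-source halo) over tuning to any one statistic.
* The g_R-vs-g_C ridge is broad and nearly flat at feasible replicate
  counts, so linear-law coefficients are noisy between runs.
* A slow strain competing without toxin (mCherry-S in scenario II at low
  r_C) loses sectors more slowly than geometric-optics boundary arguments
  predict — front roughness and lattice anisotropy weaken lateral closure
  — so scenario II at 1:1:0.1 typically retains S alongside R within the
  3 mm horizon instead of fixing R alone.
* Single bacterial layer only; no vertical structure, nutrient fields,
  colicin absorption or cell-scale mechanics. No long-term fixation-time
  analysis: survival is assessed at the 3 mm stop radius, a transient
  horizon comparable to the 48 h experiments.
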