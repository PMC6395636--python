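# Model and methods

`phagelattice` is a stochastic individual-based model of bacteria and
bacteriophages on a two-dimensional square lattice with Moore neighborhoods,
built to study how environmental structure (liquid culture vs biofilm-like
growth) shapes phage predation, combined phage + antibiotic treatment,
resistance evolution, and the invasion of sensitive communities by lysogens.
This note documents the model, its assumptions, the parameters that matter,
and the numerical and design choices that were genuinely open.

## Entities and state

Each lattice location holds at most one bacterial cell and at most
`phage_cap_per_location` free virions.  A bacterium is its species reference
plus phenotype state: an antibiotic-resistance flag, the set of phage
attachment phenotypes it resists, and the list of prophages it carries.
Genomes are represented only through these phenotype fields — explicit gene
content plays no role in the modelled dynamics.  A free virion is a species
reference, an attachment phenotype, and its age outside a host; ages within a
(location, species, phenotype) bucket are exchangeable under every dynamic
rule, so the free pool is stored in aggregated buckets with a per-location
count grid, and per-virion objects are materialized only at the
encounter level.  The interaction structure of a community is two matrices:
`host_range[phenotype, species]`, the probability that a phage with a given
attachment phenotype can infect a given species (also the adsorption scale),
and `superinfection_exclusion[incoming, resident]`, the probability that an
infection aborts when a given resident prophage is present.

## Environmental structure

Three modes span the liquid-to-biofilm axis:

- **well_mixed** — the contents of every location are randomized at each
  iteration (bacteria to a fresh random injection, virions uniformly subject
  to the cap); reproduction then competes over the Moore-1 neighborhood of
  each free site, which after mixing is equivalent to global competition.
- **semi_structured** — cells are fixed; offspring may be placed within
  `reproduction_radius` (default Moore distance 3) and virions diffuse within
  `phage_diffusion_radius`.
- **structured** — cells are fixed, offspring are placed at Moore distance 1,
  and free virions do not diffuse at all: phage spread only through the
  Moore-1 dispersal of burst offspring, so predation advances as a wave
  through contiguous hosts and strands wherever hosts are missing.  This
  follows the description of structured environments as having no mixing or
  diffusion, with phages propagating by infecting nearby bacteria.

The grid is bounded by default (toroidal is available and used by the
mass-conservation tests).  Figure-scale scenarios use 100x100 grids; all
packaged presets are desk-scaled to 50x50.

## The iteration cycle

One iteration applies, in fixed order: (1) antibiotic deployment if
scheduled, then field diffusion/degradation; (2) mixing (well-mixed) or phage
diffusion; (3) free-phage decay; (4) the infection pass; (5) prophage
induction; (6) lysis resolution (deaths, bursts, local dispersal);
(7) basal + antibiotic mortality; (8) reproduction into free space;
(9) trajectory recording.  The order is a declared convention — the key
commitment is that killing precedes reproduction, so space freed in an
iteration can be colonized within the same iteration (free space is the
limiting resource).  An iteration is the time quantum; no conversion to
wall-clock hours is attempted, and a bacterial generation is an emergent
consequence of the birth-death process rather than a parameter.

**Reproduction.**  Free locations are visited in uniformly random order.  The
live cells within the reproduction radius that have not yet divided this
iteration compete through a fitness-proportionate roulette wheel; the winner
places one (possibly mutated) offspring in the free site.  Reproduction is
asynchronous: an offspring placed earlier in the pass may itself parent a
later fill.  Each individual divides at most once per iteration — without
this cap a single survivor could repopulate an arbitrarily large emptied
region in one pass, which makes antibiotic-driven extinction impossible and
distorts every treatment scenario.  Even with the cap, an isolated cell's
fill chain can produce more than a doubling per iteration at very low
density; antibiotic kill probabilities were chosen with that in mind (below).

**Fitness.**  `base_growth_rate x (1 - cost_ab)^[antibiotic resistant] x
(1 - cost_phage)^(#resisted phenotypes)`.  Costs compose multiplicatively, so
fitness is nonnegative and independent of acquisition order.  If every
candidate has zero fitness the roulette falls back to a uniform choice.

**Mutation.**  Mutation is applied once per reproduction event: with
probability `mu_antibiotic` a sensitive offspring gains antibiotic
resistance; with probability `mu_phage_receptor` it gains resistance to one
uniformly chosen attachment phenotype it does not already resist.  Phage
mutate at burst: each offspring virion switches to a uniformly chosen
different attachment phenotype with probability `mu_attachment`.

## Infection

Every free virion co-located with a cell attempts infection, locations and
within-location order randomized, through sequential gates: (1) a host
resisting the phenotype blocks the virion (it stays free); (2) adsorption
succeeds with `host_range x adsorption_prob` (a failed draw leaves the virion
free; defective phages never adsorb); (3) each resident prophage
independently aborts the infection with its superinfection-exclusion
probability; (4) virulent phages initiate lysis; temperate phages lysogenize
with probability given by their decision curve, else initiate lysis.  All
adsorbed virions are consumed regardless of the step-3/4 outcome.  Once a
host is committed to lysis, later adsorptions join the doomed cell without
further effect; a host lysogenized earlier in the pass immediately applies
superinfection exclusion to later virions.

**Lysis-lysogeny decision.**  The lysogenization probability is a Hill
function of the local free-virion count `n` (focal location plus Moore-1
neighborhood, snapshotted per location before its encounters are resolved):

```
p(n) = p_max * n^h / (n^h + K^h)
```

Three presets share `p_max = 0.9`, `h = 2` and differ in the half-density
`K`: Lysogeny1 (K=5) and Lysogeny2 (K=15) already give a 1-10% lysogenization
chance at low local counts, while Lysogeny3 (K=150) requires very high local
densities.  The functional form and constants are package choices — the
motivating observations are that high local phage density / multiplicity of
infection favors lysogeny, and that community outcomes are driven by the
density at which lysogenization first becomes non-negligible.

**Lysis and burst.**  The host dies, freeing its location; `burst_size`
offspring virions (each drawing its attachment phenotype through the phage
mutation rule) are scattered uniformly over the host location and its Moore
neighborhood at radius `max(1, phage_diffusion_radius)`, honoring the
per-location cap (over-cap offspring search outward ring by ring; anything
truly unplaceable is counted in the `burst_capacity_lost` tally so the
virion audit stays exact).  There is no explicit eclipse/latency period:
infections resolved as lysis release their burst in the same iteration.

**Induction.**  Each prophage independently switches to the lytic cycle with
probability `induction_prob` per iteration, multiplied by
`stress_induction_factor` when the local antibiotic concentration is at or
above the MIC threshold (a threshold rather than a dose-response curve —
the simplest reading of stress-dependent induction).

**Decay.**  Free virions age each iteration and are removed with a constant
per-iteration hazard `decay_prob`, i.e. a geometric lifetime with half-life
`log 2 / -log(1 - decay_prob)`.  Ages are tracked so an age-dependent hazard
could be added without changing the pool layout.

## Antibiotics and mortality

The antibiotic field is a nonnegative concentration per location.  One dose
either sets every location to `dose` (homogeneous) or sets `n_foci` random
locations to `dose` (heterogeneous), after which the field evolves by a
discrete 8-neighbor kernel — each location keeps `1 - diffusion_fraction` of
its concentration and shares the rest equally among its Moore-1 neighbors
(on bounded grids the undistributable share stays in place, so diffusion
conserves mass exactly) — followed by first-order degradation.  Mortality
per iteration: every cell dies with the basal probability (composed with any
species-intrinsic hazard); antibiotic-sensitive cells at locations at or
above `mic_threshold` additionally die with `antibiotic_kill_prob`.

## Parameters and defaults

| parameter | default | units / meaning |
| --- | --- | --- |
| grid | 100x100 (presets 50x50), bounded | locations |
| `phage_cap_per_location` | 100 (presets 50) | virions per location |
| `base_growth_rate` | 1.0 | relative fitness |
| resistance costs | 0.1 per resistance | fitness fraction |
| `basal_death_prob` | 0.05 | per cell per iteration |
| `antibiotic_kill_prob` | 0.95 (presets 0.9; evolution preset 0.7) | per iteration above MIC |
| `mic_threshold` | 1.0 | concentration units |
| dose | 10 homogeneous; 200 x 12 foci heterogeneous | concentration units |
| degradation / diffusion | 0.01 / 0.25 | per iteration fractions |
| `burst_size` | 50 | virions per lysis |
| `adsorption_prob` | 0.9 | per encounter |
| `decay_prob` | 0.05 | per iteration (half-life ~13.5 iterations) |
| `induction_prob` | 1e-3 (invasion presets 1e-2) | per prophage per iteration |
| `stress_induction_factor` | 10 | multiplier above MIC |
| mutation rates | 1e-4 or 1e-3 per reproduction event | scenario captions |

Two defaults deserve their rationale.  *Antibiotic kill.*  At 0.95 the
sensitive population dies within ~3 iterations of exposure, which silences
the competition-release effect (sensitive cells persisting by reproducing
into space their phage-killed competitors vacated) that distinguishes
well-mixed from structured combined treatments; the two-species presets use
0.9, where reproduction during the decline matters and both extinctions still
complete within the run.  The single-species evolution preset uses 0.7 so the
sensitive population declines over several iterations while still supplying
resistance mutations — at harsher kills the mutation supply is extinguished
before the environmental treatments can differentiate.  *Induction.*  The
invasion presets raise `induction_prob` to 1e-2: with 40-fold fewer lysogens
than at figure scale, the desk-scale virion supply would otherwise be too
sparse for the invasion to progress by the response iteration (15).

## Scenario presets

Seven presets encode the canonical setups at 50x50: two-species communities
under antibiotic, virulent phage (10 particles co-inoculated at time 0), or
both; single-species resistance evolution under both stressors (mutation
rates 1e-4 by default, antibiotics at iteration 5); bacteria-phage
coevolution (receptor resistance at 1e-3 per reproduction, phage attachment
mutation ten-fold lower at 1e-4); and lysogen invasion at a 1:10
invader:resident ratio with full superinfection exclusion, in well-mixed and
fully structured variants.  `scenario(name, overrides)` applies overrides
last, so every preset scales up (e.g. 100x100, 30 replicates) or re-
parameterizes from the command line.

## Statistics and the sensitivity harness

- **Ensembles** run n seeded replicates (seeds derived from one master seed
  via `numpy` seed sequences, kept below 2^31) and report per-iteration means
  with normal-approximation 95% bands (width 0 for a single replicate).
- **Emergence time** is the first iteration a genotype/class count reaches a
  threshold (default 100 individuals); the **coefficient of variation** of
  emergence times is computed over detected replicates only, with the
  detection count reported alongside.
- **Emergence contingency** is the Yates-corrected chi-squared test on a 2x2
  detections table, with the convention that identical proportions (including
  degenerate zero margins) give statistic 0, p 1.
- **Population-level adsorption** is estimated from an adsorption-assay-like
  decline window: the log free-virion count, corrected for the known decay
  hazard, is regressed on cumulative host exposure; minus the slope is the
  per-host per-iteration rate.  The estimator requires at least 3 positive
  points in the window (default iterations 0-5) and refuses otherwise.  It
  presumes virion production is negligible in the window (use burst 0 or a
  pre-burst window); bursts inside the window bias the rate downward.
- **Early-lysogenization comparison** fits a degree-2 polynomial to the
  lysogenized-resident counts over the first 10 iterations in each
  environment and tests equality of the linear trend.  The test is
  covariance-adjusted at the replicate level: one trend coefficient per
  replicate trajectory, compared across environments with a Welch t-test.
  Points within a trajectory are strongly autocorrelated, so pooling them
  into a single regression with an interaction term badly overstates the
  evidence (6/20 false rejections at alpha = 0.05 under an identical-
  ensembles null, vs <= 1/20 for the replicate-level test).
- **The sensitivity harness** samples random parameter combinations (uniform
  intervals, integer ranges, or finite choices; categorical values are
  integer-coded in the table), appends a dummy parameter uniform on {1,2,3},
  runs seeded replicate invasions per combination, and takes the mean
  lysogenized-resident count at iteration 15 as the response.  A bagged
  ensemble of regression trees (each split drawing from a third of the
  features) is fitted to the table, and each parameter's importance is the
  percentage increase in out-of-bag MSE when its column is permuted
  (%IncMSE).  The dummy's importance is the noise floor: parameters at or
  below it are flagged non-important.  Full-scale analyses use 3000
  combinations x 30 repeats and 10,000 trees; the packaged tests run
  desk-scale tables (~100-150 rows, a few hundred trees), which is enough to
  separate a planted driver from the floor but not to estimate stable
  absolute %IncMSE values.

## What the desk-scale presets do and do not show

The presets reproduce mechanisms, not magnitudes.  At 50x50 with burst 50
and adsorption 0.9, well-mixed phage epidemics consume a sensitive
population within ~4 iterations — far more compressed than at figure scale —
and stochastic effects (lineage loss, wave stranding) are stronger.  The
packaged checks therefore assert directions and orderings: structured
environments delay phage-driven extinction and accelerate the
antibiotic-sensitive species' extinction under combined treatment; double
resistance emerges most often under structured + heterogeneous antibiotics
and least often well-mixed; the high-density lysogeny curve produces the
fewest new lysogens; early lysogenization of residents is slower under
structure (after a 1-2 iteration transient in which locally concentrated
virions lysogenize their immediate neighbors faster than mixing allows).
Absolute iteration counts, population sizes, and %IncMSE values are not
comparable to figure scale.  The stochastic orderings hold with clear
margins at 20+ replicates, but individual quantities (especially the
double-resistance fractions, whose per-replicate event counts are of order
one) remain noisy.

## Numerical and bookkeeping choices

- One `numpy` Generator per run, consumed in fixed phase order with all
  collections iterated in sorted order, makes `(config, seed) -> trajectory`
  a pure function (bitwise-identical reruns).
- Capacity handling never silently destroys virions: diffusion redraws
  over-cap moves near their origins, well-mixed redistribution reassigns
  over-cap virions to remaining capacity, and burst overflow is tallied.
  The per-iteration audit `Δbacteria = births - deaths` and
  `Δvirions = bursts - adsorptions - decays - capacity losses` holds exactly
  and is asserted in the tests.
- Occupancy and capacity invariants can be asserted after every phase
  (`check_invariants=True`; used throughout the tests).
- Antibiotic diffusion is mass-conserving to machine precision (asserted at
  1e-12 relative tolerance on toroidal grids).
- Degenerate inputs are defined, not accidental: radius-0 diffusion and
  structured mixing are identities; an all-zero-fitness roulette is uniform;
  a zero-iteration run records only the initial state; a constant response
  makes all importances 0 with a warning.

## Known limitations

Bacterial physiology (growth-state- or receptor-expression-dependent
infection), explicit intracellular phage kinetics, eclipse periods,
CRISPR/restriction defenses, gene-level genomes, and temporal or spatial
variation of the environmental structure itself are not modelled.  The
lysogeny-curve constants and the per-figure antibiotic parameters are
declared package choices.  Compatibility with any external input-file format
is not claimed; the two text-file grammars are this package's own.
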