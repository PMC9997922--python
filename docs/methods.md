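# Methods

This note documents the model implemented by `hexevo`, its parameter
defaults, the reasoning behind the genuinely open design choices, and the
limits of what the test suite demonstrates.

## Landscape and epochs

The landscape is a fixed set of 3152 flat-top hexagonal habitat cells in six
patches (1326/1326/200/200/50/50), built from `columns × rows` rectangles in
odd-q offset coordinates and surrounded by impassable matrix. The two large
patches adjoin along a shared interface at the landscape center; each medium
and small patch abuts one large patch only, giving five patch interfaces.
Patch geometry, adjacency, and cell counts are exact and tested.

Connectivity is a property of *edges*, not cells: every ordered cell pair at
hex distance 1 carries a transmission probability. Intra-patch edges are
always 1; edges into matrix are always 0 (reflective, individuals never
enter matrix); inter-patch edges depend on the epoch:

| epoch | inter-patch edges | habitat types | selection |
|---|---|---|---|
| continuous (steps 1–1000) | 1.0 | none | off |
| isolated (1001–2000) | 0.0 | none | off |
| semi-connected (2001–3000) | gaps 0.70 or 0.02, else 0 | none | off |
| semi-connected + selection (3001–4000) | as above | A/B per patch | S = 0.10 or 0.01 |

Epoch transitions happen at the start of the boundary step, and the epoch
schedule is fully configurable (the scaled-down runs used by the tests and
the acceptance script schedule single epochs directly).

**Barrier gaps (calibrated).** Each interface carries a contiguous run of
G gap edges centered on the interface midpoint, so total gap size is
identical across interfaces. G is not derivable from first principles; it is
a free geometric parameter whose only observable consequence is the
magnitude of inter-patch migration. We calibrated **G = 2** against the
observed migration regimes the model is meant to reproduce: with G = 2 the
long-dispersal/high-permeability treatment delivers > 15 migrants per
generation (enough gene flow to restore panmixia within an epoch) and the
long-dispersal/low-permeability treatment stays below one migrant per
generation; G = 1 fails the first regime (≈ 13) and G = 3 the second
(≈ 1.2). Short-dispersal treatments come out ≈ 2× above the corresponding
long-dispersal-implied scale at any G (see Limitations).

**Habitat types.** In the selection epoch, patches 1/4/6 are type A and
patches 2/3/5 are type B, so every patch adjoins at least one patch of the
opposite type and local selection always competes with immigration of the
opposite allele.

## Life cycle

Each time step is one year and runs, in order: resource acquisition, pair
formation, reproduction, juvenile dispersal, survival of everyone, then age
increment and juvenile→adult promotion.

**Resources.** Each habitat cell produces 1 unit per year, shared equally
among all individuals whose reachable 37-cell neighborhoods (hex radius 3,
clipped by zero-permeability edges) contain it. An individual's intake
divided by the resource goal, clipped to [0, 1], is its resource fraction
*f* for the year. At the saturation density of one adult per cell an
interior individual acquires ≈ 1 unit.

**Pairing.** Monogamous within a year: a female pairs with the nearest
unpaired adult male reachable within hex radius 3, ties broken by smallest
male id. Females claim males in a freshly drawn random order each step
(seeded, hence reproducible). The order matters: processing females in id
order would hand older females priority in mate competition and bias the
mean age of reproducing females upward by ≈ 0.6 years; breeding is meant to
be age-independent.

**Reproduction.** A paired female bears `max(0, round(N(F·f, σ)))`
offspring; offspring sex is 50/50, the genotype takes one uniformly chosen
allele per parent per locus (free recombination, no mutation), and the natal
patch is the mother's. Parents that produce ≥ 1 offspring for the first time
have their first-breeding step and patch recorded — the basis of the migrant
definition.

**Dispersal.** Newborns take a correlated random walk of L steps, L uniform
on {1..5} (short) or {5..25} (long). The previous heading is kept with
probability a/100 (a = 75), otherwise redrawn uniformly from all six
directions; the first heading is uniform. A proposed move across an edge
with permeability p succeeds with probability p per encounter; on failure
the step is spent at the barrier (the walker does not move) and the heading
is redrawn uniformly among currently passable edges. A successful crossing
of an edge with 0 < p < 1 sets the individual's permanent gap-crossing
flag. A walker on a cell with no passable edge stays put. Adults never
move.

**Survival.** Base survival is 0.500 (juvenile) / 0.885 (adult); individuals
with *f* < 0.20 suffer an additional 0.10 mortality (floored at 0); newborns
have not competed for resources in their birth year and carry *f* = 1.
During the selection epoch a juvenile gains +S per allele copy (loci 6–10)
matching its current cell's habitat type, capped at 1. Survival draws are
independent Bernoulli trials.

## Demographic calibration

The survival schedule, the 20 % penalty threshold, the reproduction
distribution family, and the dispersal parameters are fixed model constants.
Three quantities are not: the resource goal, the fecundity mean F, and the
fecundity SD σ. They were set analytically, before any simulation, from two
conditions the model is required to satisfy at stationarity:

1. **Equilibrium near saturation.** The population starts saturated (one
   adult per cell) and should equilibrate near that density.
2. **Generation time 8.7 years.** With age-independent breeding, the mean
   age of reproducing females equals 1/(1 − s_adult) = 8.7 *only if* adults
   rarely fall below the resource-penalty threshold, i.e. the equilibrium
   resource fraction must sit comfortably above 0.20.

The stationarity balance is 0.5 · p_pair · E[b] · s_juv = 1 − s_adult, where
E[b] is the mean of the rounded, zero-truncated normal. Zero-truncation
inflates E[b] substantially at small means (for μ = 0.22, σ = 1:
E[b] ≈ 0.5), which forces the equilibrium mean μ* = F · f* to ≈ 0.22. A
large F therefore pins f* = μ*/F at or below the 0.20 penalty threshold,
violating condition 2 and pushing the equilibrium density far above
saturation (violating condition 1). **F = 0.8, σ = 1.0, resource goal =
3.7** (10 % of a full neighborhood's production) give f* ≈ 0.27 > 0.20 and
equilibrium density ≈ 1 adult/cell. Measured outcomes: equilibrium census
≈ 2800–2900 of 3152 cells, resource fractions almost never below 0.2,
generation time 8.6–8.7 years, ≈ 115–117 generations per 1000-step epoch.
All three constants are exposed in the configuration.

## Genetics

Diploid, 10 unlinked loci, alleles coded 1–5, stored as canonical sorted
pairs (phase is never distinguished). Initial genotypes are drawn i.i.d.
from the per-locus frequency profiles with no spatial stratification. There
is deliberately no mutation operator anywhere in the code path, so per-locus
allele sets are non-increasing within any closed population — a tested
invariant. The adaptive map: locus 6 allele 2 → A and allele 4 → B; locus 7
allele 5 → A; locus 8 allele 5 → B; locus 9 allele 1 → A; locus 10 allele
1 → B. Adaptive allele initial frequencies span 0.01–0.50, so selection acts
on both rare and common variants.

## Observables

* **Generation time**: mean maternal age over all births in a window,
  excluding a 100-step burn-in after initialization (the founding cohort is
  all age 1; its trace decays as 0.885^t).
* **Migrants per generation**: individuals whose gap-crossing flag is set
  and whose *first* breeding patch differs from their natal patch, counted
  by first-breeding step within the window, divided by window length over
  the window's own measured generation time. Non-breeders and gap-crossers
  that return home to breed are excluded. Emigration/immigration rates are
  stratified by sending/receiving patch.
* **Diversity**: per-capita homozygosity (fraction of homozygous loci
  averaged over individuals), allelic richness (extant alleles per locus),
  allelic evenness −Σ pᵢ ln pᵢ / ln 5 over extant alleles (1 = five equal
  alleles, 0 = fixation), heterozygosity deficit H_obs − H_exp with
  H_exp = 1 − Σ qᵢ² over extant alleles (a shifting baseline as alleles are
  lost). The evenness of the rare profile (0.01, 0.04, 0.15, 0.30, 0.50) is
  0.7252 exactly.
* **Genetic distance**: fraction of loci at which two individuals'
  unordered allele pairs differ; cross-checked in the tests against
  `ape::dist.gene(method = "percentage")` on canonical locus strings.
* **IBD correlograms**: pairwise hex distances cut into equal-width classes;
  per class, mean genetic distance and pair count (reported so spatial
  clumping can be diagnosed); random pair subsampling above 10⁵ pairs.
* **STRUCTURE export**: 25 individuals per patch, resampled with replacement
  when a patch holds fewer, integer alleles, one row per individual with two
  columns per locus (two-row dialect by flag), missing code −9.

## Numerical and reproducibility choices

One `numpy.random.Generator` per replicate drives every stochastic decision
in a fixed documented order; population arrays keep stable id order, so a
(configuration, seed) pair reproduces logs bit-for-bit. Experiment seeds
derive from (base seed, treatment index, replicate index) via
`SeedSequence`. Resource allocation is exact (sparse neighborhood sums, no
sampling). Pairing ties are broken by id. Event logs accumulate as arrays
and serialize to tidy CSVs; genotype snapshots default to each epoch's last
step.

## Problem sizes in tests and the acceptance script

Emergent-quantity checks run the full 3152-cell landscape with single-epoch
schedules: 400 steps (100 burn-in + 300 window) for generation time; 600
steps (100 + 500) per replicate for migration, 3 replicates per treatment in
the acceptance script and 4 in the test suite; the 1000-step continuous
endpoint for IBD; 100 + 250 steps for the isolation/homozygosity contrast;
150 + 250 steps for the selection response. Process-level tests use a scaled
six-patch landscape (258 cells) with the same adjacency plan.

## What the synthetic scenario does and does not show

The scenario is deliberately minimal: uniform habitat quality, binary
habitat/matrix structure, a single species, no mutation, no linkage, no
pedigree tracking, no sex-biased or condition-dependent dispersal, no
environmental stochasticity. Passing tests demonstrate that the simulator's
emergent demography and genetics behave as the model analysis predicts
(drift faster in small patches, gene flow monotone in permeability and
dispersal distance, selection raising effective carrying capacity, IBD under
short dispersal) — not that any real landscape or species behaves this way.
Real applications would need species-specific demographic rates, empirical
landscape maps, and validation data.

## Known limitations

* **Migration magnitudes are geometry-limited.** With gap width calibrated
  to the long-dispersal regimes (G = 2), the short-dispersal migration rates
  are ≈ 2× above the scale the long-dispersal treatments imply. The
  short:long ratio is set by the correlated-random-walk semantics (how a
  failed crossing consumes movement effort, how headings reset at barriers),
  for which several defensible conventions exist; ours spends the step at
  the barrier and redirects. Orderings (long > short, high > low) and both
  long-dispersal regimes are insensitive to this choice.
* **Weak residual IBD under long dispersal.** Long-dispersal IBD slopes at
  the continuous-epoch endpoint are ≈ 7× smaller than short-dispersal slopes
  but slightly positive (the landscape is only ≈ 5 long-dispersal standard
  deviations wide), so an over-powered permutation test can detect them;
  correlogram-level structure is absent.
* The resource penalty applies to any individual below 20 % of goal,
  juveniles and adults alike; newborns are exempt in their birth year.
* Whether a failed gap crossing should consume path length is unspecified in
  the model description; we consume it.
* Small-patch populations (≈ 45 adults) can drift to extinction during long
  isolation; downstream metrics treat extinct patches as missing strata.
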