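# hexevo

A forward-time, spatially explicit, individual-based simulator of
eco-evolutionary dynamics on a dynamic hexagonal landscape.

`hexevo` is aimed at landscape geneticists, population geneticists,
conservation biologists, and evolutionary ecologists who want demographic and
genetic responses — gene flow, drift, inbreeding, local adaptation,
extinction risk — to *emerge* from explicit species–landscape interactions
instead of being supplied as input parameters. Quantities that classical
models treat as givens (the migration rate *m*, the generation time *T*) are
here measured from simulation output.

## The model

**Landscape.** Six habitat patches (two large, 26 × 51 = 1326 hexagons each;
two medium, 10 × 20 = 200; two small, 5 × 10 = 50; 3152 cells in all) are
embedded in an impassable matrix. The medium and small patches abut the large
patches but not each other. Landscape structure changes across four epochs of
1000 yearly time steps: **continuous** (free movement), **isolated** (absolute
barriers on every patch interface), **semi-connected** (small barrier gaps
with per-encounter transmission probability 0.70 or 0.02; total gap size
identical on every interface), and **semi-connected with local selection**
(patches additionally carry one of two habitat types, A or B).

**Life cycle.** Each step runs (a) resource acquisition — every cell yields
one resource unit, shared equally by all individuals whose 37-cell reachable
neighborhoods cover it (scramble competition); (b) exclusive pair formation
(monogamous, nearest reachable male); (c) reproduction — each paired female
bears `max(0, round(N(F·f, σ)))` offspring, where *f* ∈ [0, 1] is her
resource fraction, F = 0.8 and σ = 1.0; (d) juvenile dispersal — a
correlated random walk of 1–5 (short) or 5–25 (long) hexagon steps with
heading persistence 0.75, where crossing a gap edge succeeds with probability
equal to its permeability per encounter; (e) survival — juveniles 0.500,
adults 0.885, −0.10 below 20 % of the resource goal, and during the selection
epoch juveniles gain +S per locally adaptive allele copy (S = 0.10 or 0.01),
capped at 1. Adults never move; juveniles become adults the next year, so
generations overlap.

**Genetics.** Individuals are diploid at 10 unlinked loci with 5 alleles
each, initialized from per-locus frequency profiles (equal, unequal, or rare)
without spatial structure. Loci 1–5 are neutral; loci 6–10 carry alleles
adaptive in habitat A or B (locus 6 carries one of each). There is no
mutation: diversity can only be lost, or locally rescued by migration.

**Observables.** Per-patch census and allele counts every step; births with
maternal age (generation time *T* = mean age of reproducing females,
≈ 1/(1 − 0.885) = 8.7 years); dispersal paths with gap-crossing flags
(a *migrant* crossed a gap and first bred outside its natal patch; migrants
per generation = migrants / (window/T)); per-capita homozygosity; allelic
richness; allelic evenness E = −Σ pᵢ ln pᵢ / ln 5; heterozygosity deficit
H_obs − H_exp with H_exp = 1 − Σ qᵢ² over extant alleles; pairwise genetic
distance (fraction of loci whose unordered allele pairs differ) and binned
isolation-by-distance correlograms; STRUCTURE-format export with 25-per-patch
resampling.

## Worked example

```python
from hexevo import SimConfig, run_replicate, generation_time, migration_summary
from hexevo.hexgrid import EpochSpec, EpochName, BarrierMode

epochs = [
    EpochSpec(EpochName.CONTINUOUS, 1, 200),
    EpochSpec(EpochName.SEMI_CONNECTED, 201, 500, BarrierMode.GAPPED, 0.70),
]
cfg = SimConfig(epochs=epochs, horizon=500, snapshot_steps=(500,))
log = run_replicate(cfg, seed=1)

gt = generation_time(log, (101, 500))
mig = migration_summary(log, (201, 500))
final = log.census_df().query("step == 500").set_index("patch")["count"]
print(f"generation time (mean maternal age): {gt:.2f} years")
print(f"migrants per generation (semi-connected window): {mig.migrants_per_generation:.2f}")
print("final census by patch:", dict(final))
```

prints

```
generation time (mean maternal age): 8.65 years
migrants per generation (semi-connected window): 5.85
final census by patch: {1: 1192, 2: 1035, 3: 115, 4: 109, 5: 21, 6: 24}
```

The generation time is not an input: it emerges from the stage-structured
survival schedule and age-independent breeding, close to the analytic
1/(1 − 0.885) = 8.7. The migration rate emerges from the interplay of
dispersal behavior, gap permeability, and patch geometry (here the default
short-dispersal behavior with highly permeable gaps). The census shows each
patch near its emergent carrying capacity, roughly one adult per habitat
cell.

A command-line interface mirrors the library: `hexevo run`,
`hexevo experiment` (the 2 × 2 × 2 factorial of dispersal × selection ×
permeability, 10 replicates each), `hexevo metrics`, and
`hexevo export-structure`. Scenario files are plain YAML; an empty file means
the default scenario above.

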