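"""Observable responses: diversity, genetic distance, IBD, migration, generation time.

All metrics operate on genotype arrays of shape (n, n_loci, 2) in canonical
sorted-pair form (as produced by the simulator) and/or on an
:class:`~hexevo.engine.EventLog`.  Per-locus quantities follow the standard
definitions: allelic richness is the count of extant alleles; allelic
evenness is the Shannon entropy of extant allele frequencies normalized by
ln(5), the maximum for five alleles; the heterozygosity deficit is
H_obs - H_exp with H_exp = 1 - sum(q_i^2) over extant alleles (a shifting
baseline as alleles are lost); pairwise genetic distance between two
individuals is the fraction of loci at which their unordered allele pairs
are not identical.

A migrant is an individual that crossed a barrier gap during natal dispersal
and whose first reproduction happened outside its natal patch; non-breeders
and temporary excursions that return home do not count.  Generation time is
the mean age of reproducing females over a window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genome
from .engine import EventLog

__all__ = [
    "PatchSample",
    "MigrationSummary",
    "per_capita_homozygosity",
    "allele_frequencies",
    "allelic_richness",
    "allelic_evenness",
    "heterozygosity_deficit",
    "pairwise_genetic_distance",
    "sample_for_distance_matrix",
    "ibd_correlogram",
    "migration_summary",
    "generation_time",
    "population_trajectories",
]


@dataclass
class PatchSample:
    """Genotyped individuals sampled from one patch."""

    patch_id: int
    ids: np.ndarray
    genotypes: np.ndarray  # (n, n_loci, 2)
    coords: np.ndarray | None = None


def _genotypes(sample) -> np.ndarray:
    g = sample.genotypes if isinstance(sample, PatchSample) else np.asarray(sample)
    if g.ndim != 3 or g.shape[2] != 2:
        raise ValueError("expected genotypes of shape (n, n_loci, 2)")
    if g.shape[0] == 0:
        raise ValueError("empty sample")
    return g


def per_capita_homozygosity(sample) -> float:
    """Mean fraction of homozygous loci per individual (= homozygous-locus
    count / (n_loci * n))."""
    g = _genotypes(sample)
    return float(np.mean(g[:, :, 0] == g[:, :, 1]))


def allele_frequencies(sample, locus: int) -> np.ndarray:
    """Frequencies of alleles 1..5 at ``locus`` (1-based); sums to 1."""
    g = _genotypes(sample)
    counts = np.bincount(
        g[:, locus - 1, :].ravel().astype(np.int64) - 1, minlength=genome.N_ALLELES
    )
    return counts / counts.sum()


def allelic_richness(sample, locus: int) -> int:
    """Number of distinct alleles extant at a locus."""
    return int(np.count_nonzero(allele_frequencies(sample, locus)))


def allelic_evenness(freqs) -> float:
    """Normalized Shannon evenness: -sum(p ln p) / ln(5) over extant alleles.

    1.0 for five equally frequent alleles, 0.0 once a single allele remains.
    """
    p = np.asarray(freqs, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must sum to 1")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / math.log(genome.N_ALLELES))


def heterozygosity_deficit(sample, locus: int) -> float:
    """H_obs - H_exp at a locus; near 0 for a large random-mating population."""
    g = _genotypes(sample)
    h_obs = float(np.mean(g[:, locus - 1, 0] != g[:, locus - 1, 1]))
    q = allele_frequencies(sample, locus)
    h_exp = 1.0 - float((q**2).sum())
    return h_obs - h_exp


def _locus_codes(genotypes: np.ndarray) -> np.ndarray:
    g = np.asarray(genotypes, dtype=np.int16)
    lo = np.minimum(g[..., 0], g[..., 1])
    hi = np.maximum(g[..., 0], g[..., 1])
    return lo * (genome.N_ALLELES + 1) + hi  # unique code per unordered pair


def pairwise_genetic_distance(genotypes) -> np.ndarray:
    """Symmetric matrix of per-pair fractions of differing loci.

    A locus "differs" when the unordered allele pairs are not identical, so
    phase never matters: {A1,A2} vs {A2,A1} is a match.
    """
    codes = _locus_codes(np.asarray(genotypes))
    if codes.ndim != 2 or len(codes) < 2:
        raise ValueError("need at least two genotypes")
    d = (codes[:, None, :] != codes[None, :, :]).mean(axis=2)
    return d


def sample_for_distance_matrix(
    log: EventLog,
    step: int | None = None,
    per_patch_n: int = 25,
    rng: np.random.Generator | int | None = None,
):
    """Patch-stratified sample from a genotype snapshot plus its distance matrix.

    Draws ``per_patch_n`` individuals from each extant patch (with
    replacement only when a patch holds fewer); extinct patches are recorded
    as missing strata.  Returns ``(sample, matrix, missing_patches)`` where
    ``sample`` is a dict with ids / patch / coords / genotypes arrays.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if step is None:
        step = max(log.snapshots)
    snap = log.snapshots[step]
    sel: list[np.ndarray] = []
    missing: list[int] = []
    for patch in log.patch_labels:
        pos = np.flatnonzero(snap["patch"] == patch)
        if len(pos) == 0:
            missing.append(patch)
            continue
        chosen = rng.choice(pos, size=per_patch_n, replace=len(pos) < per_patch_n)
        sel.append(np.sort(chosen))
    idx = np.concatenate(sel)
    sample = {
        "step": step,
        "ids": snap["ids"][idx],
        "patch": snap["patch"][idx],
        "coords": snap["coords"][idx],
        "genotypes": snap["genotypes"][idx],
    }
    matrix = pairwise_genetic_distance(sample["genotypes"])
    return sample, matrix, missing


def ibd_correlogram(
    coords: np.ndarray,
    genotypes: np.ndarray,
    n_bins: int = 10,
    max_pairs: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Isolation-by-distance profile: mean genetic distance by geographic bin.

    Inter-individual hex distances are cut into ``n_bins`` equal-width
    classes; each row reports the class bounds, the mean pairwise genetic
    distance, and the pair count (so spatial clumping can be diagnosed).
    Random pair subsampling keeps large populations tractable.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    coords = np.asarray(coords)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least two located individuals")
    n_all = n * (n - 1) // 2
    if n_all <= max_pairs:
        ii, jj = np.triu_indices(n, k=1)
    else:
        ii = rng.integers(0, n, size=max_pairs)
        jj = rng.integers(0, n, size=max_pairs)
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]
    dq = coords[ii, 0] - coords[jj, 0]
    dr = coords[ii, 1] - coords[jj, 1]
    geo = (np.abs(dq) + np.abs(dr) + np.abs(dq + dr)) // 2
    codes = _locus_codes(np.asarray(genotypes))
    gen = (codes[ii] != codes[jj]).mean(axis=1)
    edges = np.linspace(0, geo.max(), n_bins + 1)
    which = np.clip(np.digitize(geo, edges[1:-1], right=True), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = which == b
        rows.append(
            (
                edges[b],
                edges[b + 1],
                float(gen[m].mean()) if m.any() else np.nan,
                int(m.sum()),
            )
        )
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "mean_genetic_distance", "n_pairs"])


@dataclass
class MigrationSummary:
    """Migration over a step window, stratified by patch."""

    window: tuple[int, int]
    per_patch: pd.DataFrame
    n_migrants: int
    generation_time: float
    migrants_per_generation: float


def generation_time(log: EventLog, window: tuple[int, int]) -> float:
    """Mean maternal age over all birth events in [start, end] (inclusive)."""
    births = log.births_df()
    m = (births["step"] >= window[0]) & (births["step"] <= window[1])
    if not m.any():
        raise ValueError("no births in window")
    return float(births.loc[m, "mother_age"].mean())


def migration_summary(
    log: EventLog,
    window: tuple[int, int],
    gen_time: float | None = None,
) -> MigrationSummary:
    """Count migrants among first-time breeders in the window.

    A migrant crossed a barrier gap and first reproduced outside its natal
    patch; gap-crossers that returned home to breed, and non-breeders, are
    excluded.  Migrants per generation divides the migrant count by the
    number of generations spanned (window length / measured generation time).
    """
    breeders = log.breeding_df()
    m = (breeders["step"] >= window[0]) & (breeders["step"] <= window[1])
    breeders = breeders.loc[m]
    if len(breeders) == 0:
        raise ValueError("no breeding events in window")
    if gen_time is None:
        gen_time = generation_time(log, window)
    is_migrant = (breeders["crossed_gap"] == 1) & (
        breeders["patch"] != breeders["natal_patch"]
    )
    n_migrants = int(is_migrant.sum())
    rows = []
    for patch in log.patch_labels:
        natal = breeders["natal_patch"] == patch
        bred_here = breeders["patch"] == patch
        n_natal = int(natal.sum())
        emi = int((natal & is_migrant).sum())
        immi = int((bred_here & is_migrant).sum())
        philo = int((natal & (breeders["patch"] == patch)).sum())
        rows.append(
            {
                "patch": patch,
                "natal_breeders": n_natal,
                "breeders_in_patch": int(bred_here.sum()),
                "emigrants": emi,
                "immigrants": immi,
                "philopatric_fraction": philo / n_natal if n_natal else np.nan,
                "emigration_rate": emi / n_natal if n_natal else np.nan,
                "immigration_rate": immi / int(bred_here.sum())
                if bred_here.any()
                else np.nan,
            }
        )
    n_generations = (window[1] - window[0] + 1) / gen_time
    return MigrationSummary(
        window=window,
        per_patch=pd.DataFrame(rows),
        n_migrants=n_migrants,
        generation_time=float(gen_time),
        migrants_per_generation=n_migrants / n_generations,
    )


def population_trajectories(log: EventLog) -> pd.DataFrame:
    """Tidy per-patch census series with extinction flags."""
    df = log.census_df().copy()
    df["extinct"] = df["count"] == 0
    return df
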