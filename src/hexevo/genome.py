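"""Diploid ten-locus genetics: initial sampling, Mendelian inheritance, adaptation.

Individuals are diploid at 10 unlinked loci with 5 possible alleles per locus
(coded 1-5).  Loci 1-5 are strictly neutral; loci 6-10 each carry at least one
allele that confers a juvenile survival benefit in one of two habitat types.
There is no mutation anywhere in the model: the allele set present at any
locus can only shrink over time.

Genotypes are stored as integer arrays of shape (10, 2) — or (n, 10, 2) for a
population — with each locus pair kept in sorted (unordered) canonical form,
since maternal/paternal phase is never distinguished.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hexgrid import HabitatType

__all__ = [
    "N_LOCI",
    "N_ALLELES",
    "LocusSpec",
    "default_locus_table",
    "adaptation_match_table",
    "sample_genotype",
    "sample_genotypes",
    "mate_genotypes",
    "mate_population",
    "count_adaptive_alleles",
    "count_adaptive_alleles_array",
    "genotype_homozygosity",
]

N_LOCI = 10
N_ALLELES = 5


@dataclass(frozen=True)
class LocusSpec:
    """Initial allele frequencies and adaptation map for one locus.

    ``adaptation_map`` maps allele id (1-5) to the habitat type in which the
    allele is locally adaptive; alleles absent from the map are neutral.
    """

    locus_id: int
    initial_freqs: tuple[float, ...]
    adaptation_map: dict[int, HabitatType] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.initial_freqs) != N_ALLELES:
            raise ValueError(f"locus {self.locus_id}: need {N_ALLELES} frequencies")
        if any(f < 0 for f in self.initial_freqs):
            raise ValueError(f"locus {self.locus_id}: negative frequency")
        if abs(sum(self.initial_freqs) - 1.0) > 1e-9:
            raise ValueError(
                f"locus {self.locus_id}: frequencies sum to {sum(self.initial_freqs)}"
            )


_EQUAL = (0.20, 0.20, 0.20, 0.20, 0.20)
_UNEQUAL = (0.30, 0.25, 0.20, 0.15, 0.10)
_UNEQUAL_REV = (0.10, 0.15, 0.20, 0.25, 0.30)
_RARE = (0.01, 0.04, 0.15, 0.30, 0.50)
_RARE_REV = (0.50, 0.30, 0.15, 0.04, 0.01)


def default_locus_table() -> list[LocusSpec]:
    """The shipped 10-locus table: frequencies and the habitat adaptation map.

    Loci 1-5 neutral (equal / unequal / rare frequency profiles and their
    reverses); loci 6-10 carry adaptive alleles: L6 has two (A2 -> habitat A,
    A4 -> habitat B), L7 (A5 -> A), L8 (A5 -> B), L9 (A1 -> A), L10 (A1 -> B).
    """
    A, B = HabitatType.A, HabitatType.B
    return [
        LocusSpec(1, _EQUAL),
        LocusSpec(2, _UNEQUAL),
        LocusSpec(3, _UNEQUAL_REV),
        LocusSpec(4, _RARE),
        LocusSpec(5, _RARE_REV),
        LocusSpec(6, _EQUAL, {2: A, 4: B}),
        LocusSpec(7, _UNEQUAL, {5: A}),
        LocusSpec(8, _UNEQUAL_REV, {5: B}),
        LocusSpec(9, _RARE, {1: A}),
        LocusSpec(10, _RARE_REV, {1: B}),
    ]


def adaptation_match_table(locus_specs: list[LocusSpec]) -> np.ndarray:
    """(n_loci, n_alleles) int8 table of HabitatType codes; 0 = neutral allele."""
    table = np.zeros((len(locus_specs), N_ALLELES), dtype=np.int8)
    for i, spec in enumerate(locus_specs):
        for allele, habitat in spec.adaptation_map.items():
            table[i, allele - 1] = HabitatType(habitat).value
    return table


def _freq_matrix(locus_specs: list[LocusSpec]) -> np.ndarray:
    return np.array([s.initial_freqs for s in locus_specs], dtype=np.float64)


def sample_genotypes(
    locus_specs: list[LocusSpec], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` genotypes from the initial allele frequencies.

    Both allele copies at each locus are drawn independently; there is no
    spatial stratification.  Returns an (n, n_loci, 2) int8 array in
    canonical sorted-pair form.
    """
    freqs = _freq_matrix(locus_specs)
    n_loci = len(locus_specs)
    out = np.empty((n, n_loci, 2), dtype=np.int8)
    # inverse-CDF sampling, one vectorized draw per locus
    for l in range(n_loci):
        cdf = np.cumsum(freqs[l])
        cdf[-1] = 1.0
        u = rng.random((n, 2))
        out[:, l, :] = np.searchsorted(cdf, u, side="right") + 1
    out.sort(axis=2)
    return out


def sample_genotype(locus_specs: list[LocusSpec], rng: np.random.Generator) -> np.ndarray:
    """Single-genotype convenience wrapper around :func:`sample_genotypes`."""
    return sample_genotypes(locus_specs, 1, rng)[0]


def _validate(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g)
    if g.shape[-2:] != (N_LOCI, 2):
        raise ValueError(f"genotype must have shape (..., {N_LOCI}, 2)")
    return g


def mate_population(
    mothers: np.ndarray, fathers: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mendelian offspring for paired parents, locus by locus.

    At each locus, independently (zero linkage), one uniformly chosen allele
    from each parent; no mutation.  Inputs and output are (n, n_loci, 2).
    """
    mothers = np.asarray(mothers)
    fathers = np.asarray(fathers)
    n, n_loci, _ = mothers.shape
    pick_m = rng.integers(0, 2, size=(n, n_loci))
    pick_f = rng.integers(0, 2, size=(n, n_loci))
    out = np.empty((n, n_loci, 2), dtype=np.int8)
    out[:, :, 0] = np.take_along_axis(mothers, pick_m[:, :, None], axis=2)[:, :, 0]
    out[:, :, 1] = np.take_along_axis(fathers, pick_f[:, :, None], axis=2)[:, :, 0]
    out.sort(axis=2)
    return out


def mate_genotypes(
    mother: np.ndarray, father: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Offspring genotype from a single mother/father pair."""
    return mate_population(
        _validate(mother)[None, :, :], _validate(father)[None, :, :], rng
    )[0]


def count_adaptive_alleles_array(
    genotypes: np.ndarray, habitat_codes: np.ndarray, match_table: np.ndarray
) -> np.ndarray:
    """Adaptive allele copies per individual given each individual's habitat code.

    ``genotypes``: (n, n_loci, 2); ``habitat_codes``: (n,) HabitatType codes;
    ``match_table``: from :func:`adaptation_match_table`.  A habitat code of 0
    (untyped) yields 0 for that individual.
    """
    allele_codes = match_table[
        np.arange(match_table.shape[0])[None, :, None], genotypes - 1
    ]  # (n, n_loci, 2)
    h = np.asarray(habitat_codes, dtype=np.int8)[:, None, None]
    return ((allele_codes == h) & (h > 0)).sum(axis=(1, 2))


def count_adaptive_alleles(
    g: np.ndarray, habitat: HabitatType, locus_specs: list[LocusSpec]
) -> int:
    """Number of allele copies matching ``habitat`` across the adaptive loci."""
    habitat = HabitatType(habitat)
    if habitat is HabitatType.NONE:
        raise ValueError("habitat must be A or B")
    table = adaptation_match_table(locus_specs)
    code = np.array([habitat.value], dtype=np.int8)
    return int(count_adaptive_alleles_array(_validate(g)[None], code, table)[0])


def genotype_homozygosity(g: np.ndarray) -> float:
    """Fraction of loci at which the two allele copies are identical."""
    g = _validate(g)
    return float(np.mean(g[..., 0] == g[..., 1]))
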