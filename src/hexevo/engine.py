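"""Simulation orchestration: state, the yearly event sequence, replicates.

A replicate is fully determined by its configuration and seed: one
:class:`numpy.random.Generator` drives every stochastic decision in a fixed
documented order (resources are deterministic; then the female pairing-order
permutation, fecundity draws for paired females, offspring sex, Mendelian
draws, dispersal walks, survival draws), and the population arrays keep a
stable id-sorted order, so repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import genome, lifecycle
from .hexgrid import (
    BarrierMode,
    EpochName,
    EpochSpec,
    HabitatType,
    Landscape,
    DEFAULT_HABITAT_ASSIGNMENT,
    apply_epoch,
    build_landscape,
)

__all__ = [
    "SimConfig",
    "SimState",
    "EventLog",
    "Population",
    "default_epochs",
    "treatment_grid",
    "initialize_state",
    "step",
    "run_replicate",
    "run_experiment",
]


def default_epochs(
    epoch_length: int = 1000,
    gap_permeability: float = 0.70,
    selection_s: float = 0.10,
    habitat_assignment: dict[int, HabitatType] | None = None,
    extend_final: int = 0,
) -> list[EpochSpec]:
    """The four-epoch schedule: continuous, isolated, semi-connected, and
    semi-connected with local selection, each ``epoch_length`` steps."""
    if habitat_assignment is None:
        habitat_assignment = dict(DEFAULT_HABITAT_ASSIGNMENT)
    e = epoch_length
    return [
        EpochSpec(EpochName.CONTINUOUS, 1, e, BarrierMode.NONE),
        EpochSpec(EpochName.ISOLATED, e + 1, 2 * e, BarrierMode.ABSOLUTE),
        EpochSpec(
            EpochName.SEMI_CONNECTED,
            2 * e + 1,
            3 * e,
            BarrierMode.GAPPED,
            gap_permeability,
        ),
        EpochSpec(
            EpochName.SEMI_CONNECTED_SELECTION,
            3 * e + 1,
            4 * e + extend_final,
            BarrierMode.GAPPED,
            gap_permeability,
            habitat_assignment,
            selection_s,
        ),
    ]


@dataclass
class SimConfig:
    """Everything needed to run one replicate (or the full experiment)."""

    layout: tuple | None = None  # None -> default six-patch landscape
    gap_edges_per_interface: int = 2
    epochs: list[EpochSpec] = field(default_factory=default_epochs)
    demography: lifecycle.DemographyParams = field(
        default_factory=lifecycle.DemographyParams
    )
    dispersal: lifecycle.DispersalParams = field(
        default_factory=lambda: lifecycle.SHORT_DISPERSAL
    )
    locus_specs: list[genome.LocusSpec] = field(
        default_factory=genome.default_locus_table
    )
    horizon: int | None = None  # None -> last epoch's end step
    n_replicates: int = 10
    base_seed: int = 0
    snapshot_steps: tuple[int, ...] | None = None  # None -> each epoch's last step

    def __post_init__(self) -> None:
        steps = sorted((e.start_step, e.end_step) for e in self.epochs)
        for (s0, e0), (s1, _) in zip(steps, steps[1:]):
            if s1 != e0 + 1:
                raise ValueError("epochs must tile the horizon without gaps/overlap")
        if self.horizon is None:
            self.horizon = steps[-1][1]

    def epoch_for(self, step_no: int) -> EpochSpec:
        for e in self.epochs:
            if e.start_step <= step_no <= e.end_step:
                return e
        return self.epochs[-1]

    def snapshots(self) -> tuple[int, ...]:
        if self.snapshot_steps is not None:
            return self.snapshot_steps
        return tuple(
            min(e.end_step, self.horizon)
            for e in self.epochs
            if e.start_step <= self.horizon
        )

    def build_landscape(self) -> Landscape:
        return build_landscape(
            layout=self.layout, gap_edges_per_interface=self.gap_edges_per_interface
        )


def treatment_grid(config: SimConfig) -> list[tuple[str, SimConfig]]:
    """The 2 x 2 x 2 factorial: dispersal x selection strength x permeability."""
    out = []
    for disp_name, disp in (
        ("short", lifecycle.SHORT_DISPERSAL),
        ("long", lifecycle.LONG_DISPERSAL),
    ):
        for s in (0.10, 0.01):
            for perm in (0.02, 0.70):
                epochs = [
                    replace(
                        e,
                        gap_permeability=(
                            perm if e.barrier_mode is BarrierMode.GAPPED else 0.0
                        ),
                        selection_strength=s if e.selection_strength > 0 else 0.0,
                    )
                    for e in config.epochs
                ]
                cfg = replace(config, dispersal=disp, epochs=epochs)
                out.append((f"{disp_name}_S{s:g}_P{perm:g}", cfg))
    return out


class Population:
    """Struct-of-arrays container for the living population."""

    FIELDS = (
        "ids",
        "female",
        "age",
        "cell",
        "natal_patch",
        "resource",
        "crossed_gap",
        "first_bred_step",
        "first_bred_patch",
    )

    def __init__(self, **arrays) -> None:
        self.ids = arrays["ids"].astype(np.int64)
        self.female = arrays["female"].astype(bool)
        self.age = arrays["age"].astype(np.int32)
        self.cell = arrays["cell"].astype(np.int64)
        self.natal_patch = arrays["natal_patch"].astype(np.int16)
        self.resource = arrays["resource"].astype(np.float64)
        self.crossed_gap = arrays["crossed_gap"].astype(bool)
        self.first_bred_step = arrays["first_bred_step"].astype(np.int32)
        self.first_bred_patch = arrays["first_bred_patch"].astype(np.int16)
        self.genotypes = arrays["genotypes"].astype(np.int8)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def is_adult(self) -> np.ndarray:
        return self.age >= 1

    def keep(self, mask: np.ndarray) -> "Population":
        return Population(
            **{f: getattr(self, f)[mask] for f in self.FIELDS},
            genotypes=self.genotypes[mask],
        )

    def extend(self, other: "Population") -> "Population":
        return Population(
            **{
                f: np.concatenate([getattr(self, f), getattr(other, f)])
                for f in self.FIELDS
            },
            genotypes=np.concatenate([self.genotypes, other.genotypes]),
        )


class EventLog:
    """Per-step event records accumulated as arrays, served as DataFrames."""

    def __init__(self, config: SimConfig, seed: int) -> None:
        self.config = config
        self.seed = seed
        self._births: list[np.ndarray] = []  # step, mother_id, mother_age, patch
        self._deaths: list[np.ndarray] = []  # step, is_juvenile, patch
        self._dispersal: list[np.ndarray] = []  # step, natal, settled, crossed, length
        self._breeding: list[np.ndarray] = []  # step, id, patch, natal, crossed, female
        self._census: list[np.ndarray] = []  # step, patch, count
        self._alleles: list[tuple[int, np.ndarray]] = []  # step, (patch,locus,allele)
        self.snapshots: dict[int, dict[str, np.ndarray]] = {}
        self.patch_labels: list[int] = []
        self.final_step = 0

    @staticmethod
    def _frame(chunks, columns) -> pd.DataFrame:
        if not chunks:
            return pd.DataFrame({c: np.array([], dtype=np.int64) for c in columns})
        data = np.concatenate(chunks, axis=0)
        return pd.DataFrame(dict(zip(columns, data.T)))

    def births_df(self) -> pd.DataFrame:
        return self._frame(self._births, ["step", "mother_id", "mother_age", "patch"])

    def deaths_df(self) -> pd.DataFrame:
        return self._frame(self._deaths, ["step", "is_juvenile", "patch"])

    def dispersal_df(self) -> pd.DataFrame:
        return self._frame(
            self._dispersal,
            ["step", "natal_patch", "settled_patch", "crossed_gap", "path_length"],
        )

    def breeding_df(self) -> pd.DataFrame:
        return self._frame(
            self._breeding,
            ["step", "individual_id", "patch", "natal_patch", "crossed_gap", "female"],
        )

    def census_df(self) -> pd.DataFrame:
        return self._frame(self._census, ["step", "patch", "count"])

    def allele_counts_df(self) -> pd.DataFrame:
        rows = []
        for s, arr in self._alleles:
            n_patch, n_loci, n_alleles = arr.shape
            idx = np.indices(arr.shape).reshape(3, -1)
            rows.append(
                np.column_stack(
                    [
                        np.full(idx.shape[1], s),
                        np.asarray(self.patch_labels)[idx[0]],
                        idx[1] + 1,
                        idx[2] + 1,
                        arr.reshape(-1),
                    ]
                )
            )
        return self._frame(rows, ["step", "patch", "locus", "allele", "count"])


@dataclass
class SimState:
    config: SimConfig
    landscape: Landscape
    population: Population
    rng: np.random.Generator
    log: EventLog
    step_no: int = 1
    next_id: int = 0
    _match_table: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self._match_table is None:
            self._match_table = genome.adaptation_match_table(self.config.locus_specs)


def initialize_state(config: SimConfig, rng: np.random.Generator | int) -> SimState:
    """Saturate the landscape: one adult (age 1) per habitat cell, sexes 50/50
    at random, genotypes drawn from the initial allele frequencies."""
    if not isinstance(rng, np.random.Generator):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = -1
    landscape = config.build_landscape()
    apply_epoch(landscape, config.epoch_for(1))
    n = landscape.n_cells
    pop = Population(
        ids=np.arange(n),
        female=rng.random(n) < 0.5,
        age=np.ones(n, dtype=np.int32),
        cell=np.arange(n),
        natal_patch=landscape.patch_ids.copy(),
        resource=np.ones(n),
        crossed_gap=np.zeros(n, dtype=bool),
        first_bred_step=np.full(n, -1, dtype=np.int32),
        first_bred_patch=np.full(n, -1, dtype=np.int16),
        genotypes=genome.sample_genotypes(config.locus_specs, n, rng),
    )
    log = EventLog(config, seed)
    log.patch_labels = landscape.patch_labels
    return SimState(config, landscape, pop, rng, log, step_no=1, next_id=n)


def _record_first_breeding(state: SimState, positions: np.ndarray) -> None:
    pop = state.population
    fresh = positions[pop.first_bred_step[positions] < 0]
    if len(fresh) == 0:
        return
    patches = state.landscape.patch_ids[pop.cell[fresh]]
    pop.first_bred_step[fresh] = state.step_no
    pop.first_bred_patch[fresh] = patches
    state.log._breeding.append(
        np.column_stack(
            [
                np.full(len(fresh), state.step_no),
                pop.ids[fresh],
                patches,
                pop.natal_patch[fresh],
                pop.crossed_gap[fresh].astype(np.int64),
                pop.female[fresh].astype(np.int64),
            ]
        )
    )


def step(state: SimState) -> SimState:
    """Advance one year: epoch transition, then life-cycle events (a)-(e)."""
    cfg = state.config
    epoch = cfg.epoch_for(state.step_no)
    if state.landscape.epoch is not epoch:
        apply_epoch(state.landscape, epoch)
    pop = state.population
    ls = state.landscape
    rng = state.rng
    log = state.log
    n_adults = len(pop)

    # (a) resource acquisition — all residents are adults at step start
    pop.resource = lifecycle.resource_fractions(
        ls, pop.cell, cfg.demography.resource_goal
    )

    # (b) pair formation
    fpos_all = np.flatnonzero(pop.female)
    mpos_all = np.flatnonzero(~pop.female)
    fi, mi = lifecycle.pair_indices(
        ls,
        pop.cell[fpos_all],
        pop.ids[fpos_all],
        pop.cell[mpos_all],
        pop.ids[mpos_all],
        cfg.demography.pairing_radius,
        priority=rng.permutation(len(fpos_all)),
    )
    mothers = fpos_all[fi]
    fathers = mpos_all[mi]

    # (c) reproduction
    counts = (
        lifecycle.offspring_counts(pop.resource[mothers], cfg.demography, rng)
        if len(mothers)
        else np.zeros(0, dtype=np.int64)
    )
    bred = counts > 0
    _record_first_breeding(state, mothers[bred])
    _record_first_breeding(state, fathers[bred])
    mo = np.repeat(mothers, counts)
    fa = np.repeat(fathers, counts)
    n_off = len(mo)
    if n_off:
        natal = ls.patch_ids[pop.cell[mo]].astype(np.int16)
        log._births.append(
            np.column_stack(
                [
                    np.full(n_off, state.step_no),
                    pop.ids[mo],
                    pop.age[mo].astype(np.int64),
                    natal.astype(np.int64),
                ]
            )
        )
        offspring = Population(
            ids=np.arange(state.next_id, state.next_id + n_off),
            female=rng.random(n_off) < 0.5,
            age=np.zeros(n_off, dtype=np.int32),
            cell=pop.cell[mo].copy(),
            natal_patch=natal,
            resource=np.ones(n_off),
            crossed_gap=np.zeros(n_off, dtype=bool),
            first_bred_step=np.full(n_off, -1, dtype=np.int32),
            first_bred_patch=np.full(n_off, -1, dtype=np.int16),
            genotypes=genome.mate_population(
                pop.genotypes[mo], pop.genotypes[fa], rng
            ),
        )
        state.next_id += n_off

        # (d) juvenile dispersal
        lo, hi = cfg.dispersal.path_length_range
        lengths = rng.integers(lo, hi + 1, size=n_off)
        final, crossed = lifecycle.random_walks(
            ls, offspring.cell, lengths, cfg.dispersal.autocorrelation, rng
        )
        offspring.cell = final
        offspring.crossed_gap = crossed
        settled = ls.patch_ids[final]
        log._dispersal.append(
            np.column_stack(
                [
                    np.full(n_off, state.step_no),
                    offspring.natal_patch.astype(np.int64),
                    settled.astype(np.int64),
                    crossed.astype(np.int64),
                    lengths,
                ]
            )
        )
        pop = pop.extend(offspring)

    # (e) survival — adults use this step's resource fraction, newborns 1.0
    is_juv = pop.age == 0
    S = epoch.selection_strength
    if S > 0:
        habitat_codes = ls.habitat_types[pop.cell]
        adaptive = genome.count_adaptive_alleles_array(
            pop.genotypes, habitat_codes, state._match_table
        )
    else:
        adaptive = np.zeros(len(pop), dtype=np.int64)
    probs = lifecycle.survival_probabilities(
        is_juv, pop.resource, adaptive, S, cfg.demography
    )
    alive = rng.random(len(pop)) < probs
    dead = ~alive
    if dead.any():
        log._deaths.append(
            np.column_stack(
                [
                    np.full(int(dead.sum()), state.step_no),
                    is_juv[dead].astype(np.int64),
                    ls.patch_ids[pop.cell[dead]].astype(np.int64),
                ]
            )
        )
    pop = pop.keep(alive)

    # bookkeeping: census, allele counts, snapshot
    patches = ls.patch_ids[pop.cell]
    labels = log.patch_labels
    pindex = np.searchsorted(labels, patches)
    counts_now = np.bincount(pindex, minlength=len(labels)).astype(np.int64)
    log._census.append(
        np.column_stack(
            [np.full(len(labels), state.step_no), np.asarray(labels), counts_now]
        )
    )
    loci_idx = np.arange(genome.N_LOCI, dtype=np.int64)[None, :, None]
    flat = (
        pindex[:, None, None].astype(np.int64) * genome.N_LOCI + loci_idx
    ) * genome.N_ALLELES + (pop.genotypes.astype(np.int64) - 1)
    allele_arr = np.bincount(
        flat.ravel(), minlength=len(labels) * genome.N_LOCI * genome.N_ALLELES
    ).reshape(len(labels), genome.N_LOCI, genome.N_ALLELES)
    log._alleles.append((state.step_no, allele_arr))
    if state.step_no in cfg.snapshots():
        log.snapshots[state.step_no] = {
            "ids": pop.ids.copy(),
            "cell": pop.cell.copy(),
            "patch": patches.copy(),
            "coords": ls.coords[pop.cell].copy(),
            "genotypes": pop.genotypes.copy(),
        }

    # age increment; juveniles become adults at the start of the next year
    pop.age = pop.age + 1
    state.population = pop
    log.final_step = state.step_no
    state.step_no += 1
    return state


def run_replicate(config: SimConfig, seed: int) -> EventLog:
    """Initialize and run ``horizon`` steps; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    state = initialize_state(config, rng)
    state.log.seed = seed
    for _ in range(config.horizon):
        step(state)
    state.log.final_population = state.population
    return state.log


def replicate_seed(base_seed: int, treatment_index: int, replicate_index: int) -> int:
    ss = np.random.SeedSequence([base_seed, treatment_index, replicate_index])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_experiment(
    config: SimConfig, n_replicates: int | None = None
) -> dict[tuple[str, int], EventLog]:
    """Run the full treatment grid with derived per-replicate seeds."""
    n_rep = config.n_replicates if n_replicates is None else n_replicates
    out: dict[tuple[str, int], EventLog] = {}
    for t_idx, (name, cfg) in enumerate(treatment_grid(config)):
        for rep in range(n_rep):
            seed = replicate_seed(config.base_seed, t_idx, rep)
            out[(name, rep)] = run_replicate(cfg, seed)
    return out
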