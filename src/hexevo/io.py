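"""Configuration parsing, log/report serialization, and STRUCTURE export.

The scenario file is a single YAML document; an empty file yields the full
default scenario, and every constant of the shipped configuration appears
literally in :func:`write_config` output so a scenario file is
self-documenting.  Unknown keys are rejected with their key paths.

Event logs are written as one tidy CSV per table plus per-snapshot genotype
reports, and can be read back into a lightweight object exposing the same
DataFrame accessors as a live :class:`~hexevo.engine.EventLog`, so all
metrics run equally on fresh or persisted runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genome, lifecycle
from .engine import EventLog, SimConfig, default_epochs
from .hexgrid import BarrierMode, EpochName, EpochSpec, HabitatType

__all__ = [
    "StructureExportSpec",
    "read_config",
    "write_config",
    "config_hash",
    "write_metrics",
    "write_log",
    "read_log",
    "export_structure",
]


# ---------------------------------------------------------------------------
# configuration


def _check_keys(mapping: dict, allowed: set[str], path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")


def _parse_epochs(raw: dict) -> list[EpochSpec]:
    _check_keys(
        raw,
        {
            "epoch_length",
            "gap_permeability",
            "selection_s",
            "extend_final",
            "habitat_assignment",
            "schedule",
        },
        "epochs",
    )
    if "schedule" in raw:
        out = []
        for i, e in enumerate(raw["schedule"]):
            _check_keys(
                e,
                {
                    "name",
                    "start_step",
                    "end_step",
                    "barrier_mode",
                    "gap_permeability",
                    "habitat_assignment",
                    "selection_strength",
                },
                f"epochs.schedule[{i}]",
            )
            out.append(
                EpochSpec(
                    EpochName(e["name"]),
                    int(e["start_step"]),
                    int(e["end_step"]),
                    BarrierMode(e.get("barrier_mode", "none")),
                    float(e.get("gap_permeability", 0.0)),
                    {
                        int(k): HabitatType[v]
                        for k, v in (e.get("habitat_assignment") or {}).items()
                    },
                    float(e.get("selection_strength", 0.0)),
                )
            )
        return out
    assignment = None
    if "habitat_assignment" in raw:
        assignment = {int(k): HabitatType[v] for k, v in raw["habitat_assignment"].items()}
    return default_epochs(
        epoch_length=int(raw.get("epoch_length", 1000)),
        gap_permeability=float(raw.get("gap_permeability", 0.70)),
        selection_s=float(raw.get("selection_s", 0.10)),
        habitat_assignment=assignment,
        extend_final=int(raw.get("extend_final", 0)),
    )


def _parse_loci(raw: list) -> list[genome.LocusSpec]:
    out = []
    for i, row in enumerate(raw):
        _check_keys(row, {"locus", "freqs", "adaptation"}, f"loci[{i}]")
        out.append(
            genome.LocusSpec(
                int(row["locus"]),
                tuple(float(f) for f in row["freqs"]),
                {
                    int(a): HabitatType[h]
                    for a, h in (row.get("adaptation") or {}).items()
                },
            )
        )
    return out


def read_config(path: str | Path) -> SimConfig:
    """Parse a scenario file into a fully validated :class:`SimConfig`.

    An empty file produces the default scenario; schema violations are
    reported with their key paths.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_keys(
        raw,
        {
            "landscape",
            "epochs",
            "demography",
            "dispersal",
            "loci",
            "horizon",
            "n_replicates",
            "base_seed",
            "snapshot_steps",
        },
        "<root>",
    )
    kwargs: dict = {}
    land = raw.get("landscape", {})
    _check_keys(land, {"layout", "gap_edges_per_interface"}, "landscape")
    if "layout" in land:
        kwargs["layout"] = tuple(tuple(int(x) for x in row) for row in land["layout"])
    if "gap_edges_per_interface" in land:
        kwargs["gap_edges_per_interface"] = int(land["gap_edges_per_interface"])
    if "epochs" in raw:
        kwargs["epochs"] = _parse_epochs(raw["epochs"])
    if "demography" in raw:
        allowed = set(lifecycle.DemographyParams.__dataclass_fields__)
        _check_keys(raw["demography"], allowed, "demography")
        kwargs["demography"] = lifecycle.DemographyParams(**raw["demography"])
    if "dispersal" in raw:
        d = raw["dispersal"]
        _check_keys(d, {"mode", "path_length_range", "autocorrelation"}, "dispersal")
        if "mode" in d:
            base = {"short": lifecycle.SHORT_DISPERSAL, "long": lifecycle.LONG_DISPERSAL}[
                d["mode"]
            ]
            rng_ = d.get("path_length_range", base.path_length_range)
            kwargs["dispersal"] = lifecycle.DispersalParams(
                tuple(rng_), float(d.get("autocorrelation", base.autocorrelation))
            )
        else:
            kwargs["dispersal"] = lifecycle.DispersalParams(
                tuple(d["path_length_range"]),
                float(d.get("autocorrelation", 75.0)),
            )
    if "loci" in raw:
        kwargs["locus_specs"] = _parse_loci(raw["loci"])
    for key in ("horizon", "n_replicates", "base_seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "snapshot_steps" in raw:
        kwargs["snapshot_steps"] = tuple(int(s) for s in raw["snapshot_steps"])
    return SimConfig(**kwargs)


def _config_dict(config: SimConfig) -> dict:
    return {
        "landscape": {
            "layout": [list(row) for row in config.layout] if config.layout else None,
            "gap_edges_per_interface": config.gap_edges_per_interface,
        },
        "epochs": {
            "schedule": [
                {
                    "name": e.name.value,
                    "start_step": e.start_step,
                    "end_step": e.end_step,
                    "barrier_mode": e.barrier_mode.value,
                    "gap_permeability": e.gap_permeability,
                    "habitat_assignment": {
                        str(k): v.name for k, v in e.habitat_assignment.items()
                    },
                    "selection_strength": e.selection_strength,
                }
                for e in config.epochs
            ]
        },
        "demography": {
            k: getattr(config.demography, k)
            for k in lifecycle.DemographyParams.__dataclass_fields__
        },
        "dispersal": {
            "path_length_range": list(config.dispersal.path_length_range),
            "autocorrelation": config.dispersal.autocorrelation,
        },
        "loci": [
            {
                "locus": s.locus_id,
                "freqs": list(s.initial_freqs),
                "adaptation": {str(a): h.name for a, h in s.adaptation_map.items()},
            }
            for s in config.locus_specs
        ],
        "horizon": config.horizon,
        "n_replicates": config.n_replicates,
        "base_seed": config.base_seed,
        "snapshot_steps": list(config.snapshot_steps)
        if config.snapshot_steps is not None
        else None,
    }


def write_config(config: SimConfig, path: str | Path) -> None:
    """Write a scenario file containing every parameter literally."""
    d = _config_dict(config)
    if d["landscape"]["layout"] is None:
        del d["landscape"]["layout"]
    if d["snapshot_steps"] is None:
        del d["snapshot_steps"]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def config_hash(config: SimConfig) -> str:
    """Stable digest of the full parameter set."""
    blob = json.dumps(_config_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# logs and metric tables


def write_metrics(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: SimConfig | None = None,
    seeds: list[int] | None = None,
) -> list[Path]:
    """Write one CSV per metric family plus a manifest of seeds and config hash.

    Column order and float formatting are deterministic, so identical runs
    produce byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        p = out_dir / f"{name}.csv"
        tables[name].to_csv(p, index=False, float_format="%.10g", lineterminator="\n")
        written.append(p)
    manifest = {
        "tables": [p.name for p in written],
        "seeds": seeds or [],
        "config_hash": config_hash(config) if config is not None else None,
    }
    mp = out_dir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mp)
    return written


def _snapshot_frame(snap: dict) -> pd.DataFrame:
    g = snap["genotypes"]
    cols = {"individual_id": snap["ids"], "patch": snap["patch"]}
    cols["q"] = snap["coords"][:, 0]
    cols["r"] = snap["coords"][:, 1]
    for l in range(g.shape[1]):
        cols[f"L{l + 1}a"] = g[:, l, 0]
        cols[f"L{l + 1}b"] = g[:, l, 1]
    return pd.DataFrame(cols)


def write_log(log: EventLog, out_dir: str | Path) -> None:
    """Persist an event log as tidy CSVs (one per table, one per snapshot)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "births": log.births_df(),
        "deaths": log.deaths_df(),
        "dispersal": log.dispersal_df(),
        "breeding": log.breeding_df(),
        "census": log.census_df(),
        "allele_counts": log.allele_counts_df(),
    }
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False, lineterminator="\n")
    for step, snap in log.snapshots.items():
        _snapshot_frame(snap).to_csv(
            out_dir / f"genotypes_step{step}.csv", index=False, lineterminator="\n"
        )
    meta = {
        "seed": log.seed,
        "final_step": log.final_step,
        "patch_labels": log.patch_labels,
        "config_hash": config_hash(log.config),
    }
    (out_dir / "run.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


class CsvLog:
    """Read-back view of a persisted run with the EventLog accessor interface."""

    def __init__(self, run_dir: str | Path) -> None:
        self.dir = Path(run_dir)
        meta = json.loads((self.dir / "run.json").read_text())
        self.seed = meta["seed"]
        self.final_step = meta["final_step"]
        self.patch_labels = meta["patch_labels"]
        self.snapshots: dict[int, dict[str, np.ndarray]] = {}
        for p in sorted(self.dir.glob("genotypes_step*.csv")):
            step = int(p.stem.replace("genotypes_step", ""))
            df = pd.read_csv(p)
            n_loci = sum(c.endswith("a") for c in df.columns if c.startswith("L"))
            g = np.empty((len(df), n_loci, 2), dtype=np.int8)
            for l in range(n_loci):
                g[:, l, 0] = df[f"L{l + 1}a"]
                g[:, l, 1] = df[f"L{l + 1}b"]
            self.snapshots[step] = {
                "ids": df["individual_id"].to_numpy(),
                "patch": df["patch"].to_numpy(),
                "coords": df[["q", "r"]].to_numpy(),
                "genotypes": g,
            }

    def _read(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.dir / f"{name}.csv")

    def births_df(self) -> pd.DataFrame:
        return self._read("births")

    def deaths_df(self) -> pd.DataFrame:
        return self._read("deaths")

    def dispersal_df(self) -> pd.DataFrame:
        return self._read("dispersal")

    def breeding_df(self) -> pd.DataFrame:
        return self._read("breeding")

    def census_df(self) -> pd.DataFrame:
        return self._read("census")

    def allele_counts_df(self) -> pd.DataFrame:
        return self._read("allele_counts")


def read_log(run_dir: str | Path) -> CsvLog:
    return CsvLog(run_dir)


# ---------------------------------------------------------------------------
# STRUCTURE export


@dataclass
class StructureExportSpec:
    """How to build a STRUCTURE input file from a genotype snapshot.

    ``per_patch_n`` individuals per patch (resampling with replacement when a
    patch holds fewer); one row per individual with two columns per locus by
    default, or the two-row dialect when ``two_row`` is set.
    """

    per_patch_n: int = 25
    snapshot_step: int | None = None
    missing_code: int = -9
    two_row: bool = False

    def __post_init__(self) -> None:
        if self.per_patch_n < 1:
            raise ValueError("per_patch_n must be >= 1")


def export_structure(
    snapshot: dict,
    spec: StructureExportSpec,
    rng: np.random.Generator | int,
    path: str | Path,
    patch_labels: list[int] | None = None,
) -> list[str]:
    """Write a STRUCTURE input file; returns warnings for skipped strata.

    Rows carry the individual id, the patch label as the population flag, and
    the 10 loci as integer alleles (1-5).  Patches with fewer than the quota
    are resampled with replacement until the quota is met; extinct patches
    are skipped with a warning record.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    patches = np.asarray(snapshot["patch"])
    if patch_labels is None:
        patch_labels = sorted(int(p) for p in np.unique(patches))
    warnings: list[str] = []
    lines: list[str] = []
    for patch in patch_labels:
        pos = np.flatnonzero(patches == patch)
        if len(pos) == 0:
            warnings.append(f"patch {patch}: no extant individuals; stratum skipped")
            continue
        chosen = rng.choice(pos, size=spec.per_patch_n, replace=len(pos) < spec.per_patch_n)
        for k in np.sort(chosen):
            ind = int(snapshot["ids"][k])
            g = snapshot["genotypes"][k]
            if spec.two_row:
                for copy_i in range(2):
                    alleles = " ".join(str(int(a)) for a in g[:, copy_i])
                    lines.append(f"{ind} {patch} {alleles}")
            else:
                alleles = " ".join(
                    f"{int(g[l, 0])} {int(g[l, 1])}" for l in range(g.shape[0])
                )
                lines.append(f"{ind} {patch} {alleles}")
    Path(path).write_text("\n".join(lines) + "\n")
    return warnings
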