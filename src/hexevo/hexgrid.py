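"""Hexagonal landscape: patches, barriers, gaps, and epoch-driven change.

The landscape is a set of flat-top hexagonal cells on an axial coordinate
system (q, r).  Habitat cells belong to one of six patches; everything else
is non-habitat matrix, which individuals can never enter (matrix edges and
the landscape boundary are reflective).  Patch footprints are specified as
``columns x rows`` rectangles in offset coordinates (odd-q vertical layout)
and converted to axial coordinates internally.

Inter-patch interfaces carry per-edge transmission probabilities that change
with the landscape epoch: free passage while the landscape is continuous,
absolute barriers while patches are isolated, and small barrier gaps of
configurable permeability in the semi-connected epochs.  The total gap size
is identical across every patch interface, so dispersers have a uniform
potential for crossing each one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MATRIX",
    "AXIAL_DIRECTIONS",
    "HabitatType",
    "BarrierMode",
    "EpochName",
    "HexCell",
    "EdgeSet",
    "EpochSpec",
    "Landscape",
    "DEFAULT_LAYOUT",
    "DEFAULT_HABITAT_ASSIGNMENT",
    "offset_to_axial",
    "hex_distance",
    "hex_disk",
    "build_landscape",
    "apply_epoch",
    "edge_permeability",
    "reachable_neighborhood",
]

#: patch id used for non-habitat matrix cells
MATRIX = 0

#: axial direction vectors for flat-top hexagons, counter-clockwise
AXIAL_DIRECTIONS = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))


class HabitatType(Enum):
    NONE = 0
    A = 1
    B = 2


class BarrierMode(Enum):
    NONE = "none"
    ABSOLUTE = "absolute"
    GAPPED = "gapped"


class EpochName(Enum):
    CONTINUOUS = "continuous"
    ISOLATED = "isolated"
    SEMI_CONNECTED = "semi_connected"
    SEMI_CONNECTED_SELECTION = "semi_connected_selection"


@dataclass(frozen=True)
class HexCell:
    """A single hexagonal cell: axial coordinate, patch membership, habitat type."""

    coord: tuple[int, int]
    patch_id: int
    habitat_type: HabitatType = HabitatType.NONE


@dataclass
class EpochSpec:
    """One contiguous block of simulation steps with a fixed landscape configuration.

    Parameters
    ----------
    name : EpochName
    start_step, end_step : int
        Inclusive step range; epochs must tile the horizon without overlap.
    barrier_mode : BarrierMode
        NONE (all inter-patch edges open), ABSOLUTE (closed), or GAPPED
        (gap edges carry ``gap_permeability``, the rest of the interface 0).
    gap_permeability : float
        Per-encounter transmission probability of a gap edge.
    habitat_assignment : dict patch_id -> HabitatType
        Empty except in the local-selection epoch.
    selection_strength : float
        Survival benefit per locally adaptive allele copy (juveniles only);
        may be > 0 only when habitat types are assigned.
    """

    name: EpochName
    start_step: int
    end_step: int
    barrier_mode: BarrierMode = BarrierMode.NONE
    gap_permeability: float = 0.0
    habitat_assignment: dict[int, HabitatType] = field(default_factory=dict)
    selection_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.end_step < self.start_step:
            raise ValueError("epoch end_step precedes start_step")
        if not 0.0 <= self.gap_permeability <= 1.0:
            raise ValueError("gap_permeability must be a probability")
        if self.selection_strength > 0 and not self.habitat_assignment:
            raise ValueError("selection requires a habitat assignment")
        if self.barrier_mode is BarrierMode.GAPPED and self.gap_permeability <= 0:
            raise ValueError("a GAPPED epoch needs gap_permeability > 0")


def offset_to_axial(col: int, row: int) -> tuple[int, int]:
    """Convert odd-q offset coordinates (column, row) to axial (q, r)."""
    return col, row - (col - (col & 1)) // 2


def hex_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Hexagonal lattice distance between two axial coordinates.

    Symmetric, non-negative, and satisfies the triangle inequality.
    """
    dq = a[0] - b[0]
    dr = a[1] - b[1]
    return (abs(dq) + abs(dr) + abs(dq + dr)) // 2


def hex_disk(center: tuple[int, int], radius: int) -> set[tuple[int, int]]:
    """All axial coordinates within ``radius`` steps of ``center``.

    Contains exactly ``1 + 3 r (r + 1)`` cells; radius 3 gives the
    37-cell resource neighborhood.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    cq, cr = center
    out: set[tuple[int, int]] = set()
    for dq in range(-radius, radius + 1):
        for dr in range(max(-radius, -dq - radius), min(radius, -dq + radius) + 1):
            out.add((cq + dq, cr + dr))
    return out


#: the six-patch layout: (patch_id, first column, first row, n columns, n rows)
#: in odd-q offset coordinates.  Two large 26x51 patches adjoin at the centre;
#: a 10x20 medium and a 5x10 small patch abut each large patch (never each
#: other), for 2x1326 + 2x200 + 2x50 = 3152 habitat cells and five interfaces.
DEFAULT_LAYOUT: tuple[tuple[int, int, int, int, int], ...] = (
    (1, 0, 0, 26, 51),
    (2, 26, 0, 26, 51),
    (3, -10, 10, 10, 20),
    (4, 52, 10, 10, 20),
    (5, -5, 36, 5, 10),
    (6, 52, 36, 5, 10),
)

#: habitat types in the local-selection epoch; every patch adjoins at least
#: one patch of the opposite type.
DEFAULT_HABITAT_ASSIGNMENT: dict[int, HabitatType] = {
    1: HabitatType.A,
    2: HabitatType.B,
    3: HabitatType.B,
    4: HabitatType.A,
    5: HabitatType.B,
    6: HabitatType.A,
}


class EdgeSet(Mapping):
    """Read-only map from unordered adjacent-cell pairs to transmission probability.

    Backed by the landscape's current permeability table.  Edges into matrix
    always return 0 (reflective); intra-patch edges are 1; inter-patch edges
    depend on the active epoch.
    """

    def __init__(self, landscape: "Landscape") -> None:
        self._ls = landscape

    def __getitem__(self, pair) -> float:
        a, b = tuple(pair)
        return self._ls.permeability_between(a, b)

    def _pairs(self):
        ls = self._ls
        for i in range(ls.n_cells):
            a = tuple(ls.coords[i])
            for d in range(6):
                j = ls.neighbor_table[i, d]
                if j >= 0 and i < j:
                    yield frozenset((a, tuple(ls.coords[j])))

    def __iter__(self):
        return self._pairs()

    def __len__(self) -> int:
        return int((self._ls.neighbor_table >= 0).sum()) // 2


class Landscape:
    """The hexagonal habitat mosaic and its current edge permeabilities.

    Only habitat cells are stored; a move off the stored cell set is a move
    into matrix and has permeability 0.  The per-cell, per-direction
    permeability table (`perm`) is rebuilt by :func:`apply_epoch` and is the
    single source of truth for all movement and reachability queries.
    """

    def __init__(
        self,
        coords: np.ndarray,
        patch_ids: np.ndarray,
        offsets: np.ndarray,
        gap_edges_per_interface: int = 2,
    ) -> None:
        self.coords = np.asarray(coords, dtype=np.int32)  # (n, 2) axial
        self.patch_ids = np.asarray(patch_ids, dtype=np.int16)
        self.offsets = np.asarray(offsets, dtype=np.int32)  # (n, 2) (col, row)
        self.n_cells = len(self.coords)
        self.gap_edges_per_interface = int(gap_edges_per_interface)
        self.habitat_types = np.zeros(self.n_cells, dtype=np.int8)  # HabitatType codes
        self.epoch: EpochSpec | None = None
        self._index: dict[tuple[int, int], int] = {
            (int(q), int(r)): i for i, (q, r) in enumerate(self.coords)
        }
        self._build_neighbor_table()
        self._find_interfaces()
        self.perm = np.zeros((self.n_cells, 6), dtype=np.float64)
        self._perm_version = 0
        self._cache: dict = {}
        # default: continuous landscape
        apply_epoch(self, EpochSpec(EpochName.CONTINUOUS, 1, 1, BarrierMode.NONE))

    # -- construction ------------------------------------------------------

    def _build_neighbor_table(self) -> None:
        nbr = np.full((self.n_cells, 6), -1, dtype=np.int32)
        for i, (q, r) in enumerate(self.coords):
            for d, (dq, dr) in enumerate(AXIAL_DIRECTIONS):
                j = self._index.get((int(q) + dq, int(r) + dr))
                if j is not None:
                    nbr[i, d] = j
        self.neighbor_table = nbr

    def _find_interfaces(self) -> None:
        """Record every inter-patch edge, grouped by unordered patch pair."""
        interfaces: dict[frozenset, list[tuple[int, int]]] = {}
        for i in range(self.n_cells):
            for d in range(6):
                j = self.neighbor_table[i, d]
                if j < 0 or j < i:
                    continue
                pi, pj = int(self.patch_ids[i]), int(self.patch_ids[j])
                if pi != pj:
                    interfaces.setdefault(frozenset((pi, pj)), []).append((i, int(j)))
        # deterministic ordering along each interface (by mean offset row/col)
        for key, edges in interfaces.items():
            edges.sort(
                key=lambda e: (
                    int(self.offsets[e[0], 1]) + int(self.offsets[e[1], 1]),
                    int(self.offsets[e[0], 0]) + int(self.offsets[e[1], 0]),
                )
            )
        self.interfaces = interfaces
        # a contiguous run of G gap edges centred on each interface midpoint
        self.gap_edges: dict[frozenset, list[tuple[int, int]]] = {}
        g = self.gap_edges_per_interface
        for key, edges in interfaces.items():
            if g > len(edges):
                raise ValueError(
                    f"interface {sorted(key)} has only {len(edges)} edges; "
                    f"cannot place {g} gap edges"
                )
            lo = (len(edges) - g) // 2
            self.gap_edges[key] = edges[lo : lo + g]

    # -- queries -----------------------------------------------------------

    @property
    def edges(self) -> EdgeSet:
        return EdgeSet(self)

    @property
    def patch_index(self) -> dict[int, set[tuple[int, int]]]:
        out: dict[int, set[tuple[int, int]]] = {}
        for pid in np.unique(self.patch_ids):
            mask = self.patch_ids == pid
            out[int(pid)] = {tuple(c) for c in self.coords[mask]}
        return out

    @property
    def patch_labels(self) -> list[int]:
        return sorted(int(p) for p in np.unique(self.patch_ids))

    def cell_index(self, coord: tuple[int, int]) -> int:
        return self._index[tuple(coord)]

    def is_habitat(self, coord: tuple[int, int]) -> bool:
        return tuple(coord) in self._index

    def cell(self, coord: tuple[int, int]) -> HexCell:
        i = self.cell_index(coord)
        return HexCell(
            tuple(coord), int(self.patch_ids[i]), HabitatType(int(self.habitat_types[i]))
        )

    def cells(self) -> Iterable[HexCell]:
        for i in range(self.n_cells):
            yield HexCell(
                (int(self.coords[i, 0]), int(self.coords[i, 1])),
                int(self.patch_ids[i]),
                HabitatType(int(self.habitat_types[i])),
            )

    def patch_cell_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.patch_ids, return_counts=True)
        return {int(p): int(c) for p, c in zip(ids, counts)}

    def permeability_between(self, a: tuple[int, int], b: tuple[int, int]) -> float:
        """Current transmission probability of the edge between adjacent cells."""
        if hex_distance(a, b) != 1:
            raise ValueError(f"cells {a} and {b} are not adjacent")
        ia = self._index.get(tuple(a))
        ib = self._index.get(tuple(b))
        if ia is None and ib is None:
            raise ValueError("neither cell is habitat")
        if ia is None or ib is None:
            return 0.0  # matrix edges are reflective
        d = AXIAL_DIRECTIONS.index((b[0] - a[0], b[1] - a[1]))
        return float(self.perm[ia, d])

    # -- cached movement structure for the engine --------------------------

    def bfs_rings(self, radius: int) -> list[list[np.ndarray]]:
        """Per cell, reachable cell indices grouped by passable-path depth 0..radius.

        Reachability follows edges with permeability > 0; results are cached
        until the next epoch change.
        """
        key = ("rings", radius, self._perm_version)
        if key in self._cache:
            return self._cache[key]
        passable = self.perm > 0
        nbr = self.neighbor_table
        rings: list[list[np.ndarray]] = []
        for start in range(self.n_cells):
            depth = {start: 0}
            frontier = [start]
            by_depth = [[start]]
            for d in range(1, radius + 1):
                nxt = []
                for c in frontier:
                    for k in range(6):
                        j = int(nbr[c, k])
                        if j >= 0 and passable[c, k] and j not in depth:
                            depth[j] = d
                            nxt.append(j)
                if not nxt:
                    break
                by_depth.append(nxt)
                frontier = nxt
            rings.append([np.asarray(lvl, dtype=np.int32) for lvl in by_depth])
        self._cache = {key: rings}  # keep only the current epoch's structure
        return rings

    def neighborhood_members(self, radius: int) -> tuple[np.ndarray, np.ndarray]:
        """Flattened reachable neighborhoods: (indptr, indices) CSR-style arrays."""
        key = ("csr", radius, self._perm_version)
        if key in self._cache:
            return self._cache[key]
        rings = self.bfs_rings(radius)
        indptr = np.zeros(self.n_cells + 1, dtype=np.int64)
        chunks = []
        for i, levels in enumerate(rings):
            members = np.concatenate(levels)
            chunks.append(members)
            indptr[i + 1] = indptr[i] + len(members)
        indices = np.concatenate(chunks)
        self._cache[key] = (indptr, indices)
        return indptr, indices


def build_landscape(
    patch_dims: Sequence[tuple[int, int]] | None = None,
    layout: Sequence[tuple[int, int, int, int, int]] | None = None,
    gap_edges_per_interface: int = 2,
) -> Landscape:
    """Construct the habitat landscape.

    With no arguments the default six-patch scenario is built (3152 cells).
    ``layout`` overrides the full placement as tuples of
    ``(patch_id, col0, row0, n_columns, n_rows)`` in offset coordinates.
    ``patch_dims`` alone rescales the three default size classes
    ``[(large_cols, large_rows), (medium_cols, medium_rows), (small_cols,
    small_rows)]`` while keeping the default adjacency plan.
    """
    if layout is None:
        if patch_dims is None:
            layout = DEFAULT_LAYOUT
        else:
            (lc, lr), (mc, mr), (sc, sr) = patch_dims
            if min(lc, lr, mc, mr, sc, sr) <= 0:
                raise ValueError("patch dimensions must be positive")
            layout = (
                (1, 0, 0, lc, lr),
                (2, lc, 0, lc, lr),
                (3, -mc, min(2, lr - mr), mc, mr),
                (4, 2 * lc, min(2, lr - mr), mc, mr),
                (5, -sc, lr - sr - 1, sc, sr),
                (6, 2 * lc, lr - sr - 1, sc, sr),
            )
    coords: list[tuple[int, int]] = []
    offsets: list[tuple[int, int]] = []
    patch_ids: list[int] = []
    seen: dict[tuple[int, int], int] = {}
    for pid, col0, row0, ncols, nrows in layout:
        if ncols <= 0 or nrows <= 0:
            raise ValueError(f"patch {pid} has non-positive dimensions")
        if pid == MATRIX:
            raise ValueError("patch id 0 is reserved for matrix")
        for col in range(col0, col0 + ncols):
            for row in range(row0, row0 + nrows):
                ax = offset_to_axial(col, row)
                if ax in seen:
                    raise ValueError(
                        f"patches {seen[ax]} and {pid} overlap at offset ({col}, {row})"
                    )
                seen[ax] = pid
                coords.append(ax)
                offsets.append((col, row))
                patch_ids.append(pid)
    ls = Landscape(
        np.asarray(coords),
        np.asarray(patch_ids),
        np.asarray(offsets),
        gap_edges_per_interface=gap_edges_per_interface,
    )
    return ls


def apply_epoch(landscape: Landscape, spec: EpochSpec) -> Landscape:
    """Reconfigure edge permeabilities and habitat types for an epoch.

    Idempotent for a fixed spec; switching specs back and forth restores the
    original edge set because permeabilities are recomputed from scratch.
    """
    perm = np.zeros((landscape.n_cells, 6), dtype=np.float64)
    nbr = landscape.neighbor_table
    inside = nbr >= 0
    same_patch = np.zeros_like(inside)
    safe = np.where(inside, nbr, 0)
    same_patch[inside] = (
        landscape.patch_ids[safe[inside]] == np.repeat(landscape.patch_ids, 6).reshape(-1, 6)[inside]
    )
    perm[inside & same_patch] = 1.0

    if spec.barrier_mode is BarrierMode.NONE:
        perm[inside & ~same_patch] = 1.0
    elif spec.barrier_mode is BarrierMode.ABSOLUTE:
        pass  # inter-patch edges stay at 0
    elif spec.barrier_mode is BarrierMode.GAPPED:
        for edges in landscape.gap_edges.values():
            for i, j in edges:
                di = int(np.where(nbr[i] == j)[0][0])
                dj = int(np.where(nbr[j] == i)[0][0])
                perm[i, di] = spec.gap_permeability
                perm[j, dj] = spec.gap_permeability

    habitat = np.zeros(landscape.n_cells, dtype=np.int8)
    for pid, htype in spec.habitat_assignment.items():
        habitat[landscape.patch_ids == pid] = HabitatType(htype).value
    landscape.perm = perm
    landscape.habitat_types = habitat
    landscape.epoch = spec
    landscape._perm_version += 1
    landscape._cache = {}
    return landscape


def edge_permeability(
    landscape: Landscape, frm: tuple[int, int], to: tuple[int, int]
) -> float:
    """Transmission probability for a move between two adjacent cells."""
    return landscape.permeability_between(frm, to)


def reachable_neighborhood(
    landscape: Landscape, center: tuple[int, int], radius: int
) -> set[tuple[int, int]]:
    """Habitat cells within ``radius`` passable steps of ``center``.

    The subset of the hex disk that is connected to the center through edges
    with permeability > 0 — the clipped resource/pairing neighborhood.
    """
    if not landscape.is_habitat(center):
        raise ValueError(f"{center} is not a habitat cell")
    rings = landscape.bfs_rings(radius)
    idx = landscape.cell_index(center)
    members = np.concatenate(rings[idx])
    return {(int(q), int(r)) for q, r in landscape.coords[members]}
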