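"""Atomic configurations, periodic neighbor lists and extended-XYZ I/O.

Internal units are Angstrom and eV throughout; atom indexing is 0-based.
Neighbor lists are *directed* (both (i, j) and (j, i) stored) because the
model's pair energies are asymmetric, and support cells smaller than twice
the cutoff through explicit integer-image enumeration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

_SYMBOLS = (
    "X H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe "
    "Co Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn "
    "Sb Te I Xe"
).split()


@dataclass
class AtomicSystem:
    """One configuration: species, positions, optional cell and labels."""

    symbols: list[str]
    positions: np.ndarray  # (N, 3) Angstrom
    cell: np.ndarray | None = None  # (3, 3) row vectors, Angstrom
    pbc: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=bool))
    energy: float | None = None  # eV
    forces: np.ndarray | None = None  # (N, 3) eV/Angstrom

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.pbc = np.asarray(self.pbc, dtype=bool)
        if len(self.symbols) < 1:
            raise ValueError("a system needs at least one atom")
        if self.positions.shape != (len(self.symbols), 3):
            raise ValueError("positions shape must be (N, 3)")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float)
            if self.cell.shape != (3, 3):
                raise ValueError("cell must be 3x3")
        if self.pbc.any() and self.cell is None:
            raise ValueError("periodic boundary conditions require a cell")
        if not self.pbc.any():
            self.cell = None if self.cell is None else self.cell
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != self.positions.shape:
                raise ValueError("forces shape must match positions")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def copy(self) -> "AtomicSystem":
        return AtomicSystem(
            list(self.symbols),
            self.positions.copy(),
            None if self.cell is None else self.cell.copy(),
            self.pbc.copy(),
            self.energy,
            None if self.forces is None else self.forces.copy(),
        )


class SpeciesMap:
    """Stable bijection between chemical symbols and one-hot indices."""

    def __init__(self, symbols):
        self.symbols = list(symbols)
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("duplicate species")
        self._index = {s: i for i, s in enumerate(self.symbols)}

    def __len__(self):
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise KeyError(f"species {symbol!r} not in map {self.symbols}") from None

    def encode(self, symbols) -> np.ndarray:
        return np.array([self.index(s) for s in symbols], dtype=np.intp)

    def one_hot(self, symbols) -> np.ndarray:
        idx = self.encode(symbols)
        out = np.zeros((len(idx), len(self)), dtype=float)
        out[np.arange(len(idx)), idx] = 1.0
        return out

    @staticmethod
    def from_dataset(systems) -> "SpeciesMap":
        seen = []
        for s in systems:
            for sym in s.symbols:
                if sym not in seen:
                    seen.append(sym)
        return SpeciesMap(sorted(seen, key=_SYMBOLS.index))


@dataclass
class NeighborList:
    """Directed within-cutoff pairs with periodic image shifts.

    ``pairs[k] = (i, j)`` with integer image ``shifts[k]`` such that
    ``vectors[k] = positions[j] - positions[i] + shifts[k] @ cell`` and
    ``distances[k] = ||vectors[k]|| < r_cut``.  Entries are sorted by
    ``(i, j, shift)`` so per-center reductions are reproducible.
    """

    centers: np.ndarray  # (E,)
    neighbors: np.ndarray  # (E,)
    shifts: np.ndarray  # (E, 3) int
    vectors: np.ndarray  # (E, 3)
    distances: np.ndarray  # (E,)
    r_cut: float

    @property
    def n_pairs(self) -> int:
        return len(self.centers)


def build_neighbor_list(system: AtomicSystem, r_cut: float) -> NeighborList:
    """All directed pairs with distance strictly below ``r_cut``.

    Pairs exactly at the cutoff would contribute nothing (the envelope
    vanishes there), so the strict comparison is immaterial physically and
    avoids boundary double-handling.  Periodic directions enumerate every
    integer image that can fall within the cutoff, so cells smaller than
    ``2 r_cut`` are handled exactly.
    """
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    pos = system.positions
    n = system.n_atoms
    if system.cell is not None and system.pbc.any():
        cell = system.cell
        if abs(np.linalg.det(cell)) < 1e-12:
            raise ValueError("singular cell")
        inv = np.linalg.inv(cell)
        ranges = []
        for k in range(3):
            if system.pbc[k]:
                # spacing between lattice planes normal to direction k
                spacing = 1.0 / np.linalg.norm(inv[:, k])
                ranges.append(np.arange(-int(np.ceil(r_cut / spacing)),
                                        int(np.ceil(r_cut / spacing)) + 1))
            else:
                ranges.append(np.array([0]))
        shift_grid = np.array(np.meshgrid(*ranges, indexing="ij")).reshape(3, -1).T
    else:
        cell = np.zeros((3, 3))
        shift_grid = np.zeros((1, 3), dtype=int)

    centers, neighbors, shifts, vectors, dists = [], [], [], [], []
    disp0 = pos[None, :, :] - pos[:, None, :]  # (i, j, 3): r_j - r_i
    for s in shift_grid:
        offset = s @ cell
        d = disp0 + offset
        r = np.linalg.norm(d, axis=-1)
        mask = r < r_cut
        if not s.any():
            np.fill_diagonal(mask, False)
        ii, jj = np.nonzero(mask)
        if len(ii) == 0:
            continue
        centers.append(ii)
        neighbors.append(jj)
        shifts.append(np.broadcast_to(s, (len(ii), 3)))
        vectors.append(d[ii, jj])
        dists.append(r[ii, jj])

    if centers:
        centers = np.concatenate(centers)
        neighbors = np.concatenate(neighbors)
        shifts = np.concatenate(shifts)
        vectors = np.concatenate(vectors)
        dists = np.concatenate(dists)
    else:
        centers = np.zeros(0, dtype=np.intp)
        neighbors = np.zeros(0, dtype=np.intp)
        shifts = np.zeros((0, 3), dtype=int)
        vectors = np.zeros((0, 3))
        dists = np.zeros(0)

    order = np.lexsort(
        (shifts[:, 2], shifts[:, 1], shifts[:, 0], neighbors, centers)
    )
    return NeighborList(
        centers[order].astype(np.intp),
        neighbors[order].astype(np.intp),
        shifts[order].astype(int),
        vectors[order],
        dists[order],
        float(r_cut),
    )


def average_neighbor_count(systems, r_cut: float) -> float:
    """Mean number of within-cutoff neighbors per atom over a dataset."""
    systems = list(systems)
    if not systems:
        raise ValueError("empty dataset")
    total_pairs = 0
    total_atoms = 0
    for s in systems:
        nl = build_neighbor_list(s, r_cut)
        total_pairs += nl.n_pairs
        total_atoms += s.n_atoms
    return total_pairs / total_atoms


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r'(\S+)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV_RE.finditer(line)}


def read_extxyz(path) -> list[AtomicSystem]:
    """Read every frame of an extended-XYZ file (ase-dialect keys)."""
    systems = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos_in_file = 0
    while pos_in_file < len(lines):
        header = lines[pos_in_file].strip()
        if not header:
            pos_in_file += 1
            continue
        try:
            n = int(header)
        except ValueError as e:
            raise ValueError(f"malformed atom-count line: {header!r}") from e
        if pos_in_file + 2 + n > len(lines):
            raise ValueError("truncated frame (fewer atom lines than declared)")
        info = _parse_comment(lines[pos_in_file + 1])
        props = info.get("Properties", "species:S:1:pos:R:3")
        fields = props.split(":")
        columns = [(fields[i], fields[i + 1], int(fields[i + 2]))
                   for i in range(0, len(fields), 3)]
        symbols, rows = [], []
        for line in lines[pos_in_file + 2: pos_in_file + 2 + n]:
            parts = line.split()
            expected = sum(c[2] for c in columns)
            if len(parts) != expected:
                raise ValueError(f"atom line has {len(parts)} fields, expected {expected}")
            rows.append(parts)
        col_data = {}
        start = 0
        for name, kind, width in columns:
            vals = [r[start: start + width] for r in rows]
            if kind == "S":
                col_data[name] = [v[0] for v in vals]
            else:
                col_data[name] = np.array(vals, dtype=float)
            start += width
        symbols = col_data.get("species")
        positions = col_data.get("pos")
        if symbols is None or positions is None:
            raise ValueError("Properties must include species and pos")
        cell = None
        pbc = np.zeros(3, dtype=bool)
        if "Lattice" in info:
            cell = np.array(info["Lattice"].split(), dtype=float).reshape(3, 3)
            if "pbc" in info:
                pbc = np.array([t in ("T", "True", "1") for t in info["pbc"].split()])
            else:
                pbc = np.ones(3, dtype=bool)
        energy = float(info["energy"]) if "energy" in info else None
        forces = col_data.get("forces")
        systems.append(
            AtomicSystem(symbols, positions, cell, pbc, energy, forces)
        )
        pos_in_file += 2 + n
    return systems


def write_extxyz(systems, path):
    """Write systems as extended XYZ (full float precision round-trips)."""
    if isinstance(systems, AtomicSystem):
        systems = [systems]
    with open(path, "w") as fh:
        for s in systems:
            fh.write(f"{s.n_atoms}\n")
            parts = []
            if s.cell is not None:
                flat = " ".join(repr(float(x)) for x in s.cell.ravel())
                parts.append(f'Lattice="{flat}"')
                parts.append('pbc="%s"' % " ".join("T" if b else "F" for b in s.pbc))
            props = "species:S:1:pos:R:3"
            if s.forces is not None:
                props += ":forces:R:3"
            parts.append(f"Properties={props}")
            if s.energy is not None:
                parts.append(f"energy={s.energy!r}")
            fh.write(" ".join(parts) + "\n")
            for k in range(s.n_atoms):
                cols = [s.symbols[k]] + [repr(float(x)) for x in s.positions[k]]
                if s.forces is not None:
                    cols += [repr(float(x)) for x in s.forces[k]]
                fh.write(" ".join(cols) + "\n")
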