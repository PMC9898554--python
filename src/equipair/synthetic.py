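"""Seeded generation of labelled configurations from analytic toy potentials.

Every other module is testable without any external dataset: dimer scans,
random liquids and perturbed crystals are labelled with pairwise
Lennard-Jones or Morse energies and their exact analytic forces.  The toy
potentials are smoothly truncated with the same polynomial envelope family
as the model's radial basis, so the reference labels are themselves
strictly local and, in principle, learnable to near-zero error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .irreps import RotationOp
from .radial import RadialBasisSpec
from .system import AtomicSystem, build_neighbor_list

_HARD_FLOOR = 1e-3  # Angstrom; below this two atoms are considered overlapping


@dataclass(frozen=True)
class ToyPotentialSpec:
    """An analytic pairwise reference potential.

    ``params`` holds the global parameters (``eps``/``sigma`` in eV and
    Angstrom for Lennard-Jones; ``De``/``a``/``re`` for Morse);
    ``pair_params`` optionally overrides them per unordered species pair.
    With ``smooth=True`` the pair term is multiplied by the polynomial
    envelope with exponent ``envelope_p``, making energy and forces
    exactly zero at the cutoff.
    """

    kind: str = "lennard_jones"  # "lennard_jones" | "morse"
    params: dict = field(default_factory=lambda: {"eps": 1.0, "sigma": 1.0})
    pair_params: dict = field(default_factory=dict)
    r_cut: float = 6.0
    smooth: bool = True
    envelope_p: int = 6

    def __post_init__(self):
        if self.kind not in ("lennard_jones", "morse"):
            raise ValueError(f"unknown potential {self.kind!r}")
        for v in self.params.values():
            if v <= 0:
                raise ValueError("potential parameters must be positive")

    def _params_for(self, s1: str, s2: str) -> dict:
        key = tuple(sorted((s1, s2)))
        return {**self.params, **self.pair_params.get(key, {})}

    def pair_energy_force(self, r: np.ndarray, s1: str, s2: str):
        """V(r) and dV/dr for one species pair (vectorized over r)."""
        r = np.asarray(r, dtype=float)
        if np.any(r < _HARD_FLOOR):
            raise ValueError("overlapping atoms (below hard floor)")
        p = self._params_for(s1, s2)
        if self.kind == "lennard_jones":
            s6 = (p["sigma"] / r) ** 6
            v = 4.0 * p["eps"] * (s6 ** 2 - s6)
            dv = 4.0 * p["eps"] * (-12.0 * s6 ** 2 + 6.0 * s6) / r
        else:
            e = np.exp(-p["a"] * (r - p["re"]))
            v = p["De"] * ((1.0 - e) ** 2 - 1.0)
            dv = 2.0 * p["De"] * p["a"] * e * (1.0 - e)
        if self.smooth:
            u, du = _envelope_np(r, self.r_cut, self.envelope_p)
            v, dv = v * u, dv * u + v * du
        return v, dv


def _envelope_np(r, r_cut, p):
    """Polynomial envelope and its derivative (plain numpy)."""
    d = np.asarray(r) / r_cut
    p = float(p)
    u = (
        1.0
        - (p + 1.0) * (p + 2.0) / 2.0 * d ** p
        + p * (p + 2.0) * d ** (p + 1.0)
        - p * (p + 1.0) / 2.0 * d ** (p + 2.0)
    )
    du = (
        -(p + 1.0) * (p + 2.0) / 2.0 * p * d ** (p - 1.0)
        + p * (p + 2.0) * (p + 1.0) * d ** p
        - p * (p + 1.0) / 2.0 * (p + 2.0) * d ** (p + 1.0)
    ) / r_cut
    inside = d < 1.0
    return np.where(inside, u, 0.0), np.where(inside, du, 0.0)


def toy_labels(system: AtomicSystem, spec: ToyPotentialSpec) -> AtomicSystem:
    """Attach pairwise analytic energy and exact forces to a copy of ``system``."""
    nl = build_neighbor_list(system, spec.r_cut)
    energy = 0.0
    forces = np.zeros_like(system.positions)
    if nl.n_pairs:
        v = np.zeros(nl.n_pairs)
        dv = np.zeros(nl.n_pairs)
        syms = np.array(system.symbols)
        for s1 in set(system.symbols):
            for s2 in set(system.symbols):
                mask = (syms[nl.centers] == s1) & (syms[nl.neighbors] == s2)
                if mask.any():
                    v[mask], dv[mask] = spec.pair_energy_force(
                        nl.distances[mask], s1, s2
                    )
        energy = 0.5 * float(v.sum())
        unit = nl.vectors / nl.distances[:, None]
        np.add.at(forces, nl.centers, dv[:, None] * unit)
    out = system.copy()
    out.energy = energy
    out.forces = forces
    return out


@dataclass(frozen=True)
class GeneratorSpec:
    """Random-configuration generator settings."""

    n_frames: int = 1
    n_atoms: int = 8
    composition: tuple = (("X", 1),)  # (symbol, relative count) pairs
    box: float = 8.0  # cubic box edge, Angstrom
    periodic: bool = False
    min_distance: float = 1.0
    jitter: float = 0.0  # Gaussian displacement amplitude for lattices
    seed: int = 0
    max_tries: int = 2000

    def symbols(self) -> list[str]:
        total = sum(c for _, c in self.composition)
        out = []
        for sym, c in self.composition:
            out.extend([sym] * round(self.n_atoms * c / total))
        while len(out) < self.n_atoms:
            out.append(self.composition[0][0])
        return out[: self.n_atoms]


def generate(gen: GeneratorSpec, pot: ToyPotentialSpec) -> list[AtomicSystem]:
    """Labelled random configurations honoring the minimum-distance constraint."""
    if gen.min_distance <= 0:
        raise ValueError("min_distance must be positive")
    if gen.min_distance > gen.box:
        raise ValueError("min_distance larger than the box")
    rng = np.random.default_rng(gen.seed)
    cell = np.eye(3) * gen.box if gen.periodic else None
    pbc = [gen.periodic] * 3
    frames = []
    for _ in range(gen.n_frames):
        pos = _place_atoms(rng, gen, cell)
        s = AtomicSystem(gen.symbols(), pos, cell, pbc)
        frames.append(toy_labels(s, pot))
    return frames


def _place_atoms(rng, gen: GeneratorSpec, cell):
    pos = np.zeros((0, 3))
    tries = 0
    while len(pos) < gen.n_atoms:
        cand = rng.uniform(0, gen.box, size=3)
        if _min_dist(cand, pos, cell, gen.periodic) >= gen.min_distance:
            pos = np.vstack([pos, cand])
        else:
            tries += 1
            if tries > gen.max_tries:
                raise RuntimeError(
                    f"rejection sampling failed after {gen.max_tries} tries; "
                    "the minimum-distance constraint is infeasible in this box"
                )
    if gen.jitter > 0:
        pos = pos + rng.normal(scale=gen.jitter, size=pos.shape)
    return pos


def _min_dist(cand, pos, cell, periodic):
    if len(pos) == 0:
        return np.inf
    d = pos - cand
    if periodic:
        frac = d @ np.linalg.inv(cell)
        frac -= np.round(frac)
        d = frac @ cell
    return np.linalg.norm(d, axis=1).min()


# ---------------------------------------------------------------------------
# fixture palette
# ---------------------------------------------------------------------------

def dimer_scan(pot: ToyPotentialSpec, symbols=("X", "X"), n: int = 50,
               r_min: float = 0.85, r_max: float = 2.5) -> list[AtomicSystem]:
    """Labelled dimer at ``n`` distances (units of the potential minimum)."""
    frames = []
    for r in np.linspace(r_min, r_max, n):
        s = AtomicSystem(list(symbols), [[0, 0, 0], [0, 0, r]])
        frames.append(toy_labels(s, pot))
    return frames


def simple_cubic(symbol="X", a=2.0, reps=2, jitter=0.0, seed=0,
                 vacancy=False) -> AtomicSystem:
    rng = np.random.default_rng(seed)
    pts = np.array(
        [[i, j, k] for i in range(reps) for j in range(reps) for k in range(reps)],
        dtype=float,
    ) * a
    if vacancy:
        pts = pts[1:]
    if jitter > 0:
        pts = pts + rng.normal(scale=jitter, size=pts.shape)
    return AtomicSystem([symbol] * len(pts), pts, np.eye(3) * a * reps, [True] * 3)


def fcc(symbol="Ag", a=3.6, reps=1, jitter=0.0, seed=0, vacancy=False) -> AtomicSystem:
    rng = np.random.default_rng(seed)
    motif = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
    pts = []
    for i in range(reps):
        for j in range(reps):
            for k in range(reps):
                pts.append((motif + [i, j, k]) * a)
    pts = np.vstack(pts)
    if vacancy:
        pts = pts[1:]
    if jitter > 0:
        pts = pts + rng.normal(scale=jitter, size=pts.shape)
    return AtomicSystem([symbol] * len(pts), pts, np.eye(3) * a * reps, [True] * 3)


def three_species_liquid(n_frames=10, n_atoms=8, box=6.0, seed=0,
                         pot: ToyPotentialSpec | None = None) -> list[AtomicSystem]:
    """Random liquid with a 3:1:4 Li/P/O-like composition."""
    if pot is None:
        pot = ToyPotentialSpec(
            "lennard_jones", {"eps": 0.4, "sigma": 1.8}, r_cut=4.0, envelope_p=6
        )
    gen = GeneratorSpec(
        n_frames=n_frames, n_atoms=n_atoms,
        composition=(("Li", 3), ("P", 1), ("O", 4)), box=box,
        min_distance=1.4, seed=seed,
    )
    return generate(gen, pot)


# ---------------------------------------------------------------------------
# symmetry variants
# ---------------------------------------------------------------------------

def symmetry_variants(system: AtomicSystem, seed: int = 0, n_rotations: int = 2):
    """Transformed labelled copies: rotations, inversion, translation, permutation.

    Returns ``(tag, transformed_system)`` pairs; energies are unchanged and
    forces are transformed consistently, so these are direct test inputs
    for the equivariance property.
    """
    if system.forces is None or system.energy is None:
        raise ValueError("system must carry labels")
    rng = np.random.default_rng(seed)
    out = [("identity", system.copy())]
    for k in range(n_rotations):
        R = RotationOp.random(rng)
        s = system.copy()
        s.positions = R.apply_points(s.positions)
        s.forces = R.apply_points(s.forces)
        if s.cell is not None:
            s.cell = s.cell @ R.matrix.T
        out.append((f"rotation{k}", s))
    s = system.copy()
    s.positions = -s.positions
    s.forces = -s.forces
    if s.cell is not None:
        s.cell = -s.cell
    out.append(("inversion", s))
    s = system.copy()
    t = rng.normal(scale=1.0, size=3)
    s.positions = s.positions + t
    out.append(("translation", s))
    s = system.copy()
    perm = rng.permutation(system.n_atoms)
    s.symbols = [system.symbols[i] for i in perm]
    s.positions = system.positions[perm]
    s.forces = system.forces[perm]
    out.append(("permutation", s))
    return out
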