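"""Minimal molecular dynamics and the structural/kinetic observables.

A velocity-Verlet integrator (NVE, or NVT via Berendsen velocity
rescaling) drives any energy/force provider — a trained model or an
analytic toy potential.  Observables are the radial distribution function
g(r), the neighbor-center-neighbor angular distribution, and the
mean-square displacement, all computed from unwrapped trajectories.

Units: Angstrom, eV, fs, amu, Kelvin.  The acceleration conversion
constant is ``1 eV/Angstrom/amu = 9.648533e-3 Angstrom/fs^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AllegroModel
from .synthetic import ToyPotentialSpec, toy_labels
from .system import AtomicSystem, build_neighbor_list

EV_PER_A_AMU = 9.648533290731905e-3  # Angstrom / fs^2 per (eV/Angstrom / amu)
KB_EV = 8.617333262e-5  # eV / K

_MASSES = {
    "X": 1.0, "H": 1.008, "He": 4.0026, "Li": 6.94, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Na": 22.990, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Cu": 63.546, "Ag": 107.87,
}


def atomic_masses(symbols) -> np.ndarray:
    return np.array([_MASSES.get(s, 1.0) for s in symbols])


def as_calculator(potential):
    """Adapt a model or toy-potential spec to ``f(system) -> (E, forces)``."""
    if isinstance(potential, AllegroModel):
        def calc(system):
            out = potential.predict(system)
            return out.total_energy, out.forces
        return calc
    if isinstance(potential, ToyPotentialSpec):
        def calc(system):
            labelled = toy_labels(system, potential)
            return labelled.energy, labelled.forces
        return calc
    if callable(potential):
        return potential
    raise TypeError("potential must be a model, toy spec, or callable")


@dataclass
class Trajectory:
    """Frames of one MD run with unwrapped coordinates.

    ``positions`` has shape (n_frames, N, 3); species ordering is constant
    across frames.  ``potential_energy`` and ``kinetic_energy`` are per
    frame (eV).
    """

    symbols: list[str]
    positions: np.ndarray
    timestep: float  # fs
    thermostat: str
    cell: np.ndarray | None = None
    pbc: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=bool))
    potential_energy: np.ndarray | None = None
    kinetic_energy: np.ndarray | None = None

    @property
    def n_frames(self):
        return len(self.positions)

    def total_energy(self):
        return self.potential_energy + self.kinetic_energy

    def frame(self, k) -> AtomicSystem:
        return AtomicSystem(
            self.symbols, self.positions[k],
            None if self.cell is None else self.cell, self.pbc,
        )


def velocity_verlet(system: AtomicSystem, potential, dt: float, n_steps: int,
                    thermostat: str = "none", temperature: float | None = None,
                    tau: float = 100.0, velocities: np.ndarray | None = None,
                    seed: int = 0, sample_every: int = 1) -> Trajectory:
    """Integrate Newton's equations with velocity Verlet.

    ``thermostat="none"`` is NVE and conserves the total energy up to
    integration error; ``"berendsen"`` rescales velocities toward
    ``temperature`` with time constant ``tau`` (fs).  Initial velocities
    default to zero, or are drawn Maxwell-Boltzmann when ``temperature``
    is given and no velocities are passed (seeded).
    """
    if thermostat not in ("none", "berendsen"):
        raise ValueError("thermostat must be 'none' or 'berendsen'")
    if thermostat == "berendsen" and temperature is None:
        raise ValueError("berendsen thermostat needs a target temperature")
    calc = as_calculator(potential)
    masses = atomic_masses(system.symbols)
    n = system.n_atoms
    pos = system.positions.copy()
    if velocities is not None:
        vel = np.asarray(velocities, dtype=float).copy()
    elif temperature is not None:
        rng = np.random.default_rng(seed)
        vel = rng.normal(size=(n, 3)) * np.sqrt(
            KB_EV * temperature / masses
        )[:, None] * np.sqrt(EV_PER_A_AMU)
        vel -= vel.mean(axis=0)
    else:
        vel = np.zeros((n, 3))

    def make_system(p):
        return AtomicSystem(system.symbols, p,
                            None if system.cell is None else system.cell,
                            system.pbc)

    e_pot, forces = calc(make_system(pos))
    if not np.all(np.isfinite(forces)):
        raise RuntimeError("non-finite forces at the initial configuration")
    frames, e_pots, e_kins = [pos.copy()], [e_pot], [_kinetic(vel, masses)]
    acc = forces / masses[:, None] * EV_PER_A_AMU
    for step in range(1, n_steps + 1):
        pos = pos + vel * dt + 0.5 * acc * dt ** 2
        e_pot, forces = calc(make_system(pos))
        if not np.all(np.isfinite(forces)):
            raise RuntimeError(f"non-finite forces at step {step}")
        new_acc = forces / masses[:, None] * EV_PER_A_AMU
        vel = vel + 0.5 * (acc + new_acc) * dt
        acc = new_acc
        if thermostat == "berendsen":
            t_now = _temperature(vel, masses)
            if t_now > 0:
                lam = np.sqrt(1.0 + dt / tau * (temperature / t_now - 1.0))
                vel = vel * lam
        if step % sample_every == 0:
            frames.append(pos.copy())
            e_pots.append(e_pot)
            e_kins.append(_kinetic(vel, masses))
    return Trajectory(
        list(system.symbols), np.array(frames), dt * sample_every, thermostat,
        None if system.cell is None else system.cell.copy(), system.pbc.copy(),
        np.array(e_pots), np.array(e_kins),
    )


def _kinetic(vel, masses):
    return float(0.5 * np.sum(masses[:, None] * vel ** 2) / EV_PER_A_AMU)


def _temperature(vel, masses):
    n_dof = 3 * len(masses)
    return 2.0 * _kinetic(vel, masses) / (n_dof * KB_EV)


def energy_drift(traj: Trajectory) -> float:
    """Maximum relative deviation of the total energy from its initial value."""
    e = traj.total_energy()
    scale = max(abs(e[0]), 1e-12)
    return float(np.abs(e - e[0]).max() / scale)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObservableSpec:
    """Binning and selection settings for RDF / ADF / MSD."""

    rdf_r_max: float = 10.0
    rdf_bin_width: float = 0.05  # Angstrom
    adf_central_species: str | None = None
    adf_cutoff: float = 2.5  # Angstrom
    adf_bin_width: float = 2.0  # degrees
    msd_species: str | None = None
    msd_origin_stride: int = 1

    def __post_init__(self):
        if min(self.rdf_bin_width, self.adf_bin_width) <= 0:
            raise ValueError("bin widths must be positive")


def _frames_of(traj):
    if isinstance(traj, Trajectory):
        return [traj.frame(k) for k in range(traj.n_frames)]
    return list(traj)


def rdf(traj, spec: ObservableSpec):
    """All-atom radial distribution function g(r) as a probability density.

    Estimator: per-frame histogram of directed pair distances, normalized
    by the ideal-gas shell count ``(N-1)/V * 4 pi r^2 dr`` per atom at the
    frame's density, averaged over frames.  Returns ``(bin_centers, g)``.
    Requires ``r_max`` at most half the smallest cell extent for periodic
    frames (minimum-image validity).
    """
    frames = _frames_of(traj)
    edges = np.arange(0.0, spec.rdf_r_max + spec.rdf_bin_width, spec.rdf_bin_width)
    centers = 0.5 * (edges[1:] + edges[:-1])
    acc = np.zeros(len(centers))
    for s in frames:
        if s.cell is not None and s.pbc.any():
            inv = np.linalg.inv(s.cell)
            for k in range(3):
                if s.pbc[k]:
                    half = 0.5 / np.linalg.norm(inv[:, k])
                    if spec.rdf_r_max > half + 1e-12:
                        raise ValueError(
                            f"rdf r_max {spec.rdf_r_max} exceeds half cell extent {half:.3f}"
                        )
            volume = abs(np.linalg.det(s.cell))
        else:
            # open boundaries: nominal, rotation-invariant reference volume
            # from the bounding sphere of the configuration
            center = s.positions.mean(axis=0)
            radius = np.linalg.norm(s.positions - center, axis=1).max()
            volume = 4.0 / 3.0 * np.pi * (radius + 0.5 * spec.rdf_r_max) ** 3
        nl = build_neighbor_list(s, spec.rdf_r_max)
        hist, _ = np.histogram(nl.distances, bins=edges)
        n = s.n_atoms
        shell = 4.0 * np.pi * centers ** 2 * spec.rdf_bin_width
        ideal = n * (n - 1) / volume * shell
        acc += hist / np.maximum(ideal, 1e-300)
    return centers, acc / len(frames)


def adf(traj, spec: ObservableSpec):
    """Angular distribution of neighbor-center-neighbor triplets.

    Both neighbors must lie within ``adf_cutoff`` of the central atom
    (optionally restricted to ``adf_central_species``).  Each unordered
    neighbor pair contributes one angle (no double counting).  Returns
    ``(bin_centers_deg, density)`` with the density integrating to one
    over [0, 180] degrees.
    """
    frames = _frames_of(traj)
    edges = np.arange(0.0, 180.0 + spec.adf_bin_width, spec.adf_bin_width)
    centers = 0.5 * (edges[1:] + edges[:-1])
    angles = []
    for s in frames:
        nl = build_neighbor_list(s, spec.adf_cutoff)
        for i in range(s.n_atoms):
            if (spec.adf_central_species is not None
                    and s.symbols[i] != spec.adf_central_species):
                continue
            vecs = nl.vectors[nl.centers == i]
            for a in range(len(vecs)):
                for b in range(a + 1, len(vecs)):
                    cosang = np.dot(vecs[a], vecs[b]) / (
                        np.linalg.norm(vecs[a]) * np.linalg.norm(vecs[b])
                    )
                    angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    hist, _ = np.histogram(angles, bins=edges)
    total = hist.sum()
    if total == 0:
        return centers, np.zeros(len(centers))
    return centers, hist / (total * spec.adf_bin_width)


def msd(traj: Trajectory, species: str | None = None,
        origin_stride: int | None = None):
    """Mean-square displacement vs time from unwrapped coordinates.

    Averages over the selected atoms and over multiple time origins
    spaced ``origin_stride`` frames apart.  Returns ``(t_fs, msd_A2)``
    with ``msd[0] == 0``.
    """
    pos = traj.positions
    if species is not None:
        sel = [k for k, s in enumerate(traj.symbols) if s == species]
        if not sel:
            raise ValueError(f"no atoms of species {species!r}")
        pos = pos[:, sel]
    n_frames = len(pos)
    stride = origin_stride or max(1, n_frames // 10)
    out = np.zeros(n_frames)
    counts = np.zeros(n_frames)
    for origin in range(0, n_frames, stride):
        disp = pos[origin:] - pos[origin]
        sq = (disp ** 2).sum(axis=-1).mean(axis=-1)
        out[: len(sq)] += sq
        counts[: len(sq)] += 1
    valid = counts > 0
    out[valid] /= counts[valid]
    t = np.arange(n_frames) * traj.timestep
    return t[valid], out[valid]


# ---------------------------------------------------------------------------
# receptive field
# ---------------------------------------------------------------------------

def receptive_field(n_layers: int, r_cut: float,
                    architecture: str = "strictly_local") -> float:
    """Effective interaction radius of a deep potential.

    Atom-centered message passing grows the receptive field linearly with
    depth (``n_layers * r_cut``); a strictly local pairwise model keeps it
    at ``r_cut`` regardless of depth, which is what makes spatial
    decomposition cheap.
    """
    if n_layers < 1 or r_cut <= 0:
        raise ValueError("need n_layers >= 1 and r_cut > 0")
    if architecture == "message_passing":
        return n_layers * r_cut
    if architecture == "strictly_local":
        return r_cut
    raise ValueError(f"unknown architecture {architecture!r}")


def neighbor_volume_ratio(r_eff: float, r_cut: float) -> float:
    """Volume ratio (r_eff / r_cut)^3 — the factor of extra atomic state a
    worker must hold under message passing relative to a local model."""
    return (r_eff / r_cut) ** 3
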