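"""The strictly local equivariant pair-energy model.

Every ordered pair of neighboring atoms (i, j) carries two latent tracks:
an invariant scalar vector ``x^{ij,L}`` and equivariant features
``V^{ij,L}`` grouped into irrep blocks.  Each layer embeds the central
atom's environment as a learned weighted sum of neighbor spherical
harmonics, couples it to the pair features through a Wigner-3j tensor
product, feeds the scalar path outputs back into the scalar track
(residually, with the cutoff envelope), and linearly mixes the
equivariant path outputs per output irrep.  The final scalar track is
read out as a pair energy; per-atom and total energies are envelope-
smooth sums, and forces are exact gradients through the autodiff engine.

The total energy is ``E = sum_i sigma_{Z_i} E_i + mu_{Z_i}`` with
``E_i = (sum_j sigma_{Z_i Z_j} E_ij) / sqrt(<|N(i)|>)``, which keeps the
model size-extensive.

Internal normalization keeps activations near unit variance: every
linear map divides by ``sqrt(fan_in)``, neighbor sums divide by the
square root of the dataset-average neighbor count, path mixing divides
by the square root of the number of contributing path-channel terms, and
the residual update divides by ``sqrt(2)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor
from .irreps import (
    Irrep,
    IrrepBlockArray,
    IrrepLayout,
    enumerate_paths,
    real_spherical_harmonics,
    tensor_product,
)
from .radial import RadialBasis, RadialBasisSpec, envelope
from .system import AtomicSystem, SpeciesMap, build_neighbor_list


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AllegroConfig:
    """Complete architectural description; reconstructs the model exactly.

    ``two_body_dims`` and ``latent_dims`` list the output widths of every
    linear layer of the respective MLPs (bias-free; SiLU between layers,
    none after the last); the final width of both is the scalar latent
    width.  ``parity="se3"`` omits parity bookkeeping entirely;
    ``parity="e3"`` tracks both parities for every rotation order.
    """

    species: list[str] = field(default_factory=lambda: ["X"])
    r_cut: float = 4.0
    n_layers: int = 1
    ell_max: int = 1
    parity: str = "se3"  # "se3" | "e3"
    n_equivariant: int = 1
    two_body_dims: tuple = (32, 64)
    latent_dims: tuple = (64,)
    output_hidden: int = 32
    two_body_nonlinearity: str = "silu"
    latent_nonlinearity: str = "silu"  # "silu" | "linear"
    n_basis: int = 8
    envelope_p: int = 48
    trainable_basis: bool = False
    avg_num_neighbors: float = 1.0
    path_mode: str = "all_allowed"
    trainable_shifts: bool = False
    trainable_scales: bool = False
    seed: int = 0

    def __post_init__(self):
        self.two_body_dims = tuple(int(d) for d in self.two_body_dims)
        self.latent_dims = tuple(int(d) for d in self.latent_dims)
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.ell_max < 0:
            raise ValueError("ell_max must be >= 0")
        if self.parity not in ("se3", "e3"):
            raise ValueError("parity mode must be 'se3' or 'e3'")
        if min(self.two_body_dims + self.latent_dims + (self.output_hidden,
                                                        self.n_equivariant)) < 1:
            raise ValueError("all widths must be >= 1")
        if self.two_body_dims[-1] != self.latent_dims[-1]:
            raise ValueError("two-body and latent MLPs must share the final width")

    @property
    def latent_width(self) -> int:
        return self.latent_dims[-1]

    @property
    def use_parity(self) -> bool:
        return self.parity == "e3"

    def radial_spec(self) -> RadialBasisSpec:
        return RadialBasisSpec(
            self.n_basis, self.r_cut, self.envelope_p, self.trainable_basis
        )

    def y_layout(self) -> IrrepLayout:
        return IrrepLayout.spherical(self.ell_max, use_parity=self.use_parity)

    def v_layout(self) -> IrrepLayout:
        n = self.n_equivariant
        if self.use_parity:
            blocks = [
                (n, Irrep(l, p))
                for l in range(self.ell_max + 1)
                for p in (1, -1)
            ]
        else:
            blocks = [(n, Irrep(l, None)) for l in range(self.ell_max + 1)]
        return IrrepLayout(blocks)

    def env_layout(self) -> IrrepLayout:
        n = self.n_equivariant
        return IrrepLayout(
            [(n, ir) for _, ir in self.y_layout().blocks]
        )

    def paths(self):
        """Tensor-product paths of a (non-final) layer, in canonical order."""
        return enumerate_paths(
            self.v_layout(), self.env_layout(), self.ell_max, self.path_mode
        )

    def scalar_paths(self):
        return [p for p in self.paths() if p.is_scalar_out]

    # -- reference configurations ------------------------------------------
    @staticmethod
    def lithium_phosphate() -> "AllegroConfig":
        """Small production model for the Li3PO4 solid electrolyte."""
        return AllegroConfig(
            species=["Li", "P", "O"], r_cut=4.0, n_layers=1, ell_max=1,
            parity="se3", n_equivariant=1, two_body_dims=(32, 64),
            latent_dims=(64,), output_hidden=32, n_basis=8, envelope_p=48,
        )

    @staticmethod
    def silver() -> "AllegroConfig":
        """Small production model for bulk Ag with a vacancy."""
        return AllegroConfig(
            species=["Ag"], r_cut=4.0, n_layers=1, ell_max=1,
            parity="se3", n_equivariant=1, two_body_dims=(16, 32),
            latent_dims=(32,), output_hidden=32, n_basis=8, envelope_p=48,
        )

    @staticmethod
    def qm9(n_layers: int = 1) -> "AllegroConfig":
        """Large molecular models (1 layer with l_max=3, 3 layers with 2)."""
        if n_layers not in (1, 3):
            raise ValueError("reference molecular configs have 1 or 3 layers")
        return AllegroConfig(
            species=["H", "C", "N", "O", "F"], r_cut=10.0, n_layers=n_layers,
            ell_max=3 if n_layers == 1 else 2, parity="se3",
            n_equivariant=256, two_body_dims=(128, 256, 512, 1024),
            latent_dims=(1024, 1024, 1024), output_hidden=128, n_basis=8,
            envelope_p=6, trainable_shifts=True,
        )


@dataclass
class NormStats:
    """Per-species target normalization and the average neighbor count."""

    shift: np.ndarray  # mu_Z, eV
    scale: np.ndarray  # sigma_Z, eV
    pair_scale: np.ndarray | None = None  # sigma_{Z_i Z_j}
    avg_num_neighbors: float = 1.0

    def __post_init__(self):
        self.shift = np.asarray(self.shift, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("sigma_Z must be positive")


@dataclass
class EnergyBreakdown:
    """Energies at every level of the decomposition, plus forces."""

    pair_energies: np.ndarray  # E_ij per directed pair (eV)
    atom_energies: np.ndarray  # E_i per atom (eV), sigma/mu applied
    total_energy: float  # eV
    forces: np.ndarray  # (N, 3) eV/Angstrom


@dataclass
class PairState:
    """Working state of all directed pairs at one layer."""

    x: Tensor  # (E, latent_width)
    V: IrrepBlockArray  # blocks (E, n_equivariant, 2l+1)


# ---------------------------------------------------------------------------
# batched graph
# ---------------------------------------------------------------------------

@dataclass
class Graph:
    """Concatenated neighbor graphs of one or more configurations."""

    species_idx: np.ndarray  # (N,)
    positions: np.ndarray  # (N, 3)
    centers: np.ndarray  # (E,)
    neighbors: np.ndarray  # (E,)
    offsets: np.ndarray  # (E, 3) periodic shift . cell, Angstrom
    frame_of_atom: np.ndarray  # (N,)
    n_frames: int
    n_atoms_per_frame: np.ndarray  # (n_frames,)


def make_graph(systems, species_map: SpeciesMap, r_cut: float) -> Graph:
    if isinstance(systems, AtomicSystem):
        systems = [systems]
    sp, pos, cen, nei, off, frame = [], [], [], [], [], []
    base = 0
    for f, s in enumerate(systems):
        nl = build_neighbor_list(s, r_cut)
        sp.append(species_map.encode(s.symbols))
        pos.append(s.positions)
        cen.append(nl.centers + base)
        nei.append(nl.neighbors + base)
        cell = s.cell if s.cell is not None else np.zeros((3, 3))
        off.append(nl.shifts @ cell)
        frame.append(np.full(s.n_atoms, f, dtype=np.intp))
        base += s.n_atoms
    return Graph(
        np.concatenate(sp),
        np.concatenate(pos),
        np.concatenate(cen).astype(np.intp),
        np.concatenate(nei).astype(np.intp),
        np.concatenate(off),
        np.concatenate(frame),
        len(systems),
        np.array([s.n_atoms for s in systems]),
    )


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

def _mlp(x: Tensor, weights, nonlinearity: str) -> Tensor:
    for k, W in enumerate(weights):
        x = ad.einsum("ei,io->eo", x, W) * (1.0 / np.sqrt(W.shape[0]))
        if nonlinearity == "silu" and k < len(weights) - 1:
            x = ad.silu(x)
    return x


class AllegroModel:
    """A concrete parameterization of the architecture in :class:`AllegroConfig`.

    Parameters are stored as a flat name -> Tensor dict; weights are drawn
    from a uniform distribution of unit variance and rescaled by
    ``1/sqrt(fan_in)`` at application time.
    """

    def __init__(self, config: AllegroConfig, norm: NormStats | None = None):
        self.config = config
        self.species_map = SpeciesMap(config.species)
        self.basis = RadialBasis(config.radial_spec())
        if norm is None:
            s = len(config.species)
            norm = NormStats(
                np.zeros(s), np.ones(s), None, config.avg_num_neighbors
            )
        self.norm = norm
        self._paths = config.paths()
        self._scalar_paths = [p for p in self._paths if p.is_scalar_out]
        self.params: dict[str, Tensor] = {}
        self._init_params()

    # -- parameters --------------------------------------------------------
    def _add_param(self, name, shape, rng):
        data = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=shape)
        self.params[name] = Tensor(data, requires_grad=True)

    def _init_params(self):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        s = len(cfg.species)
        width = cfg.latent_width
        n_y = len(cfg.y_layout())
        n_env = cfg.n_equivariant * n_y

        dims = (2 * s + cfg.n_basis,) + cfg.two_body_dims
        for k in range(len(cfg.two_body_dims)):
            self._add_param(f"two_body.W{k}", (dims[k], dims[k + 1]), rng)

        for layer in range(cfg.n_layers + 1):  # 0 = initial pair embedding
            self._add_param(f"embed.{layer}.W", (width, n_env), rng)

        n_scalar = len(self._scalar_paths) * cfg.n_equivariant
        ldims = (width + n_scalar,) + cfg.latent_dims
        for layer in range(1, cfg.n_layers + 1):
            for k in range(len(cfg.latent_dims)):
                self._add_param(f"latent.{layer}.W{k}", (ldims[k], ldims[k + 1]), rng)

        for layer in range(1, cfg.n_layers + 1):
            final = layer == cfg.n_layers
            for out_ir, group in self._path_groups(final):
                self._add_param(
                    f"mix.{layer}.{out_ir}",
                    (cfg.n_equivariant, len(group) * cfg.n_equivariant),
                    rng,
                )

        self._add_param("output.W0", (width, cfg.output_hidden), rng)
        self._add_param("output.W1", (cfg.output_hidden, 1), rng)

        if cfg.trainable_shifts:
            self.params["shift"] = Tensor(self.norm.shift.copy(), requires_grad=True)
        if cfg.trainable_scales:
            self.params["scale"] = Tensor(self.norm.scale.copy(), requires_grad=True)
        if cfg.trainable_basis:
            freqs = np.arange(1, cfg.n_basis + 1) * np.pi / cfg.r_cut
            self.params["basis.freq"] = Tensor(freqs, requires_grad=True)

    def _path_groups(self, final: bool):
        """Paths grouped by output irrep in canonical V-layout order.

        Final layers keep only scalar-output paths: nothing downstream
        consumes higher-order features of the last layer.
        """
        paths = self._scalar_paths if final else self._paths
        groups = {}
        for p in paths:
            groups.setdefault(p.irrep_out, []).append(p)
        ordered = [
            (ir, groups[ir])
            for _, ir in self.config.v_layout().blocks
            if ir in groups
        ]
        if not final and len(ordered) != len(self.config.v_layout().blocks):
            raise RuntimeError("some equivariant block receives no tensor-product path")
        return ordered

    def count_parameters(self):
        """Total trainable scalars with an itemized per-component breakdown."""
        breakdown = {name: int(np.prod(t.shape)) for name, t in self.params.items()}
        return sum(breakdown.values()), breakdown

    # -- forward -----------------------------------------------------------
    def forward_graph(self, graph: Graph, positions: Tensor | None = None,
                      return_state: bool = False, env_scale: float = 1.0):
        """Run the network on a batched graph.

        Returns a dict with per-frame energies, per-pair/per-atom energies
        and (with ``return_state``) all intermediate layer states, which
        the verification oracles consume.  ``env_scale`` multiplies every
        neighbor's contribution to the environment embedding (used by the
        body-order probe; 1.0 for normal operation).
        """
        cfg = self.config
        n_eq = cfg.n_equivariant
        if positions is None:
            positions = Tensor(graph.positions, requires_grad=True)
        pos_i = ad.take(positions, graph.centers)
        pos_j = ad.take(positions, graph.neighbors)
        r_vec = pos_j - pos_i + Tensor(graph.offsets)
        r = ((r_vec ** 2).sum(axis=-1)) ** 0.5  # (E,)
        u = envelope(r, self.basis.spec)  # (E,)
        u_col = ad.reshape(u, (u.shape[0], 1))

        onehot = self.species_map.one_hot(
            [self.species_map.symbols[k] for k in graph.species_idx]
        )
        oh_i = Tensor(onehot[graph.centers])
        oh_j = Tensor(onehot[graph.neighbors])
        freqs = self.params.get("basis.freq")
        basis = self.basis(r, frequencies=freqs)  # (E, n_basis)

        two_body_in = ad.concat([oh_i, oh_j, basis], axis=-1)
        x = _mlp(
            two_body_in,
            [self.params[f"two_body.W{k}"] for k in range(len(cfg.two_body_dims))],
            cfg.two_body_nonlinearity,
        ) * u_col  # x^{ij,0}

        harmonics = real_spherical_harmonics(
            cfg.ell_max, r_vec, use_parity=cfg.use_parity
        )

        def env_weights(layer, xs):
            W = self.params[f"embed.{layer}.W"]
            w = ad.einsum("ei,io->eo", xs, W) * (1.0 / np.sqrt(W.shape[0]))
            return ad.reshape(w, (w.shape[0], n_eq, len(cfg.y_layout())))

        # initial equivariant features: V0 blocks exist for every irrep in
        # the V layout; blocks whose irrep has no harmonic (odd-parity
        # mismatch in e3 mode) start at zero.
        w0 = env_weights(0, x)
        v_layout = cfg.v_layout()
        y_index = {ir: b for b, (_, ir) in enumerate(cfg.y_layout().blocks)}
        n_edges = len(graph.centers)
        v_blocks = []
        for _, ir in v_layout.blocks:
            probe = Irrep(ir.ell, ir.parity)
            if probe in y_index:
                b = y_index[probe]
                yb = harmonics.blocks[b]  # (E, 1, dim)
                blk = ad.reshape(w0[:, :, b], (n_edges, n_eq, 1)) * yb
            else:
                blk = Tensor(np.zeros((n_edges, n_eq, ir.dim)))
            v_blocks.append(blk)
        V = IrrepBlockArray(v_layout, v_blocks)

        states = [PairState(x, V)]
        env_norm = 1.0 / np.sqrt(self.norm.avg_num_neighbors)
        n_atoms = len(graph.species_idx)

        for layer in range(1, cfg.n_layers + 1):
            final = layer == cfg.n_layers
            wl = env_weights(layer, x)
            env_blocks = []
            for b, (_, ir) in enumerate(cfg.y_layout().blocks):
                wy = ad.reshape(wl[:, :, b], (n_edges, n_eq, 1)) * harmonics.blocks[b]
                summed = ad.segment_sum(wy, graph.centers, n_atoms)
                env_blocks.append(
                    ad.take(summed, graph.centers) * (env_norm * env_scale)
                )
            env = IrrepBlockArray(cfg.env_layout(), env_blocks)

            paths = self._scalar_paths if final else self._paths
            tp = tensor_product(V, env, paths)

            scalar_cols = [
                ad.reshape(tp.blocks[k], (n_edges, n_eq))
                for k, p in enumerate(paths)
                if p.is_scalar_out
            ]
            latent_in = ad.concat([x] + scalar_cols, axis=-1)
            h = _mlp(
                latent_in,
                [
                    self.params[f"latent.{layer}.W{k}"]
                    for k in range(len(cfg.latent_dims))
                ],
                cfg.latent_nonlinearity,
            )
            x = (x + h * u_col) * (1.0 / np.sqrt(2.0))

            new_blocks, new_layout = [], []
            for out_ir, group in self._path_groups(final):
                cols = [tp.blocks[paths.index(p)] for p in group]
                cat = ad.concat(cols, axis=-2)  # (E, n_paths*n_eq, dim)
                Wmix = self.params[f"mix.{layer}.{out_ir}"]
                mixed = ad.einsum("eqd,nq->end", cat, Wmix) * (
                    1.0 / np.sqrt(Wmix.shape[1])
                )
                new_blocks.append(mixed)
                new_layout.append((n_eq, out_ir))
            V = IrrepBlockArray(IrrepLayout(new_layout), new_blocks)
            states.append(PairState(x, V))

        e_pair = _mlp(
            x, [self.params["output.W0"], self.params["output.W1"]], "linear"
        )
        e_pair = ad.reshape(e_pair, (n_edges,))

        zi = graph.species_idx[graph.centers]
        zj = graph.species_idx[graph.neighbors]
        if self.norm.pair_scale is not None:
            e_pair_scaled = e_pair * Tensor(self.norm.pair_scale[zi, zj])
        else:
            e_pair_scaled = e_pair
        e_atom_raw = ad.segment_sum(e_pair_scaled, graph.centers, n_atoms) * env_norm

        scale = self.params.get("scale")
        shift = self.params.get("shift")
        scale_z = (
            ad.take(scale, graph.species_idx)
            if scale is not None
            else Tensor(self.norm.scale[graph.species_idx])
        )
        shift_z = (
            ad.take(shift, graph.species_idx)
            if shift is not None
            else Tensor(self.norm.shift[graph.species_idx])
        )
        e_atom = e_atom_raw * scale_z + shift_z
        e_frames = ad.segment_sum(e_atom, graph.frame_of_atom, graph.n_frames)

        out = {
            "positions": positions,
            "pair_energies": e_pair,
            "atom_energies": e_atom,
            "frame_energies": e_frames,
            "envelope": u,
        }
        if return_state:
            out["states"] = states
            out["harmonics"] = harmonics
        return out

    # -- user-facing prediction --------------------------------------------
    def predict(self, system: AtomicSystem) -> EnergyBreakdown:
        """Energy decomposition and forces for one configuration."""
        graph = make_graph(system, self.species_map, self.config.r_cut)
        out = self.forward_graph(graph)
        e_total = out["frame_energies"]
        total = e_total.sum()
        forces = -ad.grad(total, out["positions"]).data
        return EnergyBreakdown(
            out["pair_energies"].data.copy(),
            out["atom_energies"].data.copy(),
            float(total.data),
            forces,
        )

    def predict_batch(self, systems) -> list[EnergyBreakdown]:
        return [self.predict(s) for s in systems]

    # -- checkpointing -----------------------------------------------------
    def save(self, path):
        """Write config, normalization and parameters to an HDF5 container."""
        with h5py.File(path, "w") as f:
            f.attrs["config"] = yaml.safe_dump(asdict(self.config))
            f.attrs["shift"] = self.norm.shift
            f.attrs["scale"] = self.norm.scale
            f.attrs["avg_num_neighbors"] = self.norm.avg_num_neighbors
            if self.norm.pair_scale is not None:
                f.attrs["pair_scale"] = self.norm.pair_scale
            g = f.create_group("params")
            for name, t in self.params.items():
                g.create_dataset(name, data=t.data)

    @staticmethod
    def load(path) -> "AllegroModel":
        with h5py.File(path, "r") as f:
            cfg = AllegroConfig(**yaml.safe_load(f.attrs["config"]))
            norm = NormStats(
                np.array(f.attrs["shift"]),
                np.array(f.attrs["scale"]),
                np.array(f.attrs["pair_scale"]) if "pair_scale" in f.attrs else None,
                float(f.attrs["avg_num_neighbors"]),
            )
            model = AllegroModel(cfg, norm)
            for name in model.params:
                model.params[name] = Tensor(
                    np.array(f["params"][name]), requires_grad=True
                )
        return model


def count_parameters(config: AllegroConfig):
    """Trainable-scalar count of the model built from ``config``.

    Returns ``(total, breakdown)`` where the breakdown itemizes every
    weight tensor so a mismatch against an externally reported count can
    be localized component by component.
    """
    return AllegroModel(config).count_parameters()
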