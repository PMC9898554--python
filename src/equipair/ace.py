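"""Brute-force body-order oracles.

Two independent reference computations used to verify the model:

* the Atomic Cluster Expansion (ACE): projections ``A_{z n l}`` of the
  neighbor density onto a radial-chemical-angular basis and their
  iterated tensor products ``B^(nu)`` of body order ``nu + 1``, computed
  both through the density trick (products of the summed ``A``) and as
  explicit sums over neighbor tuples — the two must agree by bilinearity;
* the layer-recursion expansion: the model's equivariant pair features
  ``V^{ij,L}`` rewritten as an explicit sum over neighbor tuples
  ``(k_1..k_L)`` of iterated tensor products of spherical harmonics,
  weighted by the environment weights the model itself computes.  This is
  evaluated with plain numpy loops, fully independent of the recursive
  forward pass it checks.

Both oracles carry hard combinatorial budgets and raise rather than
silently truncate.

The module also hosts the body-order probe: scaling every neighbor's
contribution to the environment embedding by ``t`` makes the pair energy
of a model with linear latent/embedding MLPs a polynomial in ``t`` of
bounded degree, while any nonlinearity in those MLPs breaks polynomial
dependence.  The probe fits polynomials of increasing degree and reports
the residuals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .irreps import wigner_3j, path_scale, TPPath, Irrep, real_spherical_harmonics
from .model import AllegroModel, Graph
from .radial import RadialBasis


# ---------------------------------------------------------------------------
# ACE
# ---------------------------------------------------------------------------

@dataclass
class Environment:
    """Neighbors of one central atom: species symbols and displacement vectors."""

    symbols: list[str]
    vectors: np.ndarray  # (k, 3)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float).reshape(-1, 3)
        if len(self.symbols) != len(self.vectors):
            raise ValueError("one symbol per neighbor vector required")

    @property
    def n(self):
        return len(self.symbols)


def _harmonics_np(ell_max: int, vecs: np.ndarray):
    """Per-neighbor harmonic blocks as plain arrays: list over l of (k, 2l+1)."""
    with ad.no_grad():
        h = real_spherical_harmonics(ell_max, vecs)
    return [b.data[:, 0, :] for b in h.blocks]


class DensityProjection:
    """``A_{z n l}``: per-species radial-weighted harmonic sums of the density."""

    def __init__(self, species: list[str], n_basis: int, ell_max: int):
        self.species = list(species)
        self.n_basis = n_basis
        self.ell_max = ell_max
        self.A = {
            (z, n): [np.zeros(2 * l + 1) for l in range(ell_max + 1)]
            for z in self.species
            for n in range(n_basis)
        }

    def block(self, z, n, l):
        return self.A[(z, n)][l]


def ace_A(env: Environment, basis: RadialBasis, ell_max: int,
          species: list[str]) -> DensityProjection:
    """Project an environment onto the radial-chemical-angular basis.

    The radial-chemical basis is the model's normalized Bessel basis times
    a species indicator.
    """
    proj = DensityProjection(species, basis.spec.n_basis, ell_max)
    if env.n == 0:
        return proj
    r = np.linalg.norm(env.vectors, axis=1)
    with ad.no_grad():
        radial = basis(r).data  # (k, n_basis)
    Y = _harmonics_np(ell_max, env.vectors)
    for k, sym in enumerate(env.symbols):
        for n in range(basis.spec.n_basis):
            for l in range(ell_max + 1):
                proj.A[(sym, n)][l] = proj.A[(sym, n)][l] + radial[k, n] * Y[l][k]
    return proj


def _couple(blockA, lA, blockB, lB, l_out):
    """Single-path real tensor product of two plain blocks."""
    c = wigner_3j(lA, lB, l_out)
    scale = path_scale(TPPath(Irrep(lA), Irrep(lB), Irrep(l_out)))
    return np.einsum("ijk,i,j->k", c, blockA, blockB) * scale


def _coupling_chains(ls, ell_inter_max):
    """All intermediate-irrep chains coupling ``ls`` down to a scalar."""
    if len(ls) == 1:
        return [[]] if ls[0] == 0 else []
    chains = []

    def rec(pos, l_cur, acc):
        if pos == len(ls):
            if l_cur == 0:
                chains.append(list(acc))
            return
        for l_next in range(abs(l_cur - ls[pos]), l_cur + ls[pos] + 1):
            if l_next > ell_inter_max:
                continue
            rec(pos + 1, l_next, acc + [l_next])

    rec(1, ls[0], [])
    return chains


@dataclass(frozen=True)
class ACEKey:
    """Label of one scalar ACE descriptor component."""

    zs: tuple  # species per factor
    ns: tuple  # radial index per factor
    ls: tuple  # rotation order per factor
    inter: tuple  # intermediate coupling orders (ending at 0)


class ACEDescriptor:
    """Scalar (rotation-invariant) descriptors of body order ``nu + 1``."""

    def __init__(self, values: dict):
        self.values = values  # ACEKey -> float

    def as_array(self):
        keys = sorted(self.values, key=lambda k: (k.zs, k.ns, k.ls, k.inter))
        return keys, np.array([self.values[k] for k in keys])


_MAX_TUPLES = 200_000


def _iter_labels(species, n_basis, ell_max, nu, ell_inter_max):
    for zs in itertools.product(species, repeat=nu):
        for ns in itertools.product(range(n_basis), repeat=nu):
            for ls in itertools.product(range(ell_max + 1), repeat=nu):
                if nu == 1:
                    if ls[0] == 0:
                        yield ACEKey(zs, ns, ls, (0,))
                    continue
                for chain in _coupling_chains(list(ls), ell_inter_max):
                    yield ACEKey(zs, ns, ls, tuple(chain))


def ace_B_density(proj: DensityProjection, nu: int,
                  ell_inter_max: int | None = None) -> ACEDescriptor:
    """Scalar descriptors via the density trick (iterated products of A)."""
    if nu < 1:
        raise ValueError("nu must be >= 1")
    ell_max = proj.ell_max
    if ell_inter_max is None:
        ell_inter_max = 2 * ell_max
    values = {}
    for key in _iter_labels(proj.species, proj.n_basis, ell_max, nu, ell_inter_max):
        block = proj.block(key.zs[0], key.ns[0], key.ls[0])
        l_cur = key.ls[0]
        for a in range(1, nu):
            l_next = key.inter[a - 1]
            block = _couple(block, l_cur, proj.block(key.zs[a], key.ns[a], key.ls[a]),
                            key.ls[a], l_next)
            l_cur = l_next
        values[key] = float(block[0])
    return ACEDescriptor(values)


def ace_B_tuples(env: Environment, basis: RadialBasis, ell_max: int,
                 species: list[str], nu: int,
                 ell_inter_max: int | None = None) -> ACEDescriptor:
    """Scalar descriptors via the explicit neighbor-tuple sum."""
    if nu < 1:
        raise ValueError("nu must be >= 1")
    if env.n ** nu > _MAX_TUPLES:
        raise ValueError(
            f"tuple budget exceeded: {env.n}^{nu} neighbor tuples"
        )
    if ell_inter_max is None:
        ell_inter_max = 2 * ell_max
    r = np.linalg.norm(env.vectors, axis=1) if env.n else np.zeros(0)
    with ad.no_grad():
        radial = basis(r).data if env.n else np.zeros((0, basis.spec.n_basis))
    Y = _harmonics_np(ell_max, env.vectors) if env.n else None
    values = {}
    for key in _iter_labels(species, basis.spec.n_basis, ell_max, nu, ell_inter_max):
        total = 0.0
        for ks in itertools.product(range(env.n), repeat=nu):
            if any(env.symbols[k] != z for k, z in zip(ks, key.zs)):
                continue
            weight = np.prod([radial[k, n] for k, n in zip(ks, key.ns)])
            block = Y[key.ls[0]][ks[0]]
            l_cur = key.ls[0]
            ok = True
            for a in range(1, nu):
                l_next = key.inter[a - 1]
                block = _couple(block, l_cur, Y[key.ls[a]][ks[a]], key.ls[a], l_next)
                l_cur = l_next
            total += weight * float(block[0])
        values[key] = total
    return ACEDescriptor(values)


# ---------------------------------------------------------------------------
# layer-recursion expansion
# ---------------------------------------------------------------------------

_MAX_EXPANSION_NEIGHBORS = 4
_MAX_EXPANSION_LAYERS = 2


def allegro_expand(model: AllegroModel, graph: Graph, edge: int, layer: int):
    """Pair features ``V^{ij,L}`` by explicit neighbor-tuple expansion.

    Uses the environment-embedding weights the model computes on this
    graph, but evaluates the feature blocks with plain numpy loops over
    neighbor tuples ``(k_1..k_L)`` and per-layer tensor-product paths —
    no shared code path with the recursive forward pass.

    Returns a dict ``irrep -> (n_equivariant, 2l+1)`` array.
    """
    cfg = model.config
    if layer > min(cfg.n_layers, _MAX_EXPANSION_LAYERS):
        raise ValueError("expansion budget: layer too deep")
    center = graph.centers[edge]
    edges_of_center = np.nonzero(graph.centers == center)[0]
    if len(edges_of_center) > _MAX_EXPANSION_NEIGHBORS:
        raise ValueError("expansion budget: too many neighbors")

    out = model.forward_graph(graph, return_state=True)
    states = out["states"]
    with ad.no_grad():
        harmonics = [b.data[:, 0, :] for b in out["harmonics"].blocks]

    n_eq = cfg.n_equivariant
    env_norm = 1.0 / np.sqrt(model.norm.avg_num_neighbors)
    y_layout = cfg.y_layout()
    y_index = {ir: b for b, (_, ir) in enumerate(y_layout.blocks)}

    def embed_weights(lyr, x_data):
        W = model.params[f"embed.{lyr}.W"].data
        w = x_data @ W / np.sqrt(W.shape[0])
        return w.reshape(len(x_data), n_eq, len(y_layout))

    # V^{ij,0}: weighted harmonics of the pair direction itself
    w0 = embed_weights(0, states[0].x.data)
    v = {}
    for _, ir in cfg.v_layout().blocks:
        if ir in y_index:
            b = y_index[ir]
            v[ir] = w0[edge, :, b, None] * harmonics[b][edge][None, :]
        else:
            v[ir] = np.zeros((n_eq, ir.dim))
    terms = {(): v}  # neighbor tuple -> blocks

    for lyr in range(1, layer + 1):
        final = lyr == cfg.n_layers
        wl = embed_weights(lyr, states[lyr - 1].x.data)
        paths = model._scalar_paths if final else model._paths
        groups = model._path_groups(final)
        new_terms = {}
        for tup, blocks in terms.items():
            for k_edge in edges_of_center:
                # single-neighbor tensor product of this term
                path_out = []
                for p in paths:
                    ir1 = cfg.v_layout().blocks[p.block1][1]
                    b2 = p.block2
                    y_k = harmonics[b2][k_edge] * wl[k_edge, :, b2, None] * env_norm
                    c = wigner_3j(p.irrep1.ell, p.irrep2.ell, p.irrep_out.ell)
                    val = np.einsum("ijk,ni,nj->nk", c, blocks[ir1], y_k)
                    path_out.append(val * path_scale(p))
                mixed = {}
                for out_ir, group in groups:
                    cat = np.concatenate(
                        [path_out[paths.index(p)] for p in group], axis=0
                    )
                    W = model.params[f"mix.{lyr}.{out_ir}"].data
                    mixed[out_ir] = (W @ cat) / np.sqrt(W.shape[1])
                new_terms[tup + (int(k_edge),)] = mixed
        terms = new_terms

    irreps_out = list(next(iter(terms.values())).keys()) if terms else []
    summed = {
        ir: np.sum([blocks[ir] for blocks in terms.values()], axis=0)
        for ir in irreps_out
    }
    return summed


# ---------------------------------------------------------------------------
# body-order probe
# ---------------------------------------------------------------------------

@dataclass
class BodyOrderReport:
    degrees: list[int]
    residuals: list[float]
    is_polynomial: bool
    degree: int | None  # smallest fitting degree, when polynomial


def body_order_probe(model: AllegroModel, graph: Graph, edge: int = 0,
                     max_degree: int = 8, n_samples: int = 41,
                     t_range: float = 3.0, tol: float = 1e-12) -> BodyOrderReport:
    """Fit the pair energy as a polynomial in the environment scale ``t``.

    Every neighbor's contribution to the environment embedding is scaled
    by ``t``; for linear latent and embedding MLPs the resulting
    ``E_ij(t)`` is a polynomial of bounded degree (finite body order),
    while a nonlinear latent MLP leaves residuals above ``tol`` at every
    degree tried.  The range ``[-t_range, t_range]`` is wide enough that
    a smooth nonlinearity cannot hide inside a low-degree Taylor window.
    """
    ts = np.linspace(-t_range, t_range, n_samples)
    es = np.empty(n_samples)
    with ad.no_grad():
        for i, t in enumerate(ts):
            out = model.forward_graph(graph, env_scale=float(t))
            es[i] = out["pair_energies"].data[edge]
    scale = max(np.abs(es).max(), 1e-30)
    degrees, residuals = [], []
    best = None
    for deg in range(max_degree + 1):
        coeffs = np.polynomial.polynomial.polyfit(ts, es, deg)
        fit = np.polynomial.polynomial.polyval(ts, coeffs)
        res = float(np.abs(fit - es).max() / scale)
        degrees.append(deg)
        residuals.append(res)
        if best is None and res < tol:
            best = deg
    return BodyOrderReport(degrees, residuals, best is not None, best)
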