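"""Algebra of O(3)/SO(3) irreducible representations.

Real spherical harmonics, Wigner 3j coupling coefficients in the real
basis, tensor-product path enumeration, the tensor product itself, and
rotation operators used by the equivariance tests.

Conventions
-----------
* Components within an ``ell`` block are ordered ``m = -ell..ell``; negative
  ``m`` carries the ``sin``-type harmonic, positive ``m`` the ``cos`` type,
  without the Condon-Shortley phase.
* "Component normalization": the ``ell`` block of the spherical harmonics of
  a unit vector has squared Euclidean norm ``2*ell + 1`` (so ``Y_0 = 1`` and
  ``Y_1 = sqrt(3) * (y, z, x)``).
* Parity may be unset (``None``), which selects the SE(3) mode in which all
  parity bookkeeping is omitted.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import sympy as sp
from scipy.special import sph_harm_y
from sympy.physics.wigner import wigner_3j as _wigner_3j_sym

from . import autodiff as ad
from .autodiff import Tensor

_BATCH_LETTERS = "abcdefg"


# ---------------------------------------------------------------------------
# irreps and layouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Irrep:
    """An O(3) (or, with ``parity=None``, SO(3)) irreducible representation."""

    ell: int
    parity: int | None = None

    def __post_init__(self):
        if self.ell < 0:
            raise ValueError("rotation order ell must be >= 0")
        if self.parity not in (1, -1, None):
            raise ValueError("parity must be +1, -1 or None")

    @property
    def dim(self) -> int:
        return 2 * self.ell + 1

    def __str__(self):
        tag = {1: "e", -1: "o", None: ""}[self.parity]
        return f"{self.ell}{tag}"

    def _key(self):
        return (self.ell, 0 if self.parity is None else self.parity)


class IrrepLayout:
    """Ordered list of ``(multiplicity, Irrep)`` blocks."""

    def __init__(self, blocks):
        self.blocks = [(int(n), ir) for n, ir in blocks]
        if any(n < 1 for n, _ in self.blocks):
            raise ValueError("multiplicities must be >= 1")

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self):
        return len(self.blocks)

    def __eq__(self, other):
        return isinstance(other, IrrepLayout) and self.blocks == other.blocks

    def __repr__(self):
        return "+".join(f"{n}x{ir}" for n, ir in self.blocks)

    @property
    def dim(self) -> int:
        return sum(n * ir.dim for n, ir in self.blocks)

    def irreps(self):
        return [ir for _, ir in self.blocks]

    @staticmethod
    def spherical(ell_max: int, use_parity: bool = True) -> "IrrepLayout":
        """Layout of the spherical harmonics ``Y_0..Y_ell_max`` (parity (-1)^l)."""
        return IrrepLayout(
            [
                (1, Irrep(l, (-1) ** l if use_parity else None))
                for l in range(ell_max + 1)
            ]
        )


class IrrepBlockArray:
    """Features grouped into (channel, irrep) blocks.

    ``blocks[k]`` is a Tensor of shape ``(..., n_k, 2*ell_k + 1)`` matching
    ``layout.blocks[k]``.  Leading batch axes are shared by all blocks.
    """

    def __init__(self, layout: IrrepLayout, blocks):
        self.layout = layout
        self.blocks = [ad.astensor(b) for b in blocks]
        if len(self.blocks) != len(layout.blocks):
            raise ValueError("block count does not match layout")
        for b, (n, ir) in zip(self.blocks, layout.blocks):
            if b.shape[-2:] != (n, ir.dim):
                raise ValueError(f"block shape {b.shape} incompatible with {n}x{ir}")

    def __getitem__(self, k):
        return self.blocks[k]

    @property
    def batch_shape(self):
        return self.blocks[0].shape[:-2]

    def to_flat(self) -> Tensor:
        flat = [
            ad.reshape(b, b.shape[:-2] + (b.shape[-2] * b.shape[-1],))
            for b in self.blocks
        ]
        return ad.concat(flat, axis=-1)

    def numpy(self):
        return [b.data.copy() for b in self.blocks]


# ---------------------------------------------------------------------------
# real spherical harmonics
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def _harmonic_monomials(ell: int, m: int):
    """Monomial table ``(coeff, px, py, pz)`` of the real harmonic (ell, m).

    Closed form ``N_lm * P_l^(|m|)(z) * {Re, Im}[(x + i y)^|m|]`` with
    ``P_l^(m)`` the m-th derivative of the Legendre polynomial, normalized
    so that the block has squared norm ``2*ell + 1`` on the unit sphere.
    """
    x, y, z = sp.symbols("x y z")
    am = abs(m)
    legendre_dm = sp.diff(sp.legendre(ell, z), z, am)
    angular = sp.S.Zero
    for (px, py), c in sp.Poly((x + sp.I * y) ** am, x, y).terms():
        comp = sp.re(c) if m >= 0 else sp.im(c)
        angular += comp * x ** px * y ** py
    norm = sp.sqrt(
        sp.Integer(2 * ell + 1) * sp.factorial(ell - am) / sp.factorial(ell + am)
    )
    if am > 0:
        norm *= sp.sqrt(2)
    poly = sp.expand(norm * legendre_dm * angular)
    table = []
    for (px, py, pz), c in sp.Poly(poly, x, y, z).terms():
        table.append((float(c), int(px), int(py), int(pz)))
    return tuple(table)


def real_spherical_harmonics(
    ell_max: int, u, use_parity: bool = True, policy: str = "normalize"
) -> IrrepBlockArray:
    """Real spherical harmonics ``Y_0 .. Y_ell_max`` of unit vector(s) ``u``.

    ``u`` is a Tensor or array of shape ``(..., 3)``.  Non-unit inputs are
    normalized (``policy="normalize"``, the documented default) or rejected
    (``policy="reject"``).  Differentiable through the autodiff engine;
    each ``ell`` block has parity ``(-1)**ell`` (omitted in SE(3) mode).
    """
    u = ad.astensor(u)
    norm2 = (u ** 2).sum(axis=-1, keepdims=True)
    if policy == "reject":
        if not np.allclose(norm2.data, 1.0, atol=1e-8):
            raise ValueError("input vectors are not unit length")
        unit = u
    elif policy == "normalize":
        unit = u * norm2 ** (-0.5)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    batch = u.shape[:-1]
    x = unit[..., 0]
    y = unit[..., 1]
    z = unit[..., 2]
    blocks = []
    for ell in range(ell_max + 1):
        cols = []
        for m in range(-ell, ell + 1):
            val = None
            for coeff, px, py, pz in _harmonic_monomials(ell, m):
                term = coeff * _monomial(x, y, z, px, py, pz, batch)
                val = term if val is None else val + term
            cols.append(ad.reshape(val, batch + (1, 1)))
        blocks.append(ad.concat(cols, axis=-1))
    layout = IrrepLayout.spherical(ell_max, use_parity=use_parity)
    return IrrepBlockArray(layout, blocks)


def _monomial(x, y, z, px, py, pz, batch):
    out = None
    for base, p in ((x, px), (y, py), (z, pz)):
        if p == 0:
            continue
        f = base if p == 1 else base ** p
        out = f if out is None else out * f
    if out is None:
        out = ad.Tensor(np.ones(batch) if batch else 1.0)
    return out


# ---------------------------------------------------------------------------
# Wigner 3j in the real basis
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def _real_to_complex_basis(ell: int) -> np.ndarray:
    """Unitary ``U`` with ``Y_real = U @ Y_complex`` at order ``ell``.

    Calibrated on a fixed set of directions against the standard complex
    harmonics (Condon-Shortley convention); our real harmonics are divided
    by ``sqrt(4 pi)`` to the orthonormal scale first.
    """
    rng = np.random.default_rng(12345 + ell)
    v = rng.normal(size=(4 * ell + 8, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    theta = np.arccos(np.clip(v[:, 2], -1, 1))
    phi = np.arctan2(v[:, 1], v[:, 0])
    y_real = real_spherical_harmonics(ell, v).blocks[ell].data[:, 0, :]
    y_real = y_real / np.sqrt(4 * np.pi)
    y_complex = np.stack(
        [sph_harm_y(ell, m, theta, phi) for m in range(-ell, ell + 1)], axis=1
    )
    U, *_ = np.linalg.lstsq(y_complex, y_real, rcond=None)
    U = U.T
    assert np.allclose(U @ U.conj().T, np.eye(2 * ell + 1), atol=1e-10)
    return U


@functools.lru_cache(maxsize=None)
def wigner_3j(ell1: int, ell2: int, ell3: int) -> np.ndarray:
    """Real-basis coupling tensor of shape ``(2l1+1, 2l2+1, 2l3+1)``.

    Obtained from the complex-basis Racah closed form by the change of
    basis of :func:`_real_to_complex_basis`; the result is real up to a
    global phase which is divided out.  It satisfies
    ``sum_{m1,m2} C[m1,m2,m] C[m1,m2,m'] = (||C||^2 / (2 l3 + 1)) delta_{mm'}``
    and, contracted with two real equivariant inputs, yields a real
    equivariant output.  Raises on selection-rule violations.
    """
    if not abs(ell1 - ell2) <= ell3 <= ell1 + ell2:
        raise ValueError(
            f"invalid path: |{ell1}-{ell2}| <= {ell3} <= {ell1}+{ell2} fails"
        )
    d1, d2, d3 = 2 * ell1 + 1, 2 * ell2 + 1, 2 * ell3 + 1
    wc = np.zeros((d1, d2, d3), dtype=complex)
    for i1, m1 in enumerate(range(-ell1, ell1 + 1)):
        for i2, m2 in enumerate(range(-ell2, ell2 + 1)):
            m3 = -(m1 + m2)
            if abs(m3) > ell3:
                continue
            wc[i1, i2, m3 + ell3] = float(_wigner_3j_sym(ell1, ell2, ell3, m1, m2, m3))
    U1 = _real_to_complex_basis(ell1).conj()
    U2 = _real_to_complex_basis(ell2).conj()
    U3 = _real_to_complex_basis(ell3).conj()
    full = np.einsum("ia,jb,kc,abc->ijk", U1, U2, U3, wc)
    if np.abs(full.imag).max() > np.abs(full.real).max():
        out, leftover = full.imag, full.real
    else:
        out, leftover = full.real, full.imag
    assert np.abs(leftover).max() < 1e-10, "change of basis left a mixed-phase tensor"
    out = np.ascontiguousarray(out)
    out.setflags(write=False)
    return out


# ---------------------------------------------------------------------------
# tensor-product paths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TPPath:
    """One admissible irrep combination of a tensor product."""

    irrep1: Irrep
    irrep2: Irrep
    irrep_out: Irrep
    block1: int = 0  # positions in the input layouts
    block2: int = 0

    def __post_init__(self):
        l1, l2, lo = self.irrep1.ell, self.irrep2.ell, self.irrep_out.ell
        if not abs(l1 - l2) <= lo <= l1 + l2:
            raise ValueError(f"selection rule violated for {self}")
        p1, p2, po = self.irrep1.parity, self.irrep2.parity, self.irrep_out.parity
        if p1 is not None and p2 is not None and po != p1 * p2:
            raise ValueError(f"parity rule violated for {self}")

    def __str__(self):
        return f"{self.irrep1}x{self.irrep2}->{self.irrep_out}"

    @property
    def is_scalar_out(self) -> bool:
        out = self.irrep_out
        return out.ell == 0 and out.parity in (1, None)


def enumerate_paths(
    layout1: IrrepLayout,
    layout2: IrrepLayout,
    ell_max: int,
    mode: str = "all_allowed",
) -> list[TPPath]:
    """All tensor-product paths between two layouts with ``l_out <= ell_max``.

    ``mode="all_allowed"`` emits every admissible path;
    ``mode="restricted"`` keeps only paths whose output irrep occurs in
    ``layout1``.  Ordering is lexicographic in
    ``(l1, p1, l2, p2, l_out, p_out)`` with block positions breaking ties,
    which fixes the order of every path-dependent sum in the model.
    """
    if mode not in ("all_allowed", "restricted"):
        raise ValueError(f"unknown mode {mode!r}")
    allowed_out = {ir for _, ir in layout1.blocks} if mode == "restricted" else None
    paths = []
    for b1, (_, ir1) in enumerate(layout1.blocks):
        for b2, (_, ir2) in enumerate(layout2.blocks):
            for lo in range(abs(ir1.ell - ir2.ell), ir1.ell + ir2.ell + 1):
                if lo > ell_max:
                    continue
                po = (
                    None
                    if ir1.parity is None or ir2.parity is None
                    else ir1.parity * ir2.parity
                )
                out = Irrep(lo, po)
                if allowed_out is not None and out not in allowed_out:
                    continue
                paths.append(TPPath(ir1, ir2, out, b1, b2))
    paths.sort(
        key=lambda p: (
            p.irrep1._key(),
            p.irrep2._key(),
            p.irrep_out._key(),
            p.block1,
            p.block2,
        )
    )
    return paths


def path_scale(path: TPPath) -> float:
    """Variance-preserving constant applied to one tensor-product path.

    With component-normalized inputs the raw 3j contraction has per-output
    component variance ``||C||_F^2 / (2*l_out+1)``; dividing by its square
    root keeps unit variance.  For the scalar-scalar path this is exactly 1
    (plain multiplication).
    """
    c = wigner_3j(path.irrep1.ell, path.irrep2.ell, path.irrep_out.ell)
    return float(np.sqrt(path.irrep_out.dim) / np.linalg.norm(c))


def tensor_product(
    x: IrrepBlockArray, y: IrrepBlockArray, paths: list[TPPath]
) -> IrrepBlockArray:
    """Channel-wise tensor product along the given paths.

    Produces one output block per path; channel counts of the paired input
    blocks must match.  Bilinear in both arguments and equivariant.
    """
    out_blocks = []
    out_layout = []
    for p in paths:
        bx = x.blocks[p.block1]
        by = y.blocks[p.block2]
        if bx.shape[-2] != by.shape[-2]:
            raise ValueError(f"channel mismatch on path {p}")
        c = wigner_3j(p.irrep1.ell, p.irrep2.ell, p.irrep_out.ell)
        batch = _BATCH_LETTERS[: bx.ndim - 2]
        spec = f"ijk,{batch}ni,{batch}nj->{batch}nk"
        out = ad.einsum(spec, Tensor(c), bx, by)
        out_blocks.append(out * path_scale(p))
        out_layout.append((bx.shape[-2], p.irrep_out))
    return IrrepBlockArray(IrrepLayout(out_layout), out_blocks)


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RotationOp:
    """A proper rotation, optionally composed with spatial inversion."""

    matrix: np.ndarray
    inversion: bool = False

    def __post_init__(self):
        R = np.asarray(self.matrix, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
            raise ValueError("rotation matrix is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-10):
            raise ValueError("rotation matrix must be proper (det=+1)")
        object.__setattr__(self, "matrix", R)

    @staticmethod
    def random(rng: np.random.Generator, inversion: bool = False) -> "RotationOp":
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        return RotationOp(Q, inversion)

    def apply_points(self, x: np.ndarray) -> np.ndarray:
        s = -1.0 if self.inversion else 1.0
        return s * (np.asarray(x) @ self.matrix.T)

    def compose(self, other: "RotationOp") -> "RotationOp":
        return RotationOp(self.matrix @ other.matrix, self.inversion ^ other.inversion)


@functools.lru_cache(maxsize=None)
def _wigner_D_cached(ell: int, key: bytes) -> np.ndarray:
    R = np.frombuffer(key, dtype=float).reshape(3, 3)
    if ell == 0:
        return np.ones((1, 1))
    rng = np.random.default_rng(777 + ell)
    v = rng.normal(size=(4 * ell + 8, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    y0 = real_spherical_harmonics(ell, v).blocks[ell].data[:, 0, :]
    y1 = real_spherical_harmonics(ell, v @ R.T).blocks[ell].data[:, 0, :]
    D, *_ = np.linalg.lstsq(y0, y1, rcond=None)
    D = D.T  # Y(R v) = D Y(v)
    assert np.allclose(D @ D.T, np.eye(2 * ell + 1), atol=1e-9)
    return D


def wigner_D(ell: int, rot: RotationOp) -> np.ndarray:
    """Orthogonal matrix for the proper-rotation part of ``rot`` on the
    real order-``ell`` harmonics: ``Y_l(R u) = D(l, R) Y_l(u)``.

    Solved from the harmonics themselves on a fixed direction sample, so
    the matrix is exact in the package's own component convention.
    Inversion acts separately as the parity sign (see
    :func:`apply_rotation`).
    """
    return _wigner_D_cached(ell, rot.matrix.tobytes())


def apply_rotation(v: IrrepBlockArray, rot: RotationOp) -> IrrepBlockArray:
    """Transform every block of ``v`` by the representation of ``rot``.

    Parity-odd blocks flip sign under inversion; inversion on a
    parity-unset (SE(3)-mode) block is undefined and raises.
    """
    out = []
    for b, (_, ir) in zip(v.blocks, v.layout.blocks):
        D = wigner_D(ir.ell, rot)
        sign = 1.0
        if rot.inversion:
            if ir.parity is None:
                raise ValueError("inversion undefined for parity-unset blocks")
            sign = float(ir.parity)
        batch = _BATCH_LETTERS[: b.ndim - 2]
        transformed = ad.einsum(f"km,{batch}nm->{batch}nk", Tensor(D), b) * sign
        out.append(transformed)
    return IrrepBlockArray(v.layout, out)
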