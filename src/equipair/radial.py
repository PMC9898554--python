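"""Bessel radial basis with a smooth polynomial cutoff envelope.

The pairwise distance is encoded by ``N_basis`` spherical-Bessel-type
functions ``B_n(r) = sqrt(2/r_c) * sin(n pi r / r_c) / r`` multiplied by a
polynomial envelope ``u(r)`` that, together with its first two
derivatives, vanishes at the cutoff ``r_c``, so energies and forces stay
continuous as atoms enter or leave the cutoff sphere.

Each enveloped basis function is affinely rescaled to zero mean and unit
variance with the distance sampled uniformly on ``(0, r_c]`` (fixed
high-resolution quadrature, no randomness), so that the network sees
inputs of roughly unit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass(frozen=True)
class RadialBasisSpec:
    """Hyperparameters of the radial encoding.

    Parameters
    ----------
    n_basis:
        Number of Bessel functions (8 in all reference configurations).
    r_cut:
        Cutoff radius in Angstrom.
    envelope_p:
        Exponent ``p`` of the polynomial envelope; lower values decay
        sooner inside the cutoff.
    trainable:
        Whether the Bessel frequencies are trainable (off by default).
    """

    n_basis: int = 8
    r_cut: float = 4.0
    envelope_p: int = 6
    trainable: bool = False

    def __post_init__(self):
        if self.n_basis < 1:
            raise ValueError("n_basis must be >= 1")
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.envelope_p < 2:
            raise ValueError("envelope_p must be >= 2 for smooth forces")


def bessel(r, spec: RadialBasisSpec, frequencies=None) -> Tensor:
    """Raw Bessel radial functions, shape ``(..., n_basis)``.

    ``B_n(r) = sqrt(2/r_c) * sin(n pi r / r_c) / r`` for ``r > 0``; the
    ``r -> 0+`` limit ``sqrt(2/r_c) * n pi / r_c`` is finite but the
    domain contract is ``r > 0``.
    """
    r = ad.astensor(r)
    if np.any(r.data <= 0):
        raise ValueError("bessel basis requires r > 0")
    if frequencies is None:
        freq = Tensor(np.arange(1, spec.n_basis + 1) * np.pi / spec.r_cut)
    else:
        freq = ad.astensor(frequencies)
    prefactor = np.sqrt(2.0 / spec.r_cut)
    rr = ad.reshape(r, r.shape + (1,))
    arg = rr * ad.reshape(freq, (1,) * r.ndim + (spec.n_basis,))
    return ad.sin(arg) * (prefactor * rr ** -1.0)


def envelope(r, spec: RadialBasisSpec) -> Tensor:
    """Polynomial cutoff envelope ``u(r)`` on ``[0, r_cut]``, zero beyond.

    With ``d = r / r_cut`` and exponent ``p``::

        u = 1 - (p+1)(p+2)/2 d^p + p(p+2) d^(p+1) - p(p+1)/2 d^(p+2)

    ``u(0) = 1``; ``u`` and its first two derivatives vanish at the
    cutoff.  Values for ``r >= r_cut`` are exactly zero (the polynomial
    itself crosses zero there, so the clamp does not break smoothness).
    """
    r = ad.astensor(r)
    p = float(spec.envelope_p)
    d = r * (1.0 / spec.r_cut)
    poly = (
        1.0
        + d ** p * (-(p + 1.0) * (p + 2.0) / 2.0)
        + d ** (p + 1.0) * (p * (p + 2.0))
        + d ** (p + 2.0) * (-p * (p + 1.0) / 2.0)
    )
    mask = (r.data < spec.r_cut).astype(float)
    return poly * Tensor(mask)


@dataclass
class RadialBasis:
    """Normalized enveloped radial basis (the model-facing object)."""

    spec: RadialBasisSpec
    _shift: np.ndarray = field(init=False, repr=False)
    _scale: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self._shift, self._scale = _normalization_constants(self.spec)

    def raw(self, r) -> Tensor:
        """Enveloped but unnormalized basis ``B(r) * u(r)``."""
        return bessel(r, self.spec) * ad.reshape(
            envelope(r, self.spec), ad.astensor(r).shape + (1,)
        )

    def __call__(self, r, frequencies=None) -> Tensor:
        """Normalized enveloped basis, shape ``(..., n_basis)``."""
        r = ad.astensor(r)
        val = bessel(r, self.spec, frequencies=frequencies) * ad.reshape(
            envelope(r, self.spec), r.shape + (1,)
        )
        return (val - Tensor(self._shift)) * Tensor(1.0 / self._scale)


def cutoff_basis(r, spec: RadialBasisSpec) -> Tensor:
    """Enveloped (unnormalized) basis ``B(r) * u(r)``; zero for r >= r_cut."""
    return RadialBasis(spec).raw(r)


def _normalization_constants(spec: RadialBasisSpec, n_quad: int = 2 ** 16):
    """Per-function affine constants from uniform-r quadrature on (0, r_c]."""
    r = (np.arange(n_quad) + 0.5) * (spec.r_cut / n_quad)
    with ad.no_grad():
        vals = bessel(r, spec).data * envelope(r, spec).data[:, None]
    mean = vals.mean(axis=0)
    std = vals.std(axis=0)
    if np.any(std < 1e-12):
        raise ValueError("degenerate radial basis function (zero variance)")
    return mean, std
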