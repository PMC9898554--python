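"""Minimal reverse-mode automatic differentiation over numpy arrays.

The potential-energy model needs two kinds of exact derivatives: forces
(gradients of the energy with respect to atomic positions) and training
gradients of a loss that itself contains those forces.  The latter requires
differentiating through a backward pass, so every vector-Jacobian product
(VJP) here is expressed in terms of the same primitive operations, making
the engine closed under differentiation to arbitrary order.

Only the small set of primitives the model uses is provided: broadcasting
arithmetic, integer powers, trigonometric functions, sigmoid, reductions,
``einsum`` contractions, concatenation/slicing, gather and segment-sum.
All arithmetic is float64 unless the inputs say otherwise.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context in which no computation graph is recorded."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array with an optional backward graph."""

    __slots__ = ("data", "parents", "vjps", "requires_grad")

    def __init__(self, data, parents=(), vjps=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        if _GRAD_ENABLED:
            self.parents = tuple(parents)
            self.vjps = tuple(vjps)
            self.requires_grad = bool(requires_grad) or any(
                p.requires_grad for p in self.parents
            )
        else:
            self.parents = ()
            self.vjps = ()
            self.requires_grad = False

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1))
        return mul(self, 1.0 / float(other))

    def __rtruediv__(self, other):
        return mul(power(self, -1), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, n):
        return power(self, n)

    def __getitem__(self, key):
        return getitem(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def astensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _sum_to(t: Tensor, shape) -> Tensor:
    """Reduce a broadcast result back to ``shape`` (VJP of broadcasting)."""
    if t.shape == tuple(shape):
        return t
    data_ndim = t.ndim
    extra = data_ndim - len(shape)
    if extra > 0:
        t = tsum(t, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and t.shape[i] != 1)
    if axes:
        t = tsum(t, axis=axes, keepdims=True)
    return reshape(t, tuple(shape))


# -- primitives ------------------------------------------------------------

def add(a, b):
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data + b.data,
        parents=(a, b),
        vjps=(lambda g: _sum_to(g, a.shape), lambda g: _sum_to(g, b.shape)),
    )


def mul(a, b):
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        vjps=(
            lambda g: _sum_to(mul(g, b), a.shape),
            lambda g: _sum_to(mul(g, a), b.shape),
        ),
    )


def power(a, n):
    a = astensor(a)
    n = float(n)
    return Tensor(
        np.power(a.data, n),
        parents=(a,),
        vjps=(lambda g: mul(g, mul(power(a, n - 1.0), n)),),
    )


def sqrt(a):
    return power(a, 0.5)


def sin(a):
    a = astensor(a)
    return Tensor(np.sin(a.data), parents=(a,), vjps=(lambda g: mul(g, cos(a)),))


def cos(a):
    a = astensor(a)
    return Tensor(
        np.cos(a.data), parents=(a,), vjps=(lambda g: mul(g, mul(sin(a), -1.0)),)
    )


def exp(a):
    a = astensor(a)
    out = Tensor(np.exp(a.data), parents=(a,), vjps=())
    out.vjps = (lambda g: mul(g, out),)
    return out


def sigmoid(a):
    a = astensor(a)
    out = Tensor(
        1.0 / (1.0 + np.exp(-a.data)),
        parents=(a,),
        vjps=(),
    )
    out.vjps = (lambda g: mul(g, mul(out, add(1.0, mul(out, -1.0)))),)
    return out


def silu(a):
    """x * sigmoid(x), the SiLU / swish nonlinearity."""
    a = astensor(a)
    return mul(a, sigmoid(a))


def tsum(a, axis=None, keepdims=False):
    a = astensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return mul(g, np.ones(a.shape))
        ax = axis if isinstance(axis, tuple) else (axis,)
        ax = tuple(x % a.ndim for x in ax)
        if not keepdims:
            shp = tuple(1 if i in ax else s for i, s in enumerate(a.shape))
            g = reshape(g, shp)
        return mul(g, np.ones(a.shape))

    return Tensor(data, parents=(a,), vjps=(vjp,))


def reshape(a, shape):
    a = astensor(a)
    return Tensor(
        a.data.reshape(shape),
        parents=(a,),
        vjps=(lambda g: reshape(g, a.shape),),
    )


def getitem(a, key):
    a = astensor(a)

    def vjp(g):
        return _scatter(g, key, a.shape)

    return Tensor(a.data[key], parents=(a,), vjps=(vjp,))


class _Scatter:
    pass


def _scatter(g, key, shape):
    """Dense VJP for ``getitem``: place g at ``key`` in zeros of ``shape``."""
    g = astensor(g)

    def vjp(h):
        return getitem(h, key)

    out = np.zeros(shape)
    np.add.at(out, key, g.data)
    return Tensor(out, parents=(g,), vjps=(vjp,))


def take(a, idx, axis=0):
    """Gather rows of ``a`` along ``axis`` 0 by an integer index array."""
    a = astensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    if axis != 0:
        raise NotImplementedError("take supports axis=0 only")
    return Tensor(
        a.data[idx],
        parents=(a,),
        vjps=(lambda g: segment_sum(g, idx, a.shape[0]),),
    )


def segment_sum(a, seg, num):
    """Sum rows of ``a`` (axis 0) into ``num`` bins given by ``seg``."""
    a = astensor(a)
    seg = np.asarray(seg, dtype=np.intp)
    out = np.zeros((num,) + a.shape[1:])
    np.add.at(out, seg, a.data)
    return Tensor(out, parents=(a,), vjps=(lambda g: take(g, seg, axis=0),))


def concat(tensors, axis=-1):
    tensors = [astensor(t) for t in tensors]
    ax = axis % tensors[0].ndim
    sizes = [t.shape[ax] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(k):
        def vjp(g):
            key = tuple(
                slice(offsets[k], offsets[k + 1]) if i == ax else slice(None)
                for i in range(g.ndim)
            )
            return getitem(g, key)

        return vjp

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=ax),
        parents=tuple(tensors),
        vjps=tuple(make_vjp(k) for k in range(len(tensors))),
    )


def einsum(spec, *tensors):
    """``np.einsum`` with explicit indices (no ellipsis).

    Every index must appear in at least two places among operands and
    output so that each operand's VJP is itself an einsum.
    """
    tensors = [astensor(t) for t in tensors]
    inputs, out = spec.replace(" ", "").split("->")
    ins = inputs.split(",")
    if len(ins) != len(tensors):
        raise ValueError(f"einsum spec {spec!r} expects {len(ins)} operands")
    for k, term in enumerate(ins):
        others = set(out) | set("".join(t for i, t in enumerate(ins) if i != k))
        if not set(term) <= others:
            raise ValueError(f"einsum spec {spec!r}: operand {k} has a free index")

    def make_vjp(k):
        def vjp(g):
            operands = [g] + [t for i, t in enumerate(tensors) if i != k]
            terms = [out] + [t for i, t in enumerate(ins) if i != k]
            sub = ",".join(terms) + "->" + ins[k]
            return einsum(sub, *operands)

        return vjp

    return Tensor(
        np.einsum(spec, *[t.data for t in tensors], optimize=True),
        parents=tuple(tensors),
        vjps=tuple(make_vjp(k) for k in range(len(tensors))),
    )


# -- reverse pass ----------------------------------------------------------

def grad(output, wrt, grad_output=None, create_graph=False):
    """Gradients of a scalar (or seeded) ``output`` w.r.t. ``wrt`` tensors.

    With ``create_graph=True`` the returned gradients carry their own
    backward graph so they can be differentiated again.
    """
    single = isinstance(wrt, Tensor)
    wrt_list = [wrt] if single else list(wrt)
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))

    # topological order over the subgraph that requires grad
    topo: list[Tensor] = []
    seen = set()

    def visit(t: Tensor):
        stack = [(t, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))

    visit(output)
    cotangents: dict[int, Tensor] = {id(output): astensor(grad_output)}

    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(topo):
            g = cotangents.pop(id(node), None)
            if g is None:
                continue
            for parent, vjp in zip(node.parents, node.vjps):
                if not parent.requires_grad:
                    continue
                contrib = vjp(g)
                prev = cotangents.get(id(parent))
                cotangents[id(parent)] = contrib if prev is None else add(prev, contrib)
            # keep cotangents of requested leaves
            if any(node is w for w in wrt_list):
                cotangents[id(node)] = g

    result = []
    for w in wrt_list:
        g = cotangents.get(id(w))
        if g is None:
            g = Tensor(np.zeros_like(w.data))
        result.append(g)
    return result[0] if single else result
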