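"""Minimal reverse-mode automatic differentiation over numpy arrays.

The energy model needs analytic forces (gradients of a scalar energy with
respect to atomic positions, differentiating through a constrained linear
solve) and the trainer needs gradients of a loss that itself contains
forces — i.e. second-order, mixed position/parameter derivatives.  Every
vector-Jacobian product below is therefore expressed in terms of the same
``Tensor`` operations, so calling :func:`grad` with ``create_graph=True``
yields a graph that can be differentiated again.

Only the operations the package actually uses are implemented; this is not
a general tensor framework.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _special

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager that disables graph construction."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


class Tensor:
    __slots__ = ("data", "requires_grad", "grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        # list of (parent Tensor, vjp: cotangent Tensor -> cotangent Tensor)
        self._parents = _parents or []

    # -- plumbing -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    # -- operators ----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(astensor(other)))

    def __rsub__(self, other):
        return add(astensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return take(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    @property
    def T(self):
        return transpose(self)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _tracked(*ts) -> bool:
    return _GRAD_ENABLED[0] and any(
        isinstance(t, Tensor) and (t.requires_grad or t._parents) for t in ts
    )


def _make(data, parents) -> Tensor:
    return Tensor(data, _parents=parents)


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Sum a cotangent down to ``shape`` (reverse of numpy broadcasting)."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return reshape(g, shape)


# -- primitive operations ---------------------------------------------------

def add(a, b):
    a, b = astensor(a), astensor(b)
    out = a.data + b.data
    if not _tracked(a, b):
        return Tensor(out)
    return _make(out, [(a, lambda g: _unbroadcast(g, a.shape)),
                       (b, lambda g: _unbroadcast(g, b.shape))])


def neg(a):
    a = astensor(a)
    if not _tracked(a):
        return Tensor(-a.data)
    return _make(-a.data, [(a, lambda g: neg(g))])


def mul(a, b):
    a, b = astensor(a), astensor(b)
    out = a.data * b.data
    if not _tracked(a, b):
        return Tensor(out)
    return _make(out, [(a, lambda g: _unbroadcast(mul(g, b), a.shape)),
                       (b, lambda g: _unbroadcast(mul(g, a), b.shape))])


def power(a, p: float):
    a = astensor(a)
    out = a.data ** p
    if not _tracked(a):
        return Tensor(out)
    return _make(out, [(a, lambda g: mul(g, mul(p, power(a, p - 1.0))))])


def texp(a):
    a = astensor(a)
    out = np.exp(a.data)
    if not _tracked(a):
        return Tensor(out)
    res = _make(out, [])
    res._parents.append((a, lambda g: mul(g, texp(a))))
    return res


def tlog(a):
    a = astensor(a)
    if not _tracked(a):
        return Tensor(np.log(a.data))
    return _make(np.log(a.data), [(a, lambda g: mul(g, power(a, -1.0)))])


def tsqrt(a):
    return power(a, 0.5)


def tsin(a):
    a = astensor(a)
    if not _tracked(a):
        return Tensor(np.sin(a.data))
    return _make(np.sin(a.data), [(a, lambda g: mul(g, tcos(a)))])


def tcos(a):
    a = astensor(a)
    if not _tracked(a):
        return Tensor(np.cos(a.data))
    return _make(np.cos(a.data), [(a, lambda g: mul(g, neg(tsin(a))))])


_TWO_OVER_SQRT_PI = 2.0 / np.sqrt(np.pi)


def terf(a):
    a = astensor(a)
    out = _special.erf(a.data)
    if not _tracked(a):
        return Tensor(out)
    return _make(out, [(a, lambda g: mul(g, mul(_TWO_OVER_SQRT_PI,
                                                texp(neg(mul(a, a))))))])


def tarccos(a):
    a = astensor(a)
    out = np.arccos(np.clip(a.data, -1.0, 1.0))
    if not _tracked(a):
        return Tensor(out)
    # d/dx arccos(x) = -1/sqrt(1-x^2); callers keep |x| strictly below 1
    return _make(out, [(a, lambda g: neg(mul(g, power(add(1.0, neg(mul(a, a))), -0.5))))])


def ttanh(a):
    a = astensor(a)
    out = np.tanh(a.data)
    if not _tracked(a):
        return Tensor(out)
    res = _make(out, [])
    res._parents.append((a, lambda g: mul(g, add(1.0, neg(mul(ttanh(a), ttanh(a)))))))
    return res


def where(cond, a, b):
    """Piecewise select; ``cond`` is a constant boolean array."""
    cond = np.asarray(cond)
    a, b = astensor(a), astensor(b)
    out = np.where(cond, a.data, b.data)
    if not _tracked(a, b):
        return Tensor(out)
    zero = 0.0
    return _make(out, [
        (a, lambda g: _unbroadcast(where(cond, g, Tensor(np.zeros_like(g.data))), a.shape)),
        (b, lambda g: _unbroadcast(where(cond, Tensor(np.zeros_like(g.data)), g), b.shape)),
    ])


def celu(a, alpha: float = 0.1):
    """Smooth CELU activation: x for x>0, alpha*(exp(x/alpha)-1) otherwise."""
    a = astensor(a)
    mask = a.data > 0
    # evaluate exp only on the negative branch to avoid overflow
    safe = where(mask, Tensor(np.zeros_like(a.data)), a)
    return where(mask, a, mul(alpha, add(texp(mul(safe, 1.0 / alpha)), -1.0)))


def matmul(a, b):
    a, b = astensor(a), astensor(b)
    out = a.data @ b.data
    if not _tracked(a, b):
        return Tensor(out)
    if a.ndim == 1 and b.ndim == 2:
        return _make(out, [(a, lambda g: matmul(g, transpose(b))),
                           (b, lambda g: mul(reshape(a, (-1, 1)), reshape(g, (1, -1))))])
    if a.ndim == 2 and b.ndim == 1:
        return _make(out, [(a, lambda g: mul(reshape(g, (-1, 1)), reshape(b, (1, -1)))),
                           (b, lambda g: matmul(transpose(a), g))])
    if a.ndim == 2 and b.ndim == 2:
        return _make(out, [(a, lambda g: matmul(g, transpose(b))),
                           (b, lambda g: matmul(transpose(a), g))])
    raise ValueError("matmul supports 1-D/2-D operands only")


def tsum(a, axis=None, keepdims=False):
    a = astensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)
    if not _tracked(a):
        return Tensor(out)

    def vjp(g):
        gd = g
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(x % a.ndim for x in ax)
            shape = tuple(1 if i in ax else s for i, s in enumerate(a.shape))
            gd = reshape(gd, shape)
        return broadcast_to(gd, a.shape)

    return _make(out, [(a, vjp)])


def broadcast_to(a, shape):
    a = astensor(a)
    out = np.broadcast_to(a.data, shape)
    if not _tracked(a):
        return Tensor(out.copy())
    return _make(out.copy(), [(a, lambda g: _unbroadcast(g, a.shape))])


def reshape(a, shape):
    a = astensor(a)
    out = a.data.reshape(shape)
    if not _tracked(a):
        return Tensor(out)
    return _make(out, [(a, lambda g: reshape(g, a.shape))])


def transpose(a, axes=None):
    a = astensor(a)
    out = a.data.T if axes is None else a.data.transpose(axes)
    if not _tracked(a):
        return Tensor(out)
    inv = None if axes is None else tuple(np.argsort(axes))
    return _make(out, [(a, lambda g: transpose(g, inv))])


def take(a, key):
    """Indexing; cotangent is scatter-added back (duplicate indices sum)."""
    a = astensor(a)
    out = a.data[key]
    if not _tracked(a):
        return Tensor(out)
    return _make(out, [(a, lambda g: scatter(a.shape, key, g))])


def _scatter_np(shape, key, src: np.ndarray) -> np.ndarray:
    # bincount on raveled indices is much faster than np.add.at
    if (isinstance(key, tuple)
            and all(isinstance(k, np.ndarray) and k.dtype.kind == "i" for k in key)):
        head = np.ravel_multi_index(key, shape[:len(key)])
        rem = int(np.prod(shape[len(key):], dtype=int))
        total = int(np.prod(shape, dtype=int))
        if rem == 1:
            flat = np.bincount(head, weights=src.ravel(), minlength=total)
        else:
            idx = (head[:, None] * rem + np.arange(rem)[None, :]).ravel()
            flat = np.bincount(idx, weights=src.reshape(len(head), rem).ravel(),
                               minlength=total)
        return flat.reshape(shape)
    data = np.zeros(shape)
    np.add.at(data, key, src)
    return data


def scatter(shape, key, src):
    src = astensor(src)
    data = _scatter_np(shape, key, src.data)
    if not _tracked(src):
        return Tensor(data)
    return _make(data, [(src, lambda g: take(g, key))])


def concat(parts, axis=0):
    parts = [astensor(p) for p in parts]
    out = np.concatenate([p.data for p in parts], axis=axis)
    if not _tracked(*parts):
        return Tensor(out)
    sizes = [p.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)
    parents = []
    for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
        idx = [slice(None)] * out.ndim
        idx[axis] = slice(int(lo), int(hi))
        idx = tuple(idx)
        parents.append((p, lambda g, idx=idx: take(g, idx)))
    return _make(out, parents)


def stack(parts, axis=0):
    parts = [astensor(p) for p in parts]
    out = np.stack([p.data for p in parts], axis=axis)
    if not _tracked(*parts):
        return Tensor(out)
    parents = []
    for i, p in enumerate(parts):
        idx = [slice(None)] * out.ndim
        idx[axis] = i
        idx = tuple(idx)
        parents.append((p, lambda g, idx=idx: take(g, idx)))
    return _make(out, parents)


def solve(A, b):
    """Solve A x = b (A square 2-D, b 1-D); differentiable in both."""
    A, b = astensor(A), astensor(b)
    x = np.linalg.solve(A.data, b.data)
    if not _tracked(A, b):
        return Tensor(x)
    out = _make(x, [])

    def vjp_A(g):
        gb = solve(transpose(A), g)
        return neg(mul(reshape(gb, (-1, 1)), reshape(out, (1, -1))))

    def vjp_b(g):
        return solve(transpose(A), g)

    out._parents.append((A, vjp_A))
    out._parents.append((b, vjp_b))
    return out


def solve_batched(A, b):
    """Solve a stack of linear systems: A (B, m, m), b (B, m)."""
    A, b = astensor(A), astensor(b)
    x = np.linalg.solve(A.data, b.data[..., None])[..., 0]
    if not _tracked(A, b):
        return Tensor(x)
    out = _make(x, [])

    def _solve_T(g):
        return solve_batched(transpose(A, (0, 2, 1)), g)

    def vjp_A(g):
        gb = _solve_T(g)
        B_, m = x.shape
        return neg(mul(reshape(gb, (B_, m, 1)), reshape(out, (B_, 1, m))))

    out._parents.append((A, vjp_A))
    out._parents.append((b, _solve_T))
    return out


# -- backward ---------------------------------------------------------------

def _topo(root: Tensor):
    order, seen, stack_ = [], set(), [(root, False)]
    while stack_:
        node, processed = stack_.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack_.append((node, True))
        for parent, _ in node._parents:
            if id(parent) not in seen:
                stack_.append((parent, False))
    return order  # parents before children


def grad(output: Tensor, inputs, create_graph: bool = False,
         grad_output: Tensor | None = None, free_graph: bool | None = None):
    """Cotangents of ``output`` w.r.t. each tensor in ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own graph,
    enabling higher-order differentiation.  Unless ``create_graph`` (or
    ``free_graph=False``), the traversed graph is dismantled afterwards —
    vjp closures hold reference cycles that otherwise pile up for the
    cyclic collector.  Pass ``free_graph=False`` to backward through the
    same graph again.
    """
    if free_graph is None:
        free_graph = not create_graph
    single = isinstance(inputs, Tensor)
    if single:
        inputs = [inputs]
    grads: dict[int, Tensor] = {}
    seed = grad_output if grad_output is not None else Tensor(np.ones_like(output.data))
    grads[id(output)] = astensor(seed)
    order = _topo(output)
    ctx = no_grad() if not create_graph else _NullCtx()
    with ctx:
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else add(node.grad, g)
            for parent, vjp in node._parents:
                contrib = vjp(g)
                prev = grads.get(id(parent))
                grads[id(parent)] = contrib if prev is None else add(prev, contrib)
    result = []
    for t in inputs:
        gt = t.grad if t.grad is not None else Tensor(np.zeros_like(t.data))
        t.grad = None
        result.append(gt)
    # clear grads left on other leaves
    for node in order:
        node.grad = None
    if free_graph:
        for node in order:
            node._parents.clear()
    return result[0] if single else result


class _NullCtx:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False
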