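"""Reverse-mode automatic differentiation on numpy arrays.

The adversarial training objective needs gradients of a gradient norm (the
Lipschitz penalty differentiates the critic with respect to its *input*, and
that expression is then differentiated again with respect to the critic's
*parameters*).  Every backward rule here is therefore expressed in terms of
the same differentiable operations, so gradients are themselves graph nodes
and ``grad`` can be applied to expressions built from earlier ``grad`` calls.

Only what the package's networks require is implemented: elementwise
arithmetic with broadcasting, 2-D matmul, the usual activations, reductions,
reshaping/slicing, and concatenation.  Arrays are float64 throughout.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "parents", "grad_fn", "requires_grad")

    def __init__(self, data, parents=(), grad_fn=None, requires_grad=None):
        self.data = np.asarray(data, dtype=float)
        self.parents = parents
        self.grad_fn = grad_fn
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in parents)
        self.requires_grad = requires_grad

    # -- conveniences ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __neg__(self):
        return mul(self, _wrap(-1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __pow__(self, p):
        return pow_const(self, p)

    def __getitem__(self, idx):
        return take(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    @property
    def T(self):
        return transpose(self)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def item(self):
        return float(self.data)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)


def constant(x) -> Tensor:
    """A graph leaf that never receives gradients."""
    return Tensor(np.asarray(x, dtype=float), requires_grad=False)


def parameter(x) -> Tensor:
    """A trainable leaf."""
    return Tensor(np.array(x, dtype=float), requires_grad=True)


# ---------------------------------------------------------------------------
# broadcasting helper: reduce a gradient back to a parent's shape, using
# differentiable ops so second-order gradients stay available
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape) -> Tensor:
    gshape = g.data.shape
    if gshape == tuple(shape):
        return g
    ndiff = len(gshape) - len(shape)
    axes = list(range(ndiff))
    for i, s in enumerate(shape):
        if s == 1 and gshape[ndiff + i] != 1:
            axes.append(ndiff + i)
    if axes:
        g = tsum(g, axis=tuple(axes), keepdims=True)
    return reshape(g, tuple(shape))


def _expand(g: Tensor, shape) -> Tensor:
    """Broadcast a (possibly reduced) gradient up to ``shape``."""
    if g.data.shape == tuple(shape):
        return g
    return mul(g, constant(np.ones(shape)))


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))
    out.grad_fn = lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, (a, b))
    out.grad_fn = lambda g: (
        _unbroadcast(g, a.shape),
        _unbroadcast(mul(g, constant(-1.0)), b.shape),
    )
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))
    out.grad_fn = lambda g: (
        _unbroadcast(mul(g, b), a.shape),
        _unbroadcast(mul(g, a), b.shape),
    )
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data, (a, b))
    out.grad_fn = lambda g: (
        _unbroadcast(div(g, b), a.shape),
        _unbroadcast(mul(mul(g, constant(-1.0)), div(a, mul(b, b))), b.shape),
    )
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))
    out.grad_fn = lambda g: (matmul(g, transpose(b)), matmul(transpose(a), g))
    return out


def pow_const(a: Tensor, p: float) -> Tensor:
    out = Tensor(a.data ** p, (a,))
    out.grad_fn = lambda g: (mul(g, mul(constant(p), pow_const(a, p - 1))),)
    return out


def exp(a: Tensor) -> Tensor:
    out = Tensor(np.exp(a.data), (a,))
    out.grad_fn = lambda g: (mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), (a,))
    out.grad_fn = lambda g: (div(g, a),)
    return out


def sqrt(a: Tensor) -> Tensor:
    out = Tensor(np.sqrt(a.data), (a,))
    out.grad_fn = lambda g: (div(g, mul(constant(2.0), out)),)
    return out


def tanh(a: Tensor) -> Tensor:
    out = Tensor(np.tanh(a.data), (a,))
    out.grad_fn = lambda g: (mul(g, sub(constant(1.0), mul(out, out))),)
    return out


def sigmoid(a: Tensor) -> Tensor:
    out = Tensor(1.0 / (1.0 + np.exp(-a.data)), (a,))
    out.grad_fn = lambda g: (mul(g, mul(out, sub(constant(1.0), out))),)
    return out


def relu(a: Tensor) -> Tensor:
    mask = (a.data > 0).astype(float)
    out = Tensor(a.data * mask, (a,))
    out.grad_fn = lambda g: (mul(g, constant(mask)),)
    return out


def absolute(a: Tensor) -> Tensor:
    # subgradient 0 at the kink, matching np.sign(0) == 0
    sign = np.sign(a.data)
    out = Tensor(np.abs(a.data), (a,))
    out.grad_fn = lambda g: (mul(g, constant(sign)),)
    return out


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def backward(g):
        if axis is not None and not keepdims:
            kshape = list(a.shape)
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in axes:
                kshape[ax] = 1
            g = reshape(g, tuple(kshape))
        elif axis is None and not keepdims:
            g = reshape(g, (1,) * a.data.ndim) if a.data.ndim else g
        return (_expand(g, a.shape),)

    out.grad_fn = backward
    return out


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return div(tsum(a, axis=axis, keepdims=keepdims), constant(float(n)))


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), (a,))
    out.grad_fn = lambda g: (reshape(g, a.shape),)
    return out


def transpose(a: Tensor) -> Tensor:
    out = Tensor(a.data.T, (a,))
    out.grad_fn = lambda g: (transpose(g),)
    return out


def take(a: Tensor, idx) -> Tensor:
    out = Tensor(a.data[idx], (a,))
    out.grad_fn = lambda g: (scatter(g, idx, a.shape),)
    return out


def scatter(t: Tensor, idx, shape) -> Tensor:
    buf = np.zeros(shape)
    np.add.at(buf, idx, t.data)
    out = Tensor(buf, (t,))
    out.grad_fn = lambda g: (take(g, idx),)
    return out


def flip(a: Tensor, axis: int) -> Tensor:
    out = Tensor(np.flip(a.data, axis=axis).copy(), (a,))
    out.grad_fn = lambda g: (flip(g, axis),)
    return out


def concat(tensors, axis=0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * g.data.ndim
            index[axis] = slice(int(lo), int(hi))
            grads.append(take(g, tuple(index)))
        return tuple(grads)

    out.grad_fn = backward
    return out


def stack(tensors, axis=1) -> Tensor:
    """Stack equal-shape tensors along a new axis (built from reshape+concat)."""
    expanded = []
    for t in tensors:
        shape = list(t.shape)
        shape.insert(axis, 1)
        expanded.append(reshape(t, tuple(shape)))
    return concat(expanded, axis=axis)


def softmax(a: Tensor, axis=-1) -> Tensor:
    """Numerically stable softmax; the max-shift is treated as a constant."""
    shift = constant(a.data.max(axis=axis, keepdims=True))
    e = exp(sub(a, shift))
    return div(e, tsum(e, axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# reverse-mode driver
# ---------------------------------------------------------------------------

def grad(output: Tensor, inputs, seed=None):
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    Returned gradients are themselves :class:`Tensor` graph nodes, so a
    scalar built from them can be differentiated again.
    """
    if seed is None:
        if output.data.size != 1:
            raise ValueError("grad needs a scalar output (or an explicit seed)")
        seed = constant(np.ones_like(output.data))

    topo = _toposort(output)  # root first, leaves last
    grads = {id(output): seed}
    for node in topo:
        g = grads.get(id(node))
        if g is None or node.grad_fn is None:
            continue
        for p, pg in zip(node.parents, node.grad_fn(g)):
            if pg is None or not p.requires_grad:
                continue
            acc = grads.get(id(p))
            grads[id(p)] = pg if acc is None else add(acc, pg)
    return [
        grads.get(id(t), constant(np.zeros(t.shape))) for t in inputs
    ]


def _toposort(root: Tensor):
    """Iterative DFS topological order (outputs first)."""
    out, seen = [], set()
    stack_ = [(root, iter(root.parents))]
    if not root.requires_grad:
        return out
    seen.add(id(root))
    while stack_:
        node, it = stack_[-1]
        advanced = False
        for child in it:
            if child.requires_grad and id(child) not in seen:
                seen.add(id(child))
                stack_.append((child, iter(child.parents)))
                advanced = True
                break
        if not advanced:
            out.append(node)
            stack_.pop()
    out.reverse()
    return out
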