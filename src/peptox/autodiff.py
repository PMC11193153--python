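"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The network in :mod:`peptox.model` is small (tens of thousands of
parameters) and runs on CPU, so a compact tape-based engine over whole
arrays is sufficient: every operation builds a node recording its parents
and a closure that accumulates gradients into them.  Broadcasting follows
NumPy semantics; gradients of broadcast operands are summed back to the
operand's shape.

Only the operations the model needs are provided.  All of them are pure
functions of ``Tensor`` and/or plain array/scalar operands; plain operands
are treated as constants.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "concat",
    "matmul",
    "relu",
    "sigmoid",
    "tanh",
    "exp",
    "log",
    "sqrt",
    "clip",
    "softmax",
    "vector_norm",
    "gather_rows",
    "scatter_add_rows",
    "Adam",
]


class Tensor:
    """An array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape),
                                 dtype=np.float64)
        else:
            self.grad += g

    def _accumulate_at(self, idx, g, exact=False):
        """Accumulate into a sub-view without allocating a full buffer.

        ``exact`` marks index expressions free of duplicate positions
        (slices/ints), where plain in-place addition is valid; fancy
        integer indices go through ``np.add.at``.
        """
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        if exact:
            self.grad[idx] += g
        else:
            np.add.at(self.grad, idx, g)

    def backward(self, grad=None):
        """Run reverse-mode accumulation from this node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, processed = stack.pop()
                if processed:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return _add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return _mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return _add(self, _const_neg(other))

    def __rsub__(self, other):
        return _add(-self, other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return _mul(self, other ** -1.0)
        return _mul(self, 1.0 / np.asarray(other, dtype=np.float64))

    def __rtruediv__(self, other):
        return _mul(self ** -1.0, other)

    def __pow__(self, p):
        x = self
        out = Tensor(x.data ** p, parents=(x,))

        def backward(g):
            x._accumulate(_unbroadcast(g * p * x.data ** (p - 1), x.data.shape))

        out._backward = backward
        return out

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        x = self
        idx_tuple = idx if isinstance(idx, tuple) else (idx,)
        exact = all(isinstance(i, (slice, int, np.integer))
                    for i in idx_tuple)
        out = Tensor(x.data[idx], parents=(x,))

        def backward(g):
            x._accumulate_at(idx, g, exact=exact)

        out._backward = backward
        return out

    def reshape(self, *shape):
        x = self
        out = Tensor(x.data.reshape(*shape), parents=(x,))

        def backward(g):
            x._accumulate(g.reshape(x.data.shape))

        out._backward = backward
        return out

    def transpose(self, axes):
        x = self
        inv = np.argsort(axes)
        out = Tensor(x.data.transpose(axes), parents=(x,))

        def backward(g):
            x._accumulate(g.transpose(inv))

        out._backward = backward
        return out

    def swapaxes(self, a, b):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(tuple(axes))

    def sum(self, axis=None, keepdims=False):
        x = self
        out = Tensor(x.data.sum(axis=axis, keepdims=keepdims), parents=(x,))

        def backward(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            x._accumulate(np.broadcast_to(gg, x.data.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def tensor(data, requires_grad=False):
    return Tensor(data, requires_grad=requires_grad)


def _as_const(x):
    return np.asarray(x, dtype=np.float64)


def _const_neg(x):
    return -x if isinstance(x, Tensor) else -_as_const(x)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (the operand's pre-broadcast shape)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _add(a, b):
    if not isinstance(b, Tensor):
        b_data = _as_const(b)
        out = Tensor(a.data + b_data, parents=(a,))

        def backward(g):
            a._accumulate(_unbroadcast(g, a.data.shape))

        out._backward = backward
        return out
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def _mul(a, b):
    if not isinstance(b, Tensor):
        b_data = _as_const(b)
        out = Tensor(a.data * b_data, parents=(a,))

        def backward(g):
            a._accumulate(_unbroadcast(g * b_data, a.data.shape))

        out._backward = backward
        return out
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def matmul(a, b):
    """Batched matrix product with NumPy broadcasting of batch axes."""
    a_t = a if isinstance(a, Tensor) else Tensor(a)
    b_t = b if isinstance(b, Tensor) else Tensor(b)
    out = Tensor(a_t.data @ b_t.data, parents=(a_t, b_t))

    def backward(g):
        if a_t.requires_grad:
            ga = g @ np.swapaxes(b_t.data, -1, -2)
            a_t._accumulate(_unbroadcast(ga, a_t.data.shape))
        if b_t.requires_grad:
            gb = np.swapaxes(a_t.data, -1, -2) @ g
            b_t._accumulate(_unbroadcast(gb, b_t.data.shape))

    out._backward = backward
    return out


def concat(tensors, axis=-1):
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out


def _unary(x, value, dvalue):
    out = Tensor(value, parents=(x,))

    def backward(g):
        x._accumulate(g * dvalue)

    out._backward = backward
    return out


def relu(x):
    return _unary(x, np.maximum(x.data, 0.0), (x.data > 0).astype(np.float64))


def sigmoid(x):
    s = 1.0 / (1.0 + np.exp(-x.data))
    return _unary(x, s, s * (1.0 - s))


def tanh(x):
    t = np.tanh(x.data)
    return _unary(x, t, 1.0 - t * t)


def exp(x):
    e = np.exp(x.data)
    return _unary(x, e, e)


def log(x):
    return _unary(x, np.log(x.data), 1.0 / x.data)


def sqrt(x):
    s = np.sqrt(x.data)
    return _unary(x, s, 0.5 / np.maximum(s, 1e-300))


def clip(x, lo, hi):
    inside = ((x.data > lo) & (x.data < hi)).astype(np.float64)
    return _unary(x, np.clip(x.data, lo, hi), inside)


def softmax(x, axis=-1):
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    p = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(p, parents=(x,))

    def backward(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        x._accumulate(p * (g - dot))

    out._backward = backward
    return out


def vector_norm(x, axis=-1):
    """Euclidean norm along ``axis``; exact zero forward for zero vectors,
    with a guarded backward so zero-norm inputs get zero gradient."""
    n = np.linalg.norm(x.data, axis=axis)
    out = Tensor(n, parents=(x,))

    def backward(g):
        safe = np.where(n > 0, n, 1.0)
        x._accumulate(np.expand_dims(g / safe, axis) * x.data)

    out._backward = backward
    return out


def gather_rows(x, index):
    """Select rows of a 2-D (or leading-axis) tensor: ``x[index]``."""
    return x[np.asarray(index)]


def scatter_add_rows(x, index, n_rows):
    """Sum rows of ``x`` into ``n_rows`` output rows keyed by ``index``."""
    index = np.asarray(index)
    shape = (n_rows,) + x.data.shape[1:]
    buf = np.zeros(shape)
    np.add.at(buf, index, x.data)
    out = Tensor(buf, parents=(x,))

    def backward(g):
        x._accumulate(g[index])

    out._backward = backward
    return out


class Adam:
    """Adam optimizer over a dict of parameter Tensors, with optional
    decoupled-from-nothing classic L2 weight decay added to gradients."""

    def __init__(self, params, lr=4e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m = self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            v = self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
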