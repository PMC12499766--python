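"""Minimal reverse-mode automatic differentiation over numpy arrays.

The binding model is small (a few hundred thousand scalars at most) and is
trained on desk-scale graphs, so a compact tape-based engine over float64
numpy arrays is sufficient.  Only the primitives the encoder and losses need
are implemented; every primitive's vector-Jacobian product is exercised by
finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "concat", "fixed_matmul", "Adam", "SGD"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, parents=(), vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = parents
        self._vjp = vjp  # callable(out_grad) -> accumulates into parents

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff machinery --------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._vjp is not None and node.grad is not None:
                node._vjp(node.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def vjp(g):
                if self.requires_grad:
                    self._accumulate(g)
                if other.requires_grad:
                    other._accumulate(g)
            out._vjp = vjp
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._vjp = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def vjp(g):
                if self.requires_grad:
                    self._accumulate(g * other.data)
                if other.requires_grad:
                    other._accumulate(g * self.data)
            out._vjp = vjp
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def vjp(g):
                if self.requires_grad:
                    self._accumulate(g / other.data)
                if other.requires_grad:
                    other._accumulate(-g * self.data / other.data ** 2)
            out._vjp = vjp
        return out

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent: float):
        out = _make(self.data ** exponent, (self,))
        if out.requires_grad:
            out._vjp = lambda g: self._accumulate(
                g * exponent * self.data ** (exponent - 1)
            )
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out.requires_grad:
            def vjp(g):
                if self.requires_grad:
                    self._accumulate(g @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ g)
            out._vjp = vjp
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = _make(val, (self,))
        if out.requires_grad:
            out._vjp = lambda g: self._accumulate(g * val)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out.requires_grad:
            out._vjp = lambda g: self._accumulate(g / self.data)
        return out

    def relu(self):
        mask = self.data > 0
        out = _make(self.data * mask, (self,))
        if out.requires_grad:
            out._vjp = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self):
        val = _sigmoid(self.data)
        out = _make(val, (self,))
        if out.requires_grad:
            out._vjp = lambda g: self._accumulate(g * val * (1.0 - val))
        return out

    def softplus(self):
        # numerically stable log(1+exp(x))
        val = np.logaddexp(0.0, self.data)
        out = _make(val, (self,))
        if out.requires_grad:
            sig = _sigmoid(self.data)
            out._vjp = lambda g: self._accumulate(g * sig)
        return out

    def sqrt(self):
        return self ** 0.5

    def clip_min(self, floor: float):
        """max(x, floor); gradient passes only where x > floor."""
        mask = self.data > floor
        out = _make(np.maximum(self.data, floor), (self,))
        if out.requires_grad:
            out._vjp = lambda g: self._accumulate(g * mask)
        return out

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def vjp(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))
            out._vjp = vjp
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))
        if out.requires_grad:
            out._vjp = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    @property
    def T(self):
        out = _make(self.data.T, (self,))
        if out.requires_grad:
            out._vjp = lambda g: self._accumulate(g.T)
        return out

    def gather(self, index):
        """Row gather: out[i] = self[index[i]]."""
        index = np.asarray(index, dtype=np.intp)
        out = _make(self.data[index], (self,))
        if out.requires_grad:
            def vjp(g):
                acc = np.zeros_like(self.data)
                np.add.at(acc, index, g)
                self._accumulate(acc)
            out._vjp = vjp
        return out

    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        val = e / e.sum(axis=axis, keepdims=True)
        out = _make(val, (self,))
        if out.requires_grad:
            def vjp(g):
                dot = (g * val).sum(axis=axis, keepdims=True)
                self._accumulate((g - dot) * val)
            out._vjp = vjp
        return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _make(data, parents) -> Tensor:
    rg = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=rg, parents=tuple(p for p in parents if p.requires_grad))


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def vjp(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._vjp = vjp
    return out


def fixed_matmul(matrix, t: Tensor) -> Tensor:
    """Product `matrix @ t` with a constant (possibly sparse) left factor."""
    t = astensor(t)
    out = _make(matrix @ t.data, (t,))
    if out.requires_grad:
        mt = matrix.T
        out._vjp = lambda g: t._accumulate(mt @ g)
    return out


class SGD:
    """Plain gradient step; `maximize=True` ascends (used for the saddle α)."""

    def __init__(self, params: dict, lr: float, maximize: bool = False):
        self.params = params
        self.lr = lr
        self.sign = 1.0 if maximize else -1.0

    def step(self):
        for t in self.params.values():
            if t.grad is not None:
                t.data = t.data + self.sign * self.lr * t.grad

    def zero_grad(self):
        for t in self.params.values():
            t.grad = None


class Adam:
    """Adaptive moment estimation over a dict of named Tensors.

    ``decay_exclude`` is a predicate on parameter names; matching parameters
    (conventionally biases, normalization gains/offsets, and wide linear
    terms) are exempt from weight decay.
    """

    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 decay_exclude=None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decay_exclude = decay_exclude or (lambda name: False)
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self):
        self.t += 1
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and not self.decay_exclude(name):
                g = g + self.weight_decay * p.data
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1 ** self.t)
            vhat = self.v[name] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None
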