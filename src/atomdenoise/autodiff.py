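"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the operations the structural losses and the
equivariant network need: broadcasting arithmetic, matmul, reductions,
elementwise nonlinearities, gather/indexing, stacking and trigonometry.
Gradients are accumulated by a topological-order backward sweep.

Only ``Tensor`` leaves created with ``requires_grad=True`` (typically model
parameters and coordinate arrays) receive ``.grad``; everything else is
treated as a constant.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, value, requires_grad: bool = False, parents=(), backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.value)

    def detach(self) -> "Tensor":
        return Tensor(self.value)

    # -- autograd core --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.value)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and not t._parents:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if pg is None:
                        continue
                    key = id(parent)
                    grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        o = as_tensor(other)
        out = Tensor(self.value + o.value, parents=(self, o))
        out._backward = lambda g: (
            _unbroadcast(g, self.value.shape),
            _unbroadcast(g, o.value.shape),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        o = as_tensor(other)
        out = Tensor(self.value * o.value, parents=(self, o))
        out._backward = lambda g: (
            _unbroadcast(g * o.value, self.value.shape),
            _unbroadcast(g * self.value, o.value.shape),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = as_tensor(other)
        out = Tensor(self.value / o.value, parents=(self, o))
        out._backward = lambda g: (
            _unbroadcast(g / o.value, self.value.shape),
            _unbroadcast(-g * self.value / o.value**2, o.value.shape),
        )
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.value**p, parents=(self,))
        out._backward = lambda g: (g * p * self.value ** (p - 1),)
        return out

    def __matmul__(self, other):
        o = as_tensor(other)
        out = Tensor(self.value @ o.value, parents=(self, o))

        def back(g):
            a, b = self.value, o.value
            if a.ndim == 1 and b.ndim == 2:
                return g @ b.T, np.outer(a, g)
            if a.ndim == 2 and b.ndim == 1:
                return np.outer(g, b), a.T @ g
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        out._backward = back
        return out

    # -- indexing / shaping ---------------------------------------------------
    def __getitem__(self, idx):
        out = Tensor(self.value[idx], parents=(self,))

        def back(g):
            full = np.zeros_like(self.value)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = back
        return out

    def reshape(self, *shape):
        out = Tensor(self.value.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.value.shape),)
        return out

    def transpose(self, *axes):
        ax = axes or None
        out = Tensor(self.value.transpose(ax), parents=(self,))
        inv = np.argsort(ax) if ax else None
        out._backward = lambda g: (g.transpose(inv) if inv is not None else g.transpose(),)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.value.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.value.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.value.shape).copy(),)

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else np.prod(
            [self.value.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- elementwise ----------------------------------------------------------
    def exp(self):
        v = np.exp(self.value)
        out = Tensor(v, parents=(self,))
        out._backward = lambda g: (g * v,)
        return out

    def log(self):
        out = Tensor(np.log(self.value), parents=(self,))
        out._backward = lambda g: (g / self.value,)
        return out

    def sqrt(self):
        v = np.sqrt(self.value)
        out = Tensor(v, parents=(self,))
        out._backward = lambda g: (g * 0.5 / v,)
        return out

    def tanh(self):
        v = np.tanh(self.value)
        out = Tensor(v, parents=(self,))
        out._backward = lambda g: (g * (1.0 - v * v),)
        return out

    def relu(self):
        mask = self.value > 0
        out = Tensor(self.value * mask, parents=(self,))
        out._backward = lambda g: (g * mask,)
        return out

    def sigmoid(self):
        v = 1.0 / (1.0 + np.exp(-self.value))
        out = Tensor(v, parents=(self,))
        out._backward = lambda g: (g * v * (1.0 - v),)
        return out

    def sin(self):
        out = Tensor(np.sin(self.value), parents=(self,))
        out._backward = lambda g: (g * np.cos(self.value),)
        return out

    def cos(self):
        out = Tensor(np.cos(self.value), parents=(self,))
        out._backward = lambda g: (-g * np.sin(self.value),)
        return out

    def arccos(self):
        # input clipped away from +-1 by the caller; gradient -1/sqrt(1-x^2)
        out = Tensor(np.arccos(self.value), parents=(self,))
        out._backward = lambda g: (-g / np.sqrt(np.maximum(1.0 - self.value**2, 1e-12)),)
        return out

    def clip_min(self, lo: float):
        mask = self.value > lo
        out = Tensor(np.maximum(self.value, lo), parents=(self,))
        out._backward = lambda g: (g * mask,)
        return out

    def clip_max(self, hi: float):
        mask = self.value < hi
        out = Tensor(np.minimum(self.value, hi), parents=(self,))
        out._backward = lambda g: (g * mask,)
        return out

    def abs(self):
        s = np.sign(self.value)
        out = Tensor(np.abs(self.value), parents=(self,))
        out._backward = lambda g: (g * s,)
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(x, requires_grad: bool = False) -> Tensor:
    return Tensor(np.array(x, dtype=np.float64), requires_grad=requires_grad)


# -- free functions ------------------------------------------------------------
def stack(tensors, axis=0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.value for t in ts], axis=axis), parents=tuple(ts))

    def back(g):
        parts = np.split(g, len(ts), axis=axis)
        return [np.squeeze(p, axis=axis) for p in parts]

    out._backward = back
    return out


def concatenate(tensors, axis=0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.value for t in ts], axis=axis), parents=tuple(ts))
    sizes = [t.value.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: list(np.split(g, splits, axis=axis))
    return out


def where(cond: np.ndarray, a, b) -> Tensor:
    ta, tb = as_tensor(a), as_tensor(b)
    out = Tensor(np.where(cond, ta.value, tb.value), parents=(ta, tb))
    out._backward = lambda g: (
        _unbroadcast(np.where(cond, g, 0.0), ta.value.shape),
        _unbroadcast(np.where(cond, 0.0, g), tb.value.shape),
    )
    return out


def cross(a, b) -> Tensor:
    """Cross product over the last axis (size 3), built from index arithmetic."""
    ta, tb = as_tensor(a), as_tensor(b)
    ax, ay, az = ta[..., 0], ta[..., 1], ta[..., 2]
    bx, by, bz = tb[..., 0], tb[..., 1], tb[..., 2]
    return stack([ay * bz - az * by, az * bx - ax * bz, ax * by - ay * bx], axis=-1)


def norm(a, axis=-1, eps: float = 0.0) -> Tensor:
    ta = as_tensor(a)
    return ((ta * ta).sum(axis=axis) + eps).sqrt()


def arctan2(y, x) -> Tensor:
    ty, tx = as_tensor(y), as_tensor(x)
    out = Tensor(np.arctan2(ty.value, tx.value), parents=(ty, tx))
    denom = ty.value**2 + tx.value**2
    out._backward = lambda g: (
        _unbroadcast(g * tx.value / denom, ty.value.shape),
        _unbroadcast(-g * ty.value / denom, tx.value.shape),
    )
    return out


def softmax(x: Tensor, axis=-1) -> Tensor:
    x = as_tensor(x)
    shifted = x - Tensor(x.value.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis=-1) -> Tensor:
    x = as_tensor(x)
    shifted = x - Tensor(x.value.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()
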