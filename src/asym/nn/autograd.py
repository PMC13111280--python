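"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the model needs: broadcasting
arithmetic, batched matmul, pointwise nonlinearities, reductions,
shape surgery, softmax, and a handful of fused sequence primitives
(1-D convolution, max-pooling, nearest upsampling, normalisation,
linear recurrence) that get custom gradients for speed.

Arrays default to float32. A global no-grad switch is provided for
inference so the tape is not retained.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction inside the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if arr.dtype != np.float32:   # float32 is the engine-wide dtype
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # -- constructors -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping --------------------------------------------------
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

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the tape
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in node._backward(node.grad):
                if not parent.requires_grad:
                    continue
                g = _unbroadcast(g, parent.data.shape)
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=True)
                else:
                    parent.grad += g
            if node._backward is not None and node is not self:
                node.grad = None  # free intermediate grads eagerly

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(self.data + other.data, (self, other),
                           lambda g: ((self, g), (other, g)))
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        return Tensor._make(a.data * b.data, (a, b),
                            lambda g: ((a, g * b.data), (b, g * a.data)))

    __rmul__ = __mul__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: ((self, -g),))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other
        inv = 1.0 / b.data
        return Tensor._make(a.data * inv, (a, b),
                            lambda g: ((a, g * inv), (b, -g * a.data * inv * inv)))

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        d = self.data
        return Tensor._make(d ** p, (self,),
                            lambda g: ((self, g * p * d ** (p - 1)),))

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return (a, ga), (b, gb)

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    # -- pointwise ----------------------------------------------------
    def exp(self):
        out_d = np.exp(self.data)
        return Tensor._make(out_d, (self,), lambda g: ((self, g * out_d),))

    def log(self):
        d = self.data
        return Tensor._make(np.log(d), (self,), lambda g: ((self, g / d),))

    def sqrt(self):
        out_d = np.sqrt(self.data)
        return Tensor._make(out_d, (self,),
                            lambda g: ((self, g * 0.5 / out_d),))

    def tanh(self):
        out_d = np.tanh(self.data)
        return Tensor._make(out_d, (self,),
                            lambda g: ((self, g * (1.0 - out_d * out_d)),))

    def sigmoid(self):
        out_d = _sigmoid(self.data)
        return Tensor._make(out_d, (self,),
                            lambda g: ((self, g * out_d * (1.0 - out_d)),))

    def silu(self):
        s = _sigmoid(self.data)
        out_d = self.data * s
        return Tensor._make(out_d, (self,),
                            lambda g: ((self, g * (s + out_d * (1.0 - s))),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,),
                            lambda g: ((self, g * mask),))

    def softplus(self):
        d = self.data
        out_d = np.logaddexp(0.0, d)
        return Tensor._make(out_d, (self,),
                            lambda g: ((self, g * _sigmoid(d)),))

    # -- reductions ---------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_d = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.data.shape)),)

        return Tensor._make(out_d, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims=False):
        out_d = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_d).astype(self.data.dtype)
        # split ties evenly so the gradient stays well-defined
        mask /= mask.sum(axis=axis, keepdims=True)

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, g * mask),)

        return Tensor._make(out_d if keepdims else out_d.squeeze(axis),
                            (self,), bwd)

    # -- shape surgery ------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: ((self, g.reshape(orig)),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: ((self, g.transpose(inv)),))

    def swapaxes(self, a: int, b: int):
        return Tensor._make(np.swapaxes(self.data, a, b), (self,),
                            lambda g: ((self, np.swapaxes(g, a, b)),))

    def flip(self, axis: int):
        return Tensor._make(np.flip(self.data, axis=axis), (self,),
                            lambda g: ((self, np.flip(g, axis=axis)),))

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return ((self, full),)

        return Tensor._make(self.data[idx], (self,), bwd)

    def expand_dims(self, axis: int):
        return Tensor._make(np.expand_dims(self.data, axis), (self,),
                            lambda g: ((self, np.squeeze(g, axis)),))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        return tuple((t, p) for t, p in zip(tensors, parts))

    return Tensor._make(data, tuple(tensors), bwd)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple((t, np.squeeze(p, axis=axis))
                     for t, p in zip(tensors, parts))

    return Tensor._make(data, tuple(tensors), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    out_d = np.subtract(x.data, x.data.max(axis=axis, keepdims=True))
    np.exp(out_d, out=out_d)
    out_d /= out_d.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * out_d).sum(axis=axis, keepdims=True)
        return ((x, out_d * (g - dot)),)

    return Tensor._make(out_d, (x,), bwd)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy on raw logits."""
    t = np.asarray(targets, dtype=logits.data.dtype)
    z = logits.data
    loss = np.logaddexp(0.0, z) - t * z
    n = z.size

    def bwd(g):
        return ((logits, g * (_sigmoid(z) - t) / n),)

    return Tensor._make(np.float32(loss.mean()), (logits,), bwd)
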