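"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The model stack in this package (biased-attention 3D encoder, selective
state-space sequence branch, mol-attention fusion head) is small enough that a
dependency-light scalar/tensor autograd engine is the right tool: every
operation here is a thin wrapper around a NumPy primitive with an explicit
vector-Jacobian product.  Arrays are float64 throughout; determinism is
inherited from NumPy.

Only the operations the model needs are implemented.  Broadcasting follows
NumPy semantics; gradients of broadcast operands are summed back down to the
operand shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "stack", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference/eval paths)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad and _GRAD_ENABLED[-1]
        self.grad = None
        self._backward = None
        self._prev: tuple = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._prev:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)

    @staticmethod
    def _accum(node: "Tensor", grad: np.ndarray):
        if not node.requires_grad:
            return
        if node.grad is None:
            node.grad = grad.copy()
        else:
            node.grad += grad

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def bwd(out, a=self, b=other):
            Tensor._accum(a, _unbroadcast(out.grad, a.shape))
            Tensor._accum(b, _unbroadcast(out.grad, b.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(out, a=self):
            Tensor._accum(a, -out.grad)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bwd(out, a=self, b=other):
            Tensor._accum(a, _unbroadcast(out.grad * b.data, a.shape))
            Tensor._accum(b, _unbroadcast(out.grad * a.data, b.shape))

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bwd(out, a=self, b=other):
            Tensor._accum(a, _unbroadcast(out.grad / b.data, a.shape))
            Tensor._accum(b, _unbroadcast(-out.grad * a.data / (b.data**2), b.shape))

        return self._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        assert np.isscalar(exponent)

        def bwd(out, a=self):
            Tensor._accum(a, out.grad * exponent * a.data ** (exponent - 1))

        return self._make(self.data**exponent, (self,), bwd)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data

        def bwd(out, sa=self, sb=other):
            g = out.grad
            if sa.data.ndim == 1 and sb.data.ndim == 2:
                Tensor._accum(sa, g @ sb.data.T)
                Tensor._accum(sb, np.outer(sa.data, g))
            elif sa.data.ndim == 2 and sb.data.ndim == 1:
                Tensor._accum(sa, np.outer(g, sb.data))
                Tensor._accum(sb, sa.data.T @ g)
            elif sa.data.ndim == 1 and sb.data.ndim == 1:
                Tensor._accum(sa, g * sb.data)
                Tensor._accum(sb, g * sa.data)
            else:
                Tensor._accum(sa, g @ np.swapaxes(sb.data, -1, -2))
                Tensor._accum(sb, np.swapaxes(sa.data, -1, -2) @ g)

        return self._make(a @ b, (self, other), bwd)

    # -- elementwise nonlinearities --------------------------------------

    def exp(self):
        val = np.exp(self.data)

        def bwd(out, a=self, v=val):
            Tensor._accum(a, out.grad * v)

        return self._make(val, (self,), bwd)

    def log(self):
        def bwd(out, a=self):
            Tensor._accum(a, out.grad / a.data)

        return self._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        val = np.sqrt(self.data)

        def bwd(out, a=self, v=val):
            Tensor._accum(a, out.grad * 0.5 / v)

        return self._make(val, (self,), bwd)

    def tanh(self):
        val = np.tanh(self.data)

        def bwd(out, a=self, v=val):
            Tensor._accum(a, out.grad * (1.0 - v**2))

        return self._make(val, (self,), bwd)

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(out, a=self, v=val):
            Tensor._accum(a, out.grad * v * (1.0 - v))

        return self._make(val, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(out, a=self, m=mask):
            Tensor._accum(a, out.grad * m)

        return self._make(self.data * mask, (self,), bwd)

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        val = self.data * sig

        def bwd(out, a=self, s=sig, v=val):
            Tensor._accum(a, out.grad * (s + v * (1.0 - s)))

        return self._make(val, (self,), bwd)

    def softplus(self):
        # numerically stable log(1 + e^x)
        val = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(out, a=self, s=sig):
            Tensor._accum(a, out.grad * s)

        return self._make(val, (self,), bwd)

    def abs(self):
        sign = np.sign(self.data)

        def bwd(out, a=self, s=sign):
            Tensor._accum(a, out.grad * s)

        return self._make(np.abs(self.data), (self,), bwd)

    # -- reductions / shape ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def bwd(out, a=self, ax=axis, kd=keepdims):
            g = out.grad
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            Tensor._accum(a, np.broadcast_to(g, a.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    @property
    def T(self):
        def bwd(out, a=self):
            Tensor._accum(a, out.grad.T)

        return self._make(self.data.T, (self,), bwd)

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(out, a=self, o=old):
            Tensor._accum(a, out.grad.reshape(o))

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(out, a=self, i=tuple(inv)):
            Tensor._accum(a, out.grad.transpose(i))

        return self._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(out, a=self, ix=idx):
            g = np.zeros_like(a.data)
            np.add.at(g, ix, out.grad)
            Tensor._accum(a, g)

        return self._make(self.data[idx], (self,), bwd)

    def take_rows(self, indices) -> "Tensor":
        """Row gather (embedding lookup): rows `indices` of a 2-D tensor."""
        idx = np.asarray(indices, dtype=np.intp)

        def bwd(out, a=self, ix=idx):
            g = np.zeros_like(a.data)
            np.add.at(g, ix, out.grad)
            Tensor._accum(a, g)

        return self._make(self.data[idx], (self,), bwd)

    # -- composite helpers -------------------------------------------------

    def softmax(self, axis=-1):
        shift = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def expand_dims(self, axis):
        shape = list(self.data.shape)
        shape.insert(axis if axis >= 0 else len(shape) + axis + 1, 1)
        return self.reshape(*shape)


class Parameter(Tensor):
    """Trainable tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters stay trainable under no_grad


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(out, ts=tensors, offs=offsets, ax=axis):
        for t, start, stop in zip(ts, offs[:-1], offs[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[ax] = slice(start, stop)
            Tensor._accum(t, out.grad[tuple(sl)])

    out = Tensor(data)
    if _GRAD_ENABLED[-1] and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = bwd
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(out, ts=tensors, ax=axis):
        for i, t in enumerate(ts):
            Tensor._accum(t, np.take(out.grad, i, axis=ax))

    out = Tensor(data)
    if _GRAD_ENABLED[-1] and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = bwd
    return out
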