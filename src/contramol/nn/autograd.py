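"""Minimal reverse-mode automatic differentiation over numpy arrays.

Deliberately small: only the operations needed by the transformer stacks in
this package. All arithmetic is float64. Graphs are built eagerly; calling
:meth:`Tensor.backward` accumulates gradients into every reachable tensor
with ``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "concatenate"]


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
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g, a=self, e=exponent):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1))

        return Tensor._from_op(self.data ** exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                if b.data.ndim == 2 and g.ndim > 2:
                    # batched input @ shared weight: one flat GEMM
                    gb = a.data.reshape(-1, a.data.shape[-1]).T @ g.reshape(
                        -1, g.shape[-1]
                    )
                    b._accum(gb)
                else:
                    gb = np.swapaxes(a.data, -1, -2) @ g
                    b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * (1.0 - o * o))

        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def gelu(self):
        """x * Phi(x), the exact Gaussian-CDF form."""
        phi = 0.5 * (1.0 + _erf(self.data / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * self.data ** 2) / np.sqrt(2.0 * np.pi)

        def backward(g, a=self, p=phi, d=pdf):
            if a.requires_grad:
                a._accum(g * (p + a.data * d))

        return Tensor._from_op(self.data * phi, (self,), backward)

    # -- reductions and shape ops ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            if ax is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
                return
            if not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(a.data.shape))

        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g, a=self, i=tuple(inv)):
            if a.requires_grad:
                a._accum(g.transpose(i))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    def take_rows(self, index: np.ndarray):
        """Gather rows (embedding lookup): ``self[index]`` with scatter-add backward."""
        index = np.asarray(index)

        def backward(g, a=self, idx=index):
            if a.requires_grad:
                acc = np.zeros_like(a.data)
                np.add.at(acc, idx, g)
                a._accum(acc)

        return Tensor._from_op(self.data[index], (self,), backward)

    def gather_last(self, index: np.ndarray):
        """Pick one entry along the last axis per leading position."""
        index = np.asarray(index)
        picked = np.take_along_axis(self.data, index[..., None], axis=-1)[..., 0]

        def backward(g, a=self, idx=index):
            if a.requires_grad:
                acc = np.zeros_like(a.data)
                np.put_along_axis(acc, idx[..., None], g[..., None], axis=-1)
                a._accum(acc)

        return Tensor._from_op(picked, (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, offs=offsets, ax=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._from_op(np.concatenate(datas, axis=axis), tensors, backward)
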