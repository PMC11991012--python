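"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ``numpy.ndarray`` together with a gradient
buffer and a closure that propagates incoming gradients to its parents.
``Tensor.backward()`` runs the usual topological-order sweep.  The operation
set is exactly what the segmentation network needs: broadcasting arithmetic,
matmul, exp/log/sqrt, relu/sigmoid, axis reductions (sum/mean/max), reshaping,
slicing, concatenation, and an ``unfold2d`` patch extractor from which
convolutions and 2x2 poolings are assembled.

Everything is computed in float64; at the problem sizes this package targets
(tiny encoders on 64x64 slices) precision is worth more than speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "unfold2d"]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were broadcast from size 1
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without a seed gradient requires "
                                 "a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative post-order DFS (graphs can be deep)
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.append(node)
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))
        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                      other.shape))
        out._backward = bw if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))

        def bw(g):
            self._accum(g * p * self.data ** (p - 1.0))
        out._backward = bw if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other
        # promote 1-D operands so the backward rule is uniformly 2-D
        sq_a, sq_b = a.ndim == 1, b.ndim == 1
        if sq_a:
            a = a.reshape(1, -1)
        if sq_b:
            b = b.reshape(-1, 1)
        out = Tensor(a.data @ b.data, _parents=(a, b))

        def bw(g):
            a._accum(g @ b.data.swapaxes(-1, -2))
            b._accum(a.data.swapaxes(-1, -2) @ g)
        out._backward = bw if out.requires_grad else None
        if sq_a and sq_b:
            return out.reshape(())
        if sq_a or sq_b:
            return out.reshape(-1)
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _parents=(self,))

        def bw(g):
            self._accum(g * val)
        out._backward = bw if out.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def bw(g):
            self._accum(g / self.data)
        out._backward = bw if out.requires_grad else None
        return out

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0.0
        out = Tensor(self.data * mask, _parents=(self,))

        def bw(g):
            self._accum(g * mask)
        out._backward = bw if out.requires_grad else None
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500.0, 500.0)))
        out = Tensor(val, _parents=(self,))

        def bw(g):
            self._accum(g * val * (1.0 - val))
        out._backward = bw if out.requires_grad else None
        return out

    def clip(self, lo: float | None = None, hi: float | None = None):
        """Clamp values; gradient is zero outside the kept band."""
        val = np.clip(self.data, lo, hi)
        keep = np.ones_like(self.data, dtype=bool)
        if lo is not None:
            keep &= self.data >= lo
        if hi is not None:
            keep &= self.data <= hi
        out = Tensor(val, _parents=(self,))

        def bw(g):
            self._accum(g * keep)
        out._backward = bw if out.requires_grad else None
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())
        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient routed to the first arg-max."""
        val = self.data.max(axis=axis, keepdims=True)
        hit = self.data == val
        # route ties to a single element for a well-defined subgradient
        first = np.cumsum(hit, axis=axis) == 1
        sel = hit & first
        out_val = val if keepdims else np.squeeze(val, axis=axis)
        out = Tensor(out_val, _parents=(self,))

        def bw(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape) * sel)
        out._backward = bw if out.requires_grad else None
        return out

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def bw(g):
            self._accum(g.reshape(self.shape))
        out._backward = bw if out.requires_grad else None
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))

        def bw(g):
            self._accum(g.transpose(inv))
        out._backward = bw if out.requires_grad else None
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._accum(buf)
        out._backward = bw if out.requires_grad else None
        return out


# ---------------------------------------------------------------- free funcs
def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)
    out._backward = bw if out.requires_grad else None
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))
    out._backward = bw if out.requires_grad else None
    return out


def unfold2d(x: Tensor, kernel: int, stride: int = 1,
             padding: int = 0) -> Tensor:
    """im2col: (C,H,W) -> (C*k*k, L) column matrix of sliding patches.

    Zero padding; backward scatter-adds into the padded buffer and crops.
    Convolution is then a single matmul with a (C_out, C*k*k) weight matrix;
    2x2 pooling reshapes the columns to (C, k*k, L) and reduces axis 1.
    """
    C, H, W = x.shape
    Hp, Wp = H + 2 * padding, W + 2 * padding
    Ho = (Hp - kernel) // stride + 1
    Wo = (Wp - kernel) // stride + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"kernel {kernel} does not fit input {x.shape}")

    # flat gather indices into the padded (C,Hp,Wp) buffer
    c = np.arange(C)[:, None, None, None, None, None]
    ki = np.arange(kernel)[None, :, None, None, None, None]
    kj = np.arange(kernel)[None, None, :, None, None, None]
    oi = (np.arange(Ho) * stride)[None, None, None, :, None, None]
    oj = (np.arange(Wo) * stride)[None, None, None, None, :, None]
    rows = ki + oi
    cols = kj + oj
    idx = (c * Hp * Wp + rows * Wp + cols).reshape(C * kernel * kernel, Ho * Wo)

    xpad = np.zeros((C, Hp, Wp))
    xpad[:, padding:padding + H, padding:padding + W] = x.data
    out = Tensor(xpad.reshape(-1)[idx], _parents=(x,))

    def bw(g):
        buf = np.zeros(C * Hp * Wp)
        np.add.at(buf, idx.ravel(), g.ravel())
        buf = buf.reshape(C, Hp, Wp)
        x._accum(buf[:, padding:padding + H, padding:padding + W])
    out._backward = bw if out.requires_grad else None
    return out


def unfold2d_out_hw(shape, kernel: int, stride: int = 1,
                    padding: int = 0) -> tuple[int, int]:
    """Output grid of :func:`unfold2d` for a (C,H,W) input shape."""
    _, H, W = shape
    return ((H + 2 * padding - kernel) // stride + 1,
            (W + 2 * padding - kernel) // stride + 1)
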