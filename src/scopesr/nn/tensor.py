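"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the restoration networks and the
MS-SSIM + L1 training loss need: broadcasting elementwise arithmetic,
reductions, 2-D convolution (stride 1, optional zero padding), average
pooling, nearest-neighbour upsampling, pixel shuffle, channel
concatenation and shape manipulation.  All computation is float64 and
fully deterministic, so seeded training runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req, _prev=tuple(parents) if req else ())
        if req:
            out._backward = backward
        return out

    # -- elementwise arithmetic -----------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):  # pragma: no cover - not needed
            raise TypeError("tensor exponents are not supported")
        e = float(exponent)
        out_data = self.data ** e

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * e * self.data ** (e - 1.0))

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(src_shape))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes: tuple[int, ...]):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    # -- spatial operators (NCHW) ----------------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               padding: int = 0):
        """2-D cross-correlation, stride 1.

        self: (N, C, H, W); weight: (O, C, kh, kw); bias: (O,).
        """
        x = self.data
        if padding:
            x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        n, c, h, w = x.shape
        o, c2, kh, kw = weight.shape
        if c != c2:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
        oh, ow = h - kh + 1, w - kw + 1
        if oh <= 0 or ow <= 0:
            raise ValueError("conv2d: kernel larger than (padded) input")
        s0, s1, s2, s3 = x.strides
        cols = np.lib.stride_tricks.as_strided(
            x, (n, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2, s3))
        cols = np.ascontiguousarray(cols).reshape(n, c * kh * kw, oh * ow)
        wmat = weight.data.reshape(o, c * kh * kw)
        out = np.matmul(wmat, cols).reshape(n, o, oh, ow)
        if bias is not None:
            out = out + bias.data.reshape(1, o, 1, 1)

        def backward(g):
            gmat = g.reshape(n, o, oh * ow)
            if weight.requires_grad:
                gw = np.einsum("nol,nkl->ok", gmat, cols).reshape(weight.shape)
                weight._accumulate(gw)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gcols = np.matmul(wmat.T, gmat).reshape(n, c, kh, kw, oh, ow)
                gx = np.zeros((n, c, h, w))
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i:i + oh, j:j + ow] += gcols[:, :, i, j]
                if padding:
                    gx = gx[:, :, padding:-padding, padding:-padding]
                self._accumulate(gx)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out, parents, backward)

    def crop2d(self, h2: int, w2: int):
        """Keep the top-left (h2, w2) spatial window."""
        n, c, h, w = self.shape

        def backward(g):
            if self.requires_grad:
                gx = np.zeros(self.shape)
                gx[:, :, :h2, :w2] = g
                self._accumulate(gx)

        return self._make(self.data[:, :, :h2, :w2], (self,), backward)

    def avg_pool2d(self, k: int):
        n, c, h, w = self.shape
        if h % k or w % k:
            raise ValueError(f"avg_pool2d: spatial dims {(h, w)} not divisible by {k}")
        out = self.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

        def backward(g):
            if self.requires_grad:
                gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
                self._accumulate(gx)

        return self._make(out, (self,), backward)

    def upsample_nearest(self, k: int):
        out = np.repeat(np.repeat(self.data, k, axis=2), k, axis=3)
        n, c, h, w = self.shape

        def backward(g):
            if self.requires_grad:
                gx = g.reshape(n, c, h, k, w, k).sum(axis=(3, 5))
                self._accumulate(gx)

        return self._make(out, (self,), backward)

    def pixel_shuffle(self, r: int):
        """(N, C*r*r, H, W) -> (N, C, H*r, W*r)."""
        n, cr2, h, w = self.shape
        if cr2 % (r * r):
            raise ValueError("pixel_shuffle: channels not divisible by r^2")
        c = cr2 // (r * r)
        out = (self.data.reshape(n, c, r, r, h, w)
               .transpose(0, 1, 4, 2, 5, 3)
               .reshape(n, c, h * r, w * r))

        def backward(g):
            if self.requires_grad:
                gx = (g.reshape(n, c, h, r, w, r)
                      .transpose(0, 1, 3, 5, 2, 4)
                      .reshape(n, cr2, h, w))
                self._accumulate(gx)

        return self._make(out, (self,), backward)

    # -- autodiff driver --------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
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
            for parent in node._prev:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_graph(self) -> np.ndarray:
        """Detach: return the raw array."""
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis` (used for U-Net skip connections)."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req, _prev=tuple(tensors) if req else ())

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    if req:
        out._backward = backward
    return out
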