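"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small define-by-run tape (in the spirit of micrograd, generalized to
ndarrays) providing exactly the primitives the hybrid backbone + vision
transformer needs: broadcast-aware arithmetic, batched matmul, strided 2-D
convolution (im2col), max pooling, reductions, elementwise nonlinearities,
shape ops and concatenation.  float64 throughout; gradients are accumulated
in topological order from a scalar loss.

Not a general framework: no higher-order gradients, no in-place ops, no
views that alias. Deliberately compact so it can be verified end-to-end by
finite differences in the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "erf", "relu", "gelu", "log_softmax", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to the operand's shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
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

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            if self.requires_grad:
                self._accum(-out.grad)

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self**-1.0

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward():
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1.0))

        out = self._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward():
            if self.requires_grad:
                g = out.grad @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ out.grad
                other._accum(_unbroadcast(g, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    # -- elementwise ----------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out_data)

        out = self._make(out_data, (self,), backward)
        return out

    def log(self):
        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out = self._make(np.log(self.data), (self,), backward)
        return out

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out_data**2))

        out = self._make(out_data, (self,), backward)
        return out

    def maximum(self, value: float):
        mask = self.data > value

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = self._make(np.maximum(self.data, value), (self,), backward)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else math.prod(
            self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(orig))

        out = self._make(self.data.reshape(shape), (self,), backward)
        return out

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def backward():
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        out = self._make(self.data.transpose(axes), (self,), backward)
        return out

    def __getitem__(self, key):
        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, key, out.grad)
                self._accum(g)

        out = self._make(self.data[key], (self,), backward)
        return out

    # -- spatial ops (NHWC) ---------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None", stride: int,
               pad: tuple[int, int, int, int]):
        """2-D convolution, NHWC input, (k, k, C_in, C_out) weight."""
        x = self.data
        t, b, l, r = pad
        xp = np.pad(x, ((0, 0), (t, b), (l, r), (0, 0)))
        kh, kw = weight.data.shape[:2]
        cols = sliding_window_view(xp, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
        # cols: (N, Ho, Wo, C_in, kh, kw)
        out_data = np.einsum("nhwcij,ijco->nhwo", cols, weight.data, optimize=True)
        if bias is not None:
            out_data = out_data + bias.data

        def backward():
            g = out.grad
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 1, 2)))
            if weight.requires_grad:
                weight._accum(
                    np.einsum("nhwcij,nhwo->ijco", cols, g, optimize=True)
                )
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                Ho, Wo = g.shape[1], g.shape[2]
                for i in range(kh):
                    for j in range(kw):
                        # (N, Ho, Wo, C_out) @ (C_out, C_in) scattered back
                        gxp[:, i : i + stride * Ho : stride,
                            j : j + stride * Wo : stride, :] += np.einsum(
                            "nhwo,co->nhwc", g, weight.data[i, j], optimize=True
                        )
                H, W = x.shape[1], x.shape[2]
                self._accum(gxp[:, t : t + H, l : l + W, :])

        parents = (self, weight) if bias is None else (self, weight, bias)
        out = self._make(out_data, parents, backward)
        return out

    def maxpool2d(self, window: tuple[int, int], stride: int,
                  pad: tuple[int, int, int, int]):
        """Max pooling, NHWC input; padded cells are -inf and never win."""
        x = self.data
        t, b, l, r = pad
        xp = np.pad(x, ((0, 0), (t, b), (l, r), (0, 0)), constant_values=-np.inf)
        kh, kw = window
        view = sliding_window_view(xp, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
        # view: (N, Ho, Wo, C, kh, kw)
        N, Ho, Wo, C = view.shape[:4]
        flat = view.reshape(N, Ho, Wo, C, kh * kw)
        arg = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

        def backward():
            if not self.requires_grad:
                return
            gxp = np.zeros_like(xp)
            ki, kj = np.unravel_index(arg, (kh, kw))
            n_i, h_i, w_i, c_i = np.indices(arg.shape)
            rows = h_i * stride + ki
            cols_ = w_i * stride + kj
            np.add.at(gxp, (n_i, rows, cols_, c_i), out.grad)
            H, W = x.shape[1], x.shape[2]
            self._accum(gxp[:, t : t + H, l : l + W, :])

        out = self._make(out_data, (self,), backward)
        return out

    # -- graph traversal --------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # free the tape
        for node in topo:
            node._backward = None
            node._parents = ()


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    out = Tensor(out_data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)

        def backward():
            for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out_data.ndim
                    sl[axis] = slice(start, stop)
                    t._accum(out.grad[tuple(sl)])

        out._backward = backward
    return out


def erf(x: Tensor) -> Tensor:
    from scipy.special import erf as _erf

    data = _erf(x.data)

    def backward():
        if x.requires_grad:
            x._accum(out.grad * (2.0 / np.sqrt(np.pi)) * np.exp(-x.data**2))

    out = x._make(data, (x,), backward)
    return out


def relu(x: Tensor) -> Tensor:
    return x.maximum(0.0)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    return x * 0.5 * (erf(x * (1.0 / np.sqrt(2.0))) + 1.0)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))  # detached max
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()
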