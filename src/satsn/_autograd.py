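"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records a closure graph; calling
:meth:`Tensor.backward` on a scalar loss propagates gradients to every leaf
with ``requires_grad``. The op set is exactly what the two-stream network
needs: broadcast arithmetic, matmul, reshape/transpose/indexing, relu /
sigmoid / softmax / log / exp, axis reductions (sum, mean, max), concat, and
a 3D convolution with spatial striding.

Gradient correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a gradient back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        data = np.asarray(data)
        # keep float32 pipelines in float32; promote everything else to float64
        self.data = data if data.dtype in (np.float32, np.float64) \
            else data.astype(np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- bookkeeping --------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g):
            self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * as_tensor(other) ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(self.data ** exponent, parents=(self,), backward=bw)

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            self._accum(g.reshape(self.shape))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bw)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bw)

    def index_select(self, axis: int, indices) -> "Tensor":
        indices = np.asarray(indices, dtype=int)

        def bw(g):
            acc = np.zeros_like(self.data)
            sl = [slice(None)] * self.ndim
            sl[axis] = indices
            np.add.at(acc, tuple(sl), g)
            self._accum(acc)

        return Tensor(np.take(self.data, indices, axis=axis),
                      parents=(self,), backward=bw)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out)
        # split gradient evenly across ties for determinism
        counts = mask.sum(axis=axis, keepdims=True)

        def bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * (gg / counts))

        return Tensor(out if keepdims else np.squeeze(out, axis=axis),
                      parents=(self,), backward=bw)

    # -- nonlinearities ------------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def sigmoid(self) -> "Tensor":
        out = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out * (1.0 - out))

        return Tensor(out, parents=(self,), backward=bw)

    def exp(self) -> "Tensor":
        out = np.exp(self.data)

        def bw(g):
            self._accum(g * out)

        return Tensor(out, parents=(self,), backward=bw)

    def log(self) -> "Tensor":
        def bw(g):
            self._accum(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            self._accum(out * (g - dot))

        return Tensor(out, parents=(self,), backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, o, s in zip(tensors, offsets, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(o, o + s)
            t._accum(g[tuple(sl)])

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bw)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: tuple[int, int, int] = (1, 1, 1)) -> Tensor:
    """3D convolution with 'same'-style zero padding (odd kernels).

    ``x``: (B, C_in, T, H, W); ``weight``: (C_out, C_in, kt, kh, kw);
    output: (B, C_out, T/st, H/sh, W/sw) with ceil-free shapes (dims assumed
    divisible by the stride).
    """
    B, Ci, T, H, W = x.shape
    Co, Ci2, kt, kh, kw = weight.shape
    if Ci != Ci2:
        raise ValueError(f"channel mismatch: input {Ci}, kernel {Ci2}")
    st, sh, sw = stride
    pt, ph, pw = kt // 2, kh // 2, kw // 2
    To, Ho, Wo = T // st, H // sh, W // sw

    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
    # im2col: one BLAS matmul instead of a loop over kernel offsets
    win = np.lib.stride_tricks.sliding_window_view(xp, (kt, kh, kw), axis=(2, 3, 4))
    win = win[:, :, ::st, ::sh, ::sw]                  # (B, C, To, Ho, Wo, kt, kh, kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        B * To * Ho * Wo, Ci * kt * kh * kw)
    wmat = weight.data.reshape(Co, -1)
    out = (cols @ wmat.T).reshape(B, To, Ho, Wo, Co).transpose(0, 4, 1, 2, 3)
    if bias is not None:
        out = out + bias.data[None, :, None, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, Co)
        weight._accum((g2.T @ cols).reshape(weight.shape))
        dcols = (g2 @ wmat).reshape(B, To, Ho, Wo, Ci, kt, kh, kw)
        dcols = dcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)  # (B, C, To, Ho, Wo, kt, kh, kw)
        gxp = np.zeros_like(xp)
        for dt in range(kt):
            for di in range(kh):
                for dj in range(kw):
                    gxp[:, :, dt : dt + (To - 1) * st + 1 : st,
                        di : di + (Ho - 1) * sh + 1 : sh,
                        dj : dj + (Wo - 1) * sw + 1 : sw] += dcols[..., dt, di, dj]
        x._accum(gxp[:, :, pt : pt + T, ph : ph + H, pw : pw + W])
        if bias is not None:
            bias._accum(g.sum(axis=(0, 2, 3, 4)))

    return Tensor(out, parents=parents, backward=bw)
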