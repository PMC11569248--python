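"""Minimal tape-based reverse-mode automatic differentiation on numpy.

Supports exactly the operations the model needs: broadcast arithmetic,
matmul, 1-D convolution and pooling, smooth activations, log-softmax,
reductions, slicing and concatenation.  Gradients flow to any leaf
marked ``requires_grad`` — parameters during training, and raw inputs
for gradient-attribution probing.

Everything is float64 and single-threaded numpy, so a fixed seed gives
bit-reproducible forward and backward passes.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(
        self,
        data,
        prev: tuple["Tensor", ...] = (),
        requires_grad: bool = False,
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._prev = prev
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in prev)

    # -- graph -------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, float)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.requires_grad:
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad += _unbroadcast(np.asarray(grad, float), self.data.shape)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor(self.data + other.data, (self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g):
            self._accum(-g)

        return Tensor(-self.data, (self,), backward=bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor(self.data * other.data, (self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        return Tensor(self.data / other.data, (self, other), backward=bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)

        def bw(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor(self.data @ other.data, (self, other), backward=bw)

    __matmul__ = matmul

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor(self.data.reshape(*shape), (self,), backward=bw)

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor(self.data.transpose(axes), (self,), backward=bw)

    def __getitem__(self, idx) -> "Tensor":
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor(self.data[idx], (self,), backward=bw)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise nonlinearities


def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.data)

    def bw(g):
        x._accum(g * (1.0 - out**2))

    return Tensor(out, (x,), backward=bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        x._accum(g * mask)

    return Tensor(x.data * mask, (x,), backward=bw)


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), numerically stable; strictly positive output."""
    out = np.logaddexp(0.0, x.data)

    def bw(g):
        x._accum(g * _sigmoid(x.data))

    return Tensor(out, (x,), backward=bw)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def exp(x: Tensor) -> Tensor:
    out = np.exp(x.data)

    def bw(g):
        x._accum(g * out)

    return Tensor(out, (x,), backward=bw)


def log(x: Tensor) -> Tensor:
    def bw(g):
        x._accum(g / x.data)

    return Tensor(np.log(x.data), (x,), backward=bw)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    p = np.exp(out)

    def bw(g):
        x._accum(g - p * g.sum(axis=axis, keepdims=True))

    return Tensor(out, (x,), backward=bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return exp(log_softmax(x, axis=axis))


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        tuple(tensors),
        backward=bw,
    )


# ---------------------------------------------------------------------------
# 1-D convolution / pooling (inputs are (N, C, L))


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded stride-1 cross-correlation; kernel width must be odd."""
    k = weight.data.shape[-1]
    assert k % 2 == 1, "kernel width must be odd for symmetric same-padding"
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (N,Cin,L,k)
    out = np.einsum("nclk,ock->nol", win, weight.data, optimize=True)
    out += bias.data[None, :, None]

    def bw(g):
        weight._accum(np.einsum("nclk,nol->ock", win, g, optimize=True))
        bias._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, :, j : j + g.shape[2]] += np.einsum(
                    "nol,oc->ncl", g, weight.data[:, :, j], optimize=True
                )
            x._accum(dxp[:, :, pad : pad + x.data.shape[2]])

    return Tensor(out, (x, weight, bias), backward=bw)


def avg_pool1d(x: Tensor, width: int) -> Tensor:
    n, c, l = x.data.shape
    assert l % width == 0, "length must divide pooling width"
    out = x.data.reshape(n, c, l // width, width).mean(axis=-1)

    def bw(g):
        x._accum(np.repeat(g, width, axis=-1) / width)

    return Tensor(out, (x,), backward=bw)


def max_pool1d(x: Tensor, width: int) -> Tensor:
    n, c, l = x.data.shape
    assert l % width == 0, "length must divide pooling width"
    blocks = x.data.reshape(n, c, l // width, width)
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        full = np.zeros_like(blocks)
        np.put_along_axis(full, idx[..., None], g[..., None], axis=-1)
        x._accum(full.reshape(n, c, l))

    return Tensor(out, (x,), backward=bw)
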