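"""Layers and the Adam optimiser for the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    __slots__ = ("trainable",)

    def __init__(self, data, trainable: bool = True):
        super().__init__(data, requires_grad=True)
        self.trainable = trainable


class Module:
    """Tiny module base: parameter discovery via attributes."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def trainable_parameters(self) -> list[Parameter]:
        return [p for p in self.parameters() if p.trainable]

    def freeze(self) -> None:
        for p in self.parameters():
            p.trainable = False

    def n_parameters(self, trainable_only: bool = False) -> int:
        ps = self.trainable_parameters() if trainable_only else self.parameters()
        return sum(p.data.size for p in ps)

    def state_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Parameter(_glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """Same-padded stride-1 1-D convolution on (N, C, L) input."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan = c_in * kernel
        self.w = Parameter(_glorot(rng, (c_out, c_in, kernel), fan, c_out * kernel))
        self.b = Parameter(np.zeros(c_out))
        self.kernel = kernel

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv1d(x, self.w, self.b)


class Adam:
    """Adaptive-moment optimiser over a fixed parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
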