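"""Parameterised layers over the autodiff engine.

Layers hold their parameters as ``Tensor`` objects with
``requires_grad=True`` and build the computation graph on ``__call__``.
Initialisation is He-normal from an explicit ``numpy.random.Generator``
so two builds from the same seed are bitwise identical.
"""

from __future__ import annotations

import numpy as np

from . import engine
from .engine import Tensor

DTYPE = np.float32


class Layer:
    def parameters(self) -> list[Tensor]:
        return []

    def zero_(self) -> None:
        """Set every parameter to zero (used by structural tests)."""
        for p in self.parameters():
            p.data[...] = 0


class Conv2d(Layer):
    """3x3 (or kxk) stride-1 convolution, valid or same padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 padding: str = "valid", dtype=DTYPE):
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        std = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.w = Tensor(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)).astype(dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        self.pad = (kernel - 1) // 2 if padding == "same" else 0

    def __call__(self, x) -> Tensor:
        return engine.conv2d(x, self.w, self.b, pad=self.pad)

    def parameters(self):
        return [self.w, self.b]


class ConvTranspose2d(Layer):
    """2x2 stride-2 learnable up-sampling."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, dtype=DTYPE):
        std = np.sqrt(2.0 / (in_ch * 4))
        self.w = Tensor(rng.normal(0.0, std, (in_ch, out_ch, 2, 2)).astype(dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)

    def __call__(self, x) -> Tensor:
        return engine.conv_transpose2x2(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5, dtype=DTYPE):
        self.gamma = Tensor(np.ones(ch, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, dtype=dtype), requires_grad=True)
        self.state = {"mean": np.zeros(ch, dtype=dtype), "var": np.ones(ch, dtype=dtype)}
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x, training: bool = False) -> Tensor:
        return engine.batchnorm2d(x, self.gamma, self.beta, self.state, training,
                                  momentum=self.momentum, eps=self.eps)

    def parameters(self):
        return [self.gamma, self.beta]


class Dense(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator, dtype=DTYPE):
        std = np.sqrt(2.0 / in_f)
        self.w = Tensor(rng.normal(0.0, std, (in_f, out_f)).astype(dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_f, dtype=dtype), requires_grad=True)

    def __call__(self, x) -> Tensor:
        return engine.dense(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]
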