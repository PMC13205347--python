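"""Neural-network building blocks and the Adam optimizer.

Thin module system over :mod:`nmrmatch.autodiff`: parameter registration,
train/eval mode, He/Glorot initialization, Linear / Conv2d / BatchNorm1d /
Dropout layers, and parameter counting helpers used by the ablation and
budget accounting code.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv2d

DTYPE = np.float32


class Parameter(Tensor):
    """A trainable tensor; ``frozen`` excludes it from optimization."""

    __slots__ = ("frozen",)

    def __init__(self, data, frozen: bool = False):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=not frozen)
        self.frozen = frozen


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    # -------------------------------------------------------------- traversal
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def trainable_parameters(self) -> list[Parameter]:
        return [p for p in self.parameters() if not p.frozen]

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def freeze(self) -> "Module":
        for p in self.parameters():
            p.frozen = True
            p.requires_grad = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # ------------------------------------------------------------ state dicts
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters(prefix)}
        for n, b in self._buffers.items():
            out[prefix + n] = b.copy()
        for n, m in self._modules.items():
            out.update(m.state_dict(prefix + n + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=p.data.dtype)
        self._load_buffers(state, "")

    def _load_buffers(self, state, prefix):
        for n in self._buffers:
            self._buffers[n] = np.array(state[prefix + n])
        for n, m in self._modules.items():
            m._load_buffers(state, prefix + n + ".")

    def count_parameters(self) -> dict[str, int]:
        """Exact parameter counts: total / trainable / frozen."""
        total = trainable = 0
        for p in self.parameters():
            total += p.data.size
            if not p.frozen:
                trainable += p.data.size
        return {"total": total, "trainable": trainable,
                "frozen": total - trainable}

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map ``x @ W + b`` with He (fan-in) initialization."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = math.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None
        self.in_features, self.out_features = in_features, out_features

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        scale = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(
            0.0, scale, (out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class BatchNorm1d(Module):
    """Batch normalization over axis 0; running statistics at evaluation."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self._buffers["running_mean"] = np.zeros(num_features, dtype=DTYPE)
        self._buffers["running_var"] = np.ones(num_features, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.ravel())
            n = x.shape[0]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * unbiased)
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
            xhat = (x - mu) * (1.0 / np.sqrt(var + self.eps))
        return xhat * self.weight + self.bias


class BatchNorm2d(BatchNorm1d):
    """Per-channel batch normalization for NCHW maps."""

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        flat = x.transpose(0, 2, 3, 1).reshape(N * H * W, C)
        out = super().forward(flat)
        return out.reshape(N, H, W, C).transpose(0, 3, 1, 2)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if not p.frozen]
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def bce_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy on probabilities (matches BCELoss semantics)."""
    y = np.asarray(target, dtype=pred.dtype).reshape(pred.shape)
    p = pred.clip_min(eps)
    q = (1.0 - pred).clip_min(eps)
    losses = -(Tensor(y) * p.log() + Tensor(1.0 - y) * q.log())
    return losses.mean()
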