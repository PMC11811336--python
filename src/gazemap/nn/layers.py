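"""Neural-network building blocks on top of the autograd engine.

Modules own their parameters as :class:`~gazemap.nn.autograd.Tensor` objects;
``parameters()`` walks submodules recursively.  Weight initialization is He
(fan-in) normal drawn from the rng handed to the constructor, so a model
built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "Linear",
    "GroupNorm",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "UpsampleNearest",
    "Sequential",
    "Identity",
    "SCSEBlock",
    "concat",
]


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        params.extend(v.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float32)

    def __call__(self, *args, **kwargs) -> Tensor:
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    scale = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape).astype(np.float32), requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.weight = _he_normal(rng, (cout, cin, k, k), fan_in=cin * k * k)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Stride-2 transposed convolution with a 2x2 kernel (block upsampling)."""

    def __init__(self, cin: int, cout: int, stride: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.weight = _he_normal(rng, (cin, cout, stride, stride), fan_in=cin)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias, stride=self.stride)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = _he_normal(rng, (cin, cout), fan_in=cin)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class GroupNorm(Module):
    """Group normalization (batch-size independent, so tiny batches train stably)."""

    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        while channels % groups:
            groups //= 2
        self.groups = max(groups, 1)
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, c // g, h, w)
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        var = ((xg - mu) * (xg - mu)).mean(axis=(2, 3, 4), keepdims=True)
        norm = (xg - mu) / (var + self.eps).sqrt()
        out = norm.reshape(n, c, h, w)
        return out * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2d(Module):
    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return x.maxpool2d(self.k)


class UpsampleNearest(Module):
    def __init__(self, scale: int = 2):
        self.scale = scale

    def forward(self, x: Tensor) -> Tensor:
        return x.upsample_nearest2d(self.scale)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


class SCSEBlock(Module):
    """Concurrent spatial and channel squeeze-and-excitation.

    Channel branch: global average pool -> bottleneck MLP -> sigmoid gate per
    channel.  Spatial branch: 1x1 conv -> sigmoid gate per pixel.  The two
    recalibrated maps are summed.
    """

    def __init__(self, channels: int, reduction: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)
        self.spatial = Conv2d(channels, 1, k=1, padding=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        pooled = x.mean(axis=(2, 3))  # (N, C)
        gate_c = self.fc2(self.fc1(pooled).relu()).sigmoid().reshape(n, c, 1, 1)
        gate_s = self.spatial(x).sigmoid()
        return x * gate_c + x * gate_s
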