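"""Encoder-decoder architectures for heatmap regression.

Three architectures share a residual encoder:

* ``ConvAE`` — ResNet-18-topology encoder (stage depths 2-2-2-2) feeding a
  plain decoder of 5 transposed-convolution stages, ReLU between stages and
  a final sigmoid.  No skip connections: the heatmap is reconstructed from
  the bottleneck alone.
* ``UNet`` — ResNet-34-topology encoder (3-4-6-3) with a U-Net decoder:
  nearest upsampling, skip concatenation, two 3x3 convs per stage, sigmoid
  1x1 head.
* ``AttentionUNet`` — the same with an scSE attention block after every
  decoder stage.

Widths are configurable; the full-scale widths start at 64 channels like the
original ResNets, while desk-scale tests use 8.  All spatial sizes must be
divisible by 32 (five downsamplings).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat
from .layers import (
    Conv2d,
    ConvTranspose2d,
    GroupNorm,
    Linear,
    MaxPool2d,
    Module,
    SCSEBlock,
    Sequential,
    UpsampleNearest,
)

__all__ = ["ResNetEncoder", "ConvAE", "UNet", "AttentionUNet", "ConvClassifier"]

RESNET18_DEPTHS = (2, 2, 2, 2)
RESNET34_DEPTHS = (3, 4, 6, 3)


class BasicBlock(Module):
    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng)
        self.norm1 = GroupNorm(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng=rng)
        self.norm2 = GroupNorm(cout)
        if stride != 1 or cin != cout:
            self.shortcut = Conv2d(cin, cout, 1, stride=stride, padding=0, bias=False, rng=rng)
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.norm1(self.conv1(x)).relu()
        out = self.norm2(self.conv2(out))
        skip = x if self.shortcut is None else self.shortcut(x)
        return (out + skip).relu()


class ResNetEncoder(Module):
    """Residual encoder producing features at scales 1/2, 1/4, 1/8, 1/16, 1/32."""

    def __init__(self, in_channels: int = 3, width: int = 64,
                 stage_depths: tuple[int, ...] = RESNET18_DEPTHS,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = width
        self.stem = Conv2d(in_channels, w, 3, stride=2, rng=rng)
        self.stem_norm = GroupNorm(w)
        self.pool = MaxPool2d(2)
        self.widths = [w, w, 2 * w, 4 * w, 8 * w]  # per feature scale
        stages = []
        cin = w
        for depth, cout, first_stride in zip(
            stage_depths, self.widths[1:], (1, 2, 2, 2)
        ):
            blocks = [BasicBlock(cin, cout, first_stride, rng)]
            blocks += [BasicBlock(cout, cout, 1, rng) for _ in range(depth - 1)]
            stages.append(Sequential(*blocks))
            cin = cout
        self.stages = stages

    def forward(self, x: Tensor) -> list[Tensor]:
        """Return the five feature maps, shallowest (1/2) first."""
        f1 = self.stem_norm(self.stem(x)).relu()            # 1/2
        feats = [f1]
        x = self.pool(f1)
        for i, stage in enumerate(self.stages):
            x = stage(x)
            feats.append(x)  # 1/4, 1/8, 1/16, 1/32
        return feats


class ConvAE(Module):
    def __init__(self, in_channels: int = 3, width: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder = ResNetEncoder(in_channels, width, RESNET18_DEPTHS, rng)
        w = self.encoder.widths
        # 5 deconvolution stages: 1/32 -> 1/1
        chans = [w[4], w[3], w[2], w[1], w[0], 1]
        self.deconvs = [ConvTranspose2d(a, b, rng=rng) for a, b in zip(chans, chans[1:])]

    def forward(self, x: Tensor) -> Tensor:
        z = self.encoder(x)[-1]
        for deconv in self.deconvs[:-1]:
            z = deconv(z).relu()
        return self.deconvs[-1](z).sigmoid()


class _DecoderStage(Module):
    def __init__(self, cin: int, cskip: int, cout: int, rng: np.random.Generator,
                 attention: bool):
        self.up = UpsampleNearest(2)
        self.conv1 = Conv2d(cin + cskip, cout, 3, rng=rng)
        self.norm1 = GroupNorm(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng=rng)
        self.norm2 = GroupNorm(cout)
        self.attention = SCSEBlock(cout, rng=rng) if attention else None

    def forward(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        x = self.up(x)
        if skip is not None:
            x = concat([x, skip], axis=1)
        x = self.norm1(self.conv1(x)).relu()
        x = self.norm2(self.conv2(x)).relu()
        if self.attention is not None:
            x = self.attention(x)
        return x


class UNet(Module):
    attention = False

    def __init__(self, in_channels: int = 3, width: int = 64, seed: int = 0,
                 stage_depths: tuple[int, ...] = RESNET34_DEPTHS):
        rng = np.random.default_rng(seed)
        self.encoder = ResNetEncoder(in_channels, width, stage_depths, rng)
        w = self.encoder.widths  # [w, w, 2w, 4w, 8w] at 1/2..1/32
        # decoder ladder mirrors the encoder but never tapers below 8
        # channels: tiny desk-scale widths otherwise starve the final stages
        dec = [max(4 * width, 8), max(2 * width, 8), max(width, 8),
               max(width // 2, 8), max(width // 4, 8)]
        skips = [w[3], w[2], w[1], w[0], 0]
        cin = w[4]
        self.stages = []
        for cskip, cout in zip(skips, dec):
            self.stages.append(_DecoderStage(cin, cskip, cout, rng, self.attention))
            cin = cout
        self.head = Conv2d(dec[-1], 1, 1, padding=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        feats = self.encoder(x)
        skips = [feats[3], feats[2], feats[1], feats[0], None]
        z = feats[4]
        for stage, skip in zip(self.stages, skips):
            z = stage(z, skip)
        return self.head(z).sigmoid()


class AttentionUNet(UNet):
    attention = True


class ConvClassifier(Module):
    """Small convolutional classifier: conv/pool stages, global pooling, linear head.

    Used for the diagnosis-fusion experiments; the architecture is identical
    across input modes except for the first-layer channel count.
    """

    def __init__(self, in_channels: int, n_classes: int = 4, width: int = 8,
                 depth: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.blocks = []
        cin = in_channels
        for d in range(depth):
            cout = width * (2**d)
            self.blocks.append(Conv2d(cin, cout, 3, rng=rng))
            self.blocks.append(GroupNorm(cout))
            cin = cout
        self.pool = MaxPool2d(2)
        self.head = Linear(cin, n_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        for i in range(0, len(self.blocks), 2):
            x = self.blocks[i + 1](self.blocks[i](x)).relu()
            x = self.pool(x)
        return self.head(x.mean(axis=(2, 3)))
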