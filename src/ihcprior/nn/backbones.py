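"""Backbone feature extractors.

Both backbones honor the same contract: a ``(N, S, S, in_channels)`` patch
(channels-last) maps to a ``(N, 16, 16, out_channels)`` feature grid.

* ``small_cnn`` — a few stride-2 conv/BN/ReLU stages; trains in seconds on a
  CPU and is the default for the synthetic desk-scale experiments.
* ``resnet18`` — the standard 18-layer residual network (BasicBlock layout
  [2, 2, 2, 2]), with the last stage at stride 1 so a 256 px patch yields a
  16x16 grid.  Provided for parameter accounting and full-scale runs.
"""

from __future__ import annotations

import numpy as np

from .core import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool2d,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
)

__all__ = ["SmallCNN", "BasicBlock", "ResNet18", "build_backbone", "BACKBONE_GRID"]

#: spatial grid every backbone must produce (the CAM resolution)
BACKBONE_GRID = 16


class SmallCNN(Module):
    """Stem conv + log2(input_size/16) stride-2 stages + a head conv."""

    def __init__(
        self,
        in_channels: int = 3,
        out_channels: int = 64,
        input_size: int = 64,
        width: int = 16,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        n_down = int(np.log2(input_size / BACKBONE_GRID))
        if 2**n_down * BACKBONE_GRID != input_size:
            raise ValueError(
                f"input_size {input_size} must be 16 * 2**k for some k >= 0"
            )
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.input_size = input_size
        layers: list[Module] = [
            Conv2d(in_channels, width, 3, bias=False, rng=rng),
            BatchNorm2d(width),
            ReLU(),
        ]
        ch = width
        for _ in range(n_down):
            nxt = min(ch * 2, out_channels)
            layers += [
                Conv2d(ch, nxt, 3, stride=2, bias=False, rng=rng),
                BatchNorm2d(nxt),
                ReLU(),
            ]
            ch = nxt
        layers += [
            Conv2d(ch, out_channels, 3, bias=False, rng=rng),
            BatchNorm2d(out_channels),
            ReLU(),
        ]
        self.body = Sequential(*layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.body.forward(x, train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.body.backward(grad)


class BasicBlock(Module):
    """Two 3x3 conv/BN pairs with an identity (or 1x1-projected) shortcut."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride=stride, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, 3, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_channels)
        self.relu2 = ReLU()
        if stride != 1 or in_channels != out_channels:
            self.down_conv = Conv2d(
                in_channels, out_channels, 1, stride=stride, padding=0, bias=False, rng=rng
            )
            self.down_bn = BatchNorm2d(out_channels)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self.bn1.forward(self.conv1.forward(x, train), train)
        out = self.relu1.forward(out, train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        if self.down_conv is not None:
            shortcut = self.down_bn.forward(self.down_conv.forward(x, train), train)
        else:
            shortcut = x
        return self.relu2.forward(out + shortcut, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu2.backward(grad)
        d_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(grad))
        )))
        if self.down_conv is not None:
            d_short = self.down_conv.backward(self.down_bn.backward(grad))
        else:
            d_short = grad
        return d_main + d_short


class ResNet18(Module):
    """ResNet-18 feature extractor (no classification head).

    11,176,512 trainable parameters with a 3-channel stem; the last stage
    runs at stride 1 so the output grid is 16x16 for 256x256 input.
    """

    def __init__(
        self,
        in_channels: int = 3,
        input_size: int = 256,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = 512
        self.input_size = input_size
        self.stem = Sequential(
            Conv2d(in_channels, 64, 7, stride=2, padding=3, bias=False, rng=rng),
            BatchNorm2d(64),
            ReLU(),
            MaxPool2d(3, stride=2, padding=1),
        )
        stages = []
        channels = [(64, 64, 1), (64, 128, 2), (128, 256, 2), (256, 512, 1)]
        for cin, cout, stride in channels:
            stages.append(BasicBlock(cin, cout, stride=stride, rng=rng))
            stages.append(BasicBlock(cout, cout, stride=1, rng=rng))
        self.stages = stages

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = self.stem.forward(x, train=train)
        for block in self.stages:
            x = block.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for block in reversed(self.stages):
            grad = block.backward(grad)
        return self.stem.backward(grad)


def build_backbone(
    name: str,
    in_channels: int,
    input_size: int,
    out_channels: int = 64,
    rng: np.random.Generator | None = None,
) -> Module:
    """Instantiate a named backbone honoring the 16x16-grid contract."""
    if name == "small_cnn":
        return SmallCNN(
            in_channels=in_channels,
            out_channels=out_channels,
            input_size=input_size,
            rng=rng,
        )
    if name == "resnet18":
        return ResNet18(in_channels=in_channels, input_size=input_size, rng=rng)
    raise ValueError(f"unknown backbone {name!r}; choose 'small_cnn' or 'resnet18'")
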