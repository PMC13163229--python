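"""Backbone feature extractors.

``ResNet50Backbone`` reproduces the standard ImageNet ResNet50 topology with
the classification top removed: (N, 224, 224, 3) → (N, 7, 7, 2048) and
exactly 23,587,712 parameters (53,120 of them batch-norm moving statistics).
Pretrained weights can be loaded from an ``.npz`` file keyed by parameter
name; by default the backbone is randomly initialized, which leaves every
parameter count unchanged.

``SmallBackbone`` is a three-block conv/pool stack of the same interface for
CPU-scale smoke training on phantom data.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .layers import BatchNorm, Conv2D, Layer, MaxPool2D


class _Bottleneck(Layer):
    """1×1 → 3×3 → 1×1 residual bottleneck; conv shortcut on stage entry."""

    def __init__(self, name, in_channels, filters, stride, conv_shortcut, rng):
        super().__init__(name)
        f1, f2, f3 = filters
        self.conv_shortcut = conv_shortcut
        self.c1 = Conv2D(f"{name}/conv1", in_channels, f1, 1, rng, stride=stride, padding=0)
        self.bn1 = BatchNorm(f"{name}/bn1", f1)
        self.c2 = Conv2D(f"{name}/conv2", f1, f2, 3, rng, padding=1)
        self.bn2 = BatchNorm(f"{name}/bn2", f2)
        self.c3 = Conv2D(f"{name}/conv3", f2, f3, 1, rng, padding=0)
        self.bn3 = BatchNorm(f"{name}/bn3", f3)
        self.sublayers = [self.c1, self.bn1, self.c2, self.bn2, self.c3, self.bn3]
        if conv_shortcut:
            self.cs = Conv2D(f"{name}/conv_shortcut", in_channels, f3, 1, rng, stride=stride, padding=0)
            self.bns = BatchNorm(f"{name}/bn_shortcut", f3)
            self.sublayers += [self.cs, self.bns]
        self.out_channels = f3

    def __call__(self, x, training=False):
        shortcut = self.bns(self.cs(x), training) if self.conv_shortcut else x
        y = T.relu(self.bn1(self.c1(x), training))
        y = T.relu(self.bn2(self.c2(y), training))
        y = self.bn3(self.c3(y), training)
        return T.relu(y + shortcut)


class ResNet50Backbone(Layer):
    def __init__(self, name="resnet50", rng=None, weights: str | None = None):
        super().__init__(name)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.conv1 = Conv2D(f"{name}/conv1", 3, 64, 7, rng, stride=2, padding=3)
        self.bn1 = BatchNorm(f"{name}/bn1", 64)
        self.pool = MaxPool2D(f"{name}/pool1", 3, 2, padding=1)
        self.sublayers = [self.conv1, self.bn1, self.pool]
        self.blocks: list[_Bottleneck] = []
        in_ch = 64
        for stage, (width, nblocks) in enumerate(((64, 3), (128, 4), (256, 6), (512, 3)), start=2):
            for b in range(nblocks):
                stride = 2 if (b == 0 and stage > 2) else 1
                block = _Bottleneck(
                    f"{name}/stage{stage}_block{b + 1}",
                    in_ch,
                    (width, width, width * 4),
                    stride,
                    conv_shortcut=(b == 0),
                    rng=rng,
                )
                self.blocks.append(block)
                self.sublayers.append(block)
                in_ch = width * 4
        self.out_channels = in_ch
        if weights is not None:
            self.load_weights(weights)

    def load_weights(self, path: str) -> None:
        """Load weights from an ``.npz`` keyed by parameter name; never falls
        back to random initialization silently."""
        try:
            archive = np.load(path)
        except OSError as exc:
            raise FileNotFoundError(f"backbone weight file unavailable: {path}") from exc
        self.set_weights({k: archive[k] for k in archive.files})

    def __call__(self, x, training=False):
        y = T.relu(self.bn1(self.conv1(x), training))
        y = self.pool(y)
        for block in self.blocks:
            y = block(y, training)
        return y


class SmallBackbone(Layer):
    """Reduced conv/BN/pool stack: (N, s, s, 3) → (N, s/8, s/8, width·2)."""

    def __init__(self, name="small_backbone", width=8, rng=None):
        super().__init__(name)
        rng = rng if rng is not None else np.random.default_rng(0)
        chans = [width, width, 2 * width]
        self.stages = []
        in_ch = 3
        for i, ch in enumerate(chans, start=1):
            conv = Conv2D(f"{name}/conv{i}", in_ch, ch, 3, rng, padding="same", activation=None)
            bn = BatchNorm(f"{name}/bn{i}", ch)
            pool = MaxPool2D(f"{name}/pool{i}", 2, 2)
            self.stages.append((conv, bn, pool))
            self.sublayers += [conv, bn, pool]
            in_ch = ch
        self.out_channels = in_ch

    def __call__(self, x, training=False):
        y = x
        for conv, bn, pool in self.stages:
            y = pool(T.relu(bn(conv(y), training)))
        return y
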