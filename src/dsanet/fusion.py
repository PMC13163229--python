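"""Cross-Stream Fusion and Adaptive Feature Fusion.

Cross-Stream Fusion merges the local (S1) and global (S2) stream outputs as

    F_fused = BatchNorm( S1 + S2 + S1 ⊙ S2 )

keeping each stream's own contribution plus their elementwise interaction,
then normalizing to stabilize the fused distribution.

Adaptive Feature Fusion (AFF) then refines the fused map with a learned
soft gate:

    F_out = ReLU(conv_T(F)) ⊙ sigmoid(conv_G(F))

where both convolutions are 1×1, C→C with bias (2·(C²+C) parameters; 131,584
at C=256). The sigmoid gate acts as per-element soft switches on the
ReLU-transformed features, so outputs are nonnegative and never exceed the
transformed magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tensor as T
from .layers import BatchNorm, Layer, glorot_uniform, he_normal
from .tensor import Tensor

__all__ = [
    "AffParams",
    "AdaptiveFeatureFusion",
    "cross_stream_fuse",
    "adaptive_feature_fusion",
    "aff_parameter_count",
]


def aff_parameter_count(channels: int) -> int:
    """Learnable parameters of the AFF block: two biased 1×1 convs C→C."""
    if channels < 1:
        raise ValueError("channels must be >= 1")
    return 2 * (channels * channels + channels)


class AdaptiveFeatureFusion(Layer):
    """AFF block as a network layer (NHWC batched input)."""

    def __init__(self, name: str, channels: int, rng=None):
        super().__init__(name)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.transform_w = self.add_param("transform_kernel", he_normal(rng, (1, 1, channels, channels), channels))
        self.transform_b = self.add_param("transform_bias", np.zeros(channels))
        self.gate_w = self.add_param("gate_kernel", glorot_uniform(rng, (1, 1, channels, channels), channels, channels))
        self.gate_b = self.add_param("gate_bias", np.zeros(channels))

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        if x.data.shape[3] != self.channels:
            raise ValueError(f"{self.name}: expected {self.channels} channels, got {x.data.shape[3]}")
        t = T.relu(T.conv2d(x, self.transform_w.tensor, self.transform_b.tensor, padding=0))
        g = T.sigmoid(T.conv2d(x, self.gate_w.tensor, self.gate_b.tensor, padding=0))
        return t * g


@dataclass
class AffParams:
    """Explicit AFF weights: (kernel, bias) pairs for transform and gate convs."""

    channels: int
    transform_conv: tuple = None
    gate_conv: tuple = None
    seed: int = 0

    def __post_init__(self):
        layer = AdaptiveFeatureFusion("aff", self.channels, rng=np.random.default_rng(self.seed))
        if self.transform_conv is not None:
            w, b = self.transform_conv
            layer.transform_w.data = np.asarray(w, dtype=float).reshape(layer.transform_w.data.shape)
            layer.transform_b.data = np.asarray(b, dtype=float)
        if self.gate_conv is not None:
            w, b = self.gate_conv
            layer.gate_w.data = np.asarray(w, dtype=float).reshape(layer.gate_w.data.shape)
            layer.gate_b.data = np.asarray(b, dtype=float)
        self._layer = layer

    def parameter_count(self) -> int:
        return self._layer.param_count()


def cross_stream_fuse(s1: np.ndarray, s2: np.ndarray, bn_params: BatchNorm | None = None) -> np.ndarray:
    """BatchNorm(S1 + S2 + S1⊙S2) on single (H, W, C) maps.

    With ``bn_params=None`` an identity normalization (scale 1, shift 0, zero
    mean, unit variance statistics) is used, returning the raw three-term sum.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError(f"stream shape mismatch: {s1.shape} vs {s2.shape}")
    fused = s1 + s2 + s1 * s2
    if bn_params is None:
        return fused
    return bn_params(Tensor(fused[None]), training=False).data[0]


def adaptive_feature_fusion(f: np.ndarray, params: AffParams) -> np.ndarray:
    """ReLU(conv_T(F)) ⊙ sigmoid(conv_G(F)) on a single (H, W, C) map."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 3:
        raise ValueError(f"feature map must be rank-3, got shape {f.shape}")
    if f.shape[2] != params.channels:
        raise ValueError(f"channel mismatch: map has {f.shape[2]}, params expect {params.channels}")
    return params._layer(Tensor(f[None])).data[0]
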