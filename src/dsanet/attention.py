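"""Channel-Spatial Attention (CSA).

The block refines a feature map F (H, W, C) with two multiplicative
attention maps computed from F itself and applied jointly:

    F_out = F  ⊙  A_channel  ⊙  A_spatial

* ``A_channel`` (length C, values in (0,1)): a shared two-layer MLP with a
  C/r bottleneck is applied to both the spatially global-average-pooled and
  global-max-pooled channel statistics; the two results are summed and passed
  through a sigmoid. Average pooling favors uniformly activated channels,
  max pooling favors channels with salient peaks.
* ``A_spatial`` (H, W, 1): channel-wise mean and max maps are concatenated
  and convolved with a single k×k filter, then passed through a sigmoid.

With C=256, reduction r=8 and spatial kernel k=7 (biases everywhere) the
block holds exactly 16,771 learnable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tensor as T
from .layers import Layer, glorot_uniform, he_normal
from .tensor import Tensor

__all__ = [
    "CsaParams",
    "ChannelSpatialAttention",
    "channel_attention",
    "spatial_attention",
    "apply_csa",
    "csa_parameter_count",
]


def csa_parameter_count(channels: int, reduction: int, spatial_kernel: int) -> int:
    """Closed-form learnable-parameter count of one CSA block.

    Channel MLP: C·(C/r) + C/r + (C/r)·C + C ; spatial conv: 2·k² + 1.
    """
    if channels % reduction != 0:
        raise ValueError(f"channels ({channels}) must be divisible by reduction ({reduction})")
    if spatial_kernel % 2 != 1:
        raise ValueError(f"spatial kernel must be odd, got {spatial_kernel}")
    hidden = channels // reduction
    return channels * hidden + hidden + hidden * channels + channels + 2 * spatial_kernel**2 + 1


class ChannelSpatialAttention(Layer):
    """CSA block as a network layer (NHWC batched input)."""

    def __init__(self, name: str, channels: int, reduction: int = 8, spatial_kernel: int = 7, rng=None):
        super().__init__(name)
        csa_parameter_count(channels, reduction, spatial_kernel)  # validates
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.reduction = reduction
        self.spatial_kernel = spatial_kernel
        hidden = channels // reduction
        self.w1 = self.add_param("mlp_w1", he_normal(rng, (channels, hidden), channels))
        self.b1 = self.add_param("mlp_b1", np.zeros(hidden))
        self.w2 = self.add_param("mlp_w2", glorot_uniform(rng, (hidden, channels), hidden, channels))
        self.b2 = self.add_param("mlp_b2", np.zeros(channels))
        k = spatial_kernel
        self.conv_w = self.add_param("spatial_kernel", glorot_uniform(rng, (k, k, 2, 1), k * k * 2, 1))
        self.conv_b = self.add_param("spatial_bias", np.zeros(1))

    # -- pieces -----------------------------------------------------------
    def _mlp(self, v: Tensor) -> Tensor:
        h = T.relu(T.matmul(v, self.w1.tensor) + self.b1.tensor)
        return T.matmul(h, self.w2.tensor) + self.b2.tensor

    def channel_attention(self, x: Tensor) -> Tensor:
        """Sigmoid of summed shared-MLP responses to GAP and GMP statistics; (N, C)."""
        avg = T.reduce_mean(x, axis=(1, 2))
        mx = T.reduce_max(T.reduce_max(x, axis=1), axis=1)
        return T.sigmoid(self._mlp(avg) + self._mlp(mx))

    def spatial_attention(self, x: Tensor) -> Tensor:
        """Sigmoid of a k×k convolution over the channel mean/max maps; (N, H, W, 1)."""
        avg = T.reduce_mean(x, axis=3, keepdims=True)
        mx = T.reduce_max(x, axis=3, keepdims=True)
        pooled = T.concat([avg, mx], axis=3)
        return T.sigmoid(T.conv2d(pooled, self.conv_w.tensor, self.conv_b.tensor, padding="same"))

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        if x.data.shape[3] != self.channels:
            raise ValueError(f"{self.name}: expected {self.channels} channels, got {x.data.shape[3]}")
        n = x.data.shape[0]
        ca = T.reshape(self.channel_attention(x), (n, 1, 1, self.channels))
        sa = self.spatial_attention(x)
        return x * ca * sa


# -- functional interface on single (H, W, C) feature maps -----------------


@dataclass
class CsaParams:
    """Explicit CSA weights for a single feature map.

    ``mlp_weights`` is (w1, b1, w2, b2) with the bottleneck C/r; the spatial
    convolution kernel has shape (k, k, 2, 1) over the two pooled maps.
    """

    in_channels: int
    reduction_ratio: int = 8
    spatial_kernel: int = 7
    mlp_weights: tuple = field(default=None)
    spatial_conv_weights: tuple = field(default=None)
    seed: int = 0

    def __post_init__(self):
        csa_parameter_count(self.in_channels, self.reduction_ratio, self.spatial_kernel)
        layer = ChannelSpatialAttention(
            "csa",
            self.in_channels,
            self.reduction_ratio,
            self.spatial_kernel,
            rng=np.random.default_rng(self.seed),
        )
        if self.mlp_weights is not None:
            w1, b1, w2, b2 = (np.asarray(a, dtype=float) for a in self.mlp_weights)
            layer.w1.data, layer.b1.data, layer.w2.data, layer.b2.data = w1, b1, w2, b2
        if self.spatial_conv_weights is not None:
            w, b = self.spatial_conv_weights
            layer.conv_w.data = np.asarray(w, dtype=float).reshape(layer.conv_w.data.shape)
            layer.conv_b.data = np.atleast_1d(np.asarray(b, dtype=float))
        self._layer = layer

    @classmethod
    def zeros(cls, in_channels: int, reduction_ratio: int = 8, spatial_kernel: int = 7) -> "CsaParams":
        """All-zero weights: every attention value becomes sigmoid(0) = 0.5."""
        hidden = in_channels // reduction_ratio
        k = spatial_kernel
        return cls(
            in_channels,
            reduction_ratio,
            spatial_kernel,
            mlp_weights=(
                np.zeros((in_channels, hidden)),
                np.zeros(hidden),
                np.zeros((hidden, in_channels)),
                np.zeros(in_channels),
            ),
            spatial_conv_weights=(np.zeros((k, k, 2, 1)), np.zeros(1)),
        )

    def parameter_count(self) -> int:
        return self._layer.param_count()


def _check_feature_map(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 3:
        raise ValueError(f"feature map must be rank-3 (H, W, C), got shape {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ValueError("feature map contains non-finite values")
    return f


def channel_attention(f: np.ndarray, params: CsaParams) -> np.ndarray:
    """Channel attention weights (length C, all strictly in (0,1))."""
    f = _check_feature_map(f)
    if f.shape[2] != params.in_channels:
        raise ValueError(f"channel mismatch: map has {f.shape[2]}, params expect {params.in_channels}")
    return params._layer.channel_attention(Tensor(f[None])).data[0]


def spatial_attention(f: np.ndarray, params: CsaParams) -> np.ndarray:
    """Spatial attention map of shape (H, W, 1), values strictly in (0,1)."""
    f = _check_feature_map(f)
    k, h, w = params.spatial_kernel, f.shape[0], f.shape[1]
    if k > 2 * min(h, w) + 1:
        import warnings

        warnings.warn(
            f"spatial kernel {k} exceeds 2*min(H,W)+1 = {2 * min(h, w) + 1}; computed with same padding anyway",
            stacklevel=2,
        )
    return params._layer.spatial_attention(Tensor(f[None])).data[0]


def apply_csa(f: np.ndarray, params: CsaParams) -> np.ndarray:
    """F ⊙ A_channel ⊙ A_spatial; same shape as F, never larger in magnitude."""
    f = _check_feature_map(f)
    ca = channel_attention(f, params)
    sa = spatial_attention(f, params)
    return f * ca[None, None, :] * sa
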