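"""Assembly of the dual-stream attention network.

Topology: ResNet50 backbone → two parallel streams over its (7, 7, 2048)
features — S1 (local): 3×3 conv to 256 channels + CSA; S2 (global): 5×5 conv
to 256 channels, 3×3 depthwise conv, + CSA — then cross-stream fusion
(S1 + S2 + S1⊙S2, batch-normalized), adaptive feature fusion, a GAP‖GMP
pooled descriptor of length 512, and a Dense(512)→Dropout(0.4)→Dense(256)→
Dropout(0.3)→Dense(1, sigmoid) head. The canonical configuration carries
41,976,967 parameters, 41,923,335 of them trainable (the rest are batch-norm
moving statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tensor as T
from .attention import ChannelSpatialAttention
from .backbone import ResNet50Backbone, SmallBackbone
from .fusion import AdaptiveFeatureFusion
from .layers import BatchNorm, Conv2D, Dense, DepthwiseConv2D, Dropout, Layer, global_average_pool, global_max_pool
from .tensor import Tensor

__all__ = ["ModelConfig", "DualStreamModel", "build_backbone", "build_model", "count_parameters", "predict", "classify", "summary"]


@dataclass
class ModelConfig:
    input_size: int = 224
    stream_width: int = 256
    s1_kernel: int = 3
    s2_kernel: int = 5
    depthwise_kernel: int = 3
    csa_reduction: int = 8
    csa_spatial_kernel: int = 7
    dense_units: tuple[int, int] = (512, 256)
    dropout_rates: tuple[float, float] = (0.4, 0.3)
    backbone: str = "resnet50"
    small_backbone_width: int = 8

    def __post_init__(self):
        for k in (self.s1_kernel, self.s2_kernel, self.depthwise_kernel, self.csa_spatial_kernel):
            if k % 2 != 1:
                raise ValueError(f"kernel sizes must be odd, got {k}")
        for r in self.dropout_rates:
            if not 0.0 <= r < 1.0:
                raise ValueError(f"dropout rates must be in [0,1), got {r}")
        if self.backbone not in ("resnet50", "small"):
            raise ValueError(f"unknown backbone {self.backbone!r}")

    @classmethod
    def smoke(cls, input_size: int = 32) -> "ModelConfig":
        """Reduced-width configuration for CPU-scale training and tests."""
        return cls(
            input_size=input_size,
            stream_width=8,
            csa_reduction=4,
            csa_spatial_kernel=3,
            dense_units=(16, 8),
            dropout_rates=(0.2, 0.2),
            backbone="small",
            small_backbone_width=8,
        )

    @property
    def feature_size(self) -> int:
        down = 32 if self.backbone == "resnet50" else 8
        if self.input_size % down != 0:
            raise ValueError(f"input_size {self.input_size} not divisible by backbone downsampling {down}")
        return self.input_size // down


def build_backbone(config: ModelConfig, seed: int = 0, weights: str | None = None) -> Layer:
    """Feature extractor per the configuration.

    ``weights`` is an optional ``.npz`` path (pretrained weights); when
    omitted the backbone is randomly initialized (parameter counts are
    weight-independent). A requested-but-unavailable file raises.
    """
    rng = np.random.default_rng(seed)
    if config.backbone == "resnet50":
        return ResNet50Backbone(rng=rng, weights=weights)
    if weights is not None:
        bb = SmallBackbone(width=config.small_backbone_width, rng=rng)
        bb.load_weights(weights)
        return bb
    return SmallBackbone(width=config.small_backbone_width, rng=rng)


class DualStreamModel(Layer):
    def __init__(self, config: ModelConfig, seed: int = 0, weights: str | None = None):
        super().__init__("dual_stream_model")
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2**16]))
        self.dropout_rng = np.random.default_rng(np.random.SeedSequence([seed, 2**16 + 1]))
        self.backbone = build_backbone(config, seed=seed, weights=weights)
        cb = self.backbone.out_channels
        w = config.stream_width
        self.conv_s1 = Conv2D("conv2d_s1", cb, w, config.s1_kernel, rng, padding="same", activation="relu")
        self.csa1 = ChannelSpatialAttention("channel_spatial_attention_1", w, config.csa_reduction, config.csa_spatial_kernel, rng)
        self.conv_s2 = Conv2D("conv2d_s2", cb, w, config.s2_kernel, rng, padding="same", activation="relu")
        self.depthwise = DepthwiseConv2D("depthwise_conv2d", w, config.depthwise_kernel, rng, activation="relu")
        self.csa2 = ChannelSpatialAttention("channel_spatial_attention_2", w, config.csa_reduction, config.csa_spatial_kernel, rng)
        self.fusion_bn = BatchNorm("batch_normalization", w)
        self.aff = AdaptiveFeatureFusion("adaptive_feature_fusion", w, rng)
        d1, d2 = config.dense_units
        self.dense1 = Dense("dense_1", 2 * w, d1, rng, activation="relu")
        self.drop1 = Dropout("dropout_1", config.dropout_rates[0], self.dropout_rng)
        self.dense2 = Dense("dense_2", d1, d2, rng, activation="relu")
        self.drop2 = Dropout("dropout_2", config.dropout_rates[1], self.dropout_rng)
        self.dense_out = Dense("dense_output", d2, 1, rng, activation=None)
        self.sublayers = [
            self.backbone,
            self.conv_s1,
            self.csa1,
            self.conv_s2,
            self.depthwise,
            self.csa2,
            self.fusion_bn,
            self.aff,
            self.dense1,
            self.drop1,
            self.dense2,
            self.drop2,
            self.dense_out,
        ]
        self._validate_shapes()

    # -- shape accounting --------------------------------------------------
    def expected_shapes(self) -> dict[str, tuple]:
        c = self.config
        f = c.feature_size
        w = c.stream_width
        spatial = (f, f, w)
        return {
            "input_layer": (c.input_size, c.input_size, 3),
            self.backbone.name: (f, f, self.backbone.out_channels),
            "conv2d_s1": spatial,
            "channel_spatial_attention_1": spatial,
            "conv2d_s2": spatial,
            "depthwise_conv2d": spatial,
            "channel_spatial_attention_2": spatial,
            "multiply": spatial,
            "add": spatial,
            "batch_normalization": spatial,
            "adaptive_feature_fusion": spatial,
            "global_average_pooling2d": (w,),
            "global_max_pooling2d": (w,),
            "concatenate": (2 * w,),
            "dense_1": (c.dense_units[0],),
            "dropout_1": (c.dense_units[0],),
            "dense_2": (c.dense_units[1],),
            "dropout_2": (c.dense_units[1],),
            "dense_output": (1,),
        }

    def _validate_shapes(self) -> None:
        c = self.config
        f = c.feature_size  # raises if inconsistent
        if c.csa_spatial_kernel > 2 * f + 1:
            import warnings

            warnings.warn(
                f"CSA spatial kernel {c.csa_spatial_kernel} is large for the {f}x{f} feature grid",
                stacklevel=2,
            )

    # -- forward -----------------------------------------------------------
    def forward(self, x: Tensor, training: bool = False, capture: dict | None = None) -> Tensor:
        feats = self.backbone(x, training)
        s1 = self.csa1(self.conv_s1(feats, training), training)
        s2 = self.csa2(self.depthwise(self.conv_s2(feats, training), training), training)
        fused = self.fusion_bn(s1 + s2 + s1 * s2, training)
        refined = self.aff(fused, training)
        if capture is not None:
            capture[self.backbone.name] = feats
            capture["channel_spatial_attention_1"] = s1
            capture["channel_spatial_attention_2"] = s2
            capture["batch_normalization"] = fused
            capture["adaptive_feature_fusion"] = refined
        gap = global_average_pool(refined)
        gmp = global_max_pool(refined)
        v = T.concat([gap, gmp], axis=1)
        h = self.drop1(self.dense1(v, training), training)
        h = self.drop2(self.dense2(h, training), training)
        logit = self.dense_out(h, training)
        if capture is not None:
            capture["logit"] = logit
        return T.sigmoid(logit)

    __call__ = forward

    # -- bookkeeping ---------------------------------------------------
    def layer_table(self) -> list[dict]:
        """Rows (layer, output shape, parameters, connected to) mirroring the
        architecture summary."""
        shapes = self.expected_shapes()
        zero = {"multiply", "add", "global_average_pooling2d", "global_max_pooling2d", "concatenate", "dropout_1", "dropout_2", "input_layer"}
        connectivity = {
            "input_layer": "-",
            self.backbone.name: "input_layer",
            "conv2d_s1": self.backbone.name,
            "channel_spatial_attention_1": "conv2d_s1",
            "conv2d_s2": self.backbone.name,
            "depthwise_conv2d": "conv2d_s2",
            "channel_spatial_attention_2": "depthwise_conv2d",
            "multiply": "channel_spatial_attention_1, channel_spatial_attention_2",
            "add": "channel_spatial_attention_1, channel_spatial_attention_2, multiply",
            "batch_normalization": "add",
            "adaptive_feature_fusion": "batch_normalization",
            "global_average_pooling2d": "adaptive_feature_fusion",
            "global_max_pooling2d": "adaptive_feature_fusion",
            "concatenate": "global_average_pooling2d, global_max_pooling2d",
            "dense_1": "concatenate",
            "dropout_1": "dense_1",
            "dense_2": "dropout_1",
            "dropout_2": "dense_2",
            "dense_output": "dropout_2",
        }
        by_name = {layer.name: layer for layer in self.sublayers}
        rows = []
        for name, shape in shapes.items():
            params = 0 if name in zero else by_name[name].param_count()
            rows.append(
                {
                    "layer": name,
                    "output_shape": ("None",) + shape,
                    "parameters": params,
                    "connected_to": connectivity[name],
                }
            )
        return rows

    def per_layer_counts(self) -> dict[str, int]:
        return {layer.name: layer.param_count() for layer in self.sublayers}


def build_model(config: ModelConfig | None = None, seed: int = 0, weights: str | None = None) -> DualStreamModel:
    return DualStreamModel(config or ModelConfig(), seed=seed, weights=weights)


def count_parameters(model: DualStreamModel, layer_name: str | None = None):
    """Exact integer parameter accounting; ``layer_name`` selects one row."""
    per_layer = model.per_layer_counts()
    if layer_name is not None:
        if layer_name not in per_layer:
            raise KeyError(f"unknown layer {layer_name!r}; known: {sorted(per_layer)}")
        return per_layer[layer_name]
    total = model.param_count()
    trainable = model.trainable_param_count()
    return {
        "total": total,
        "trainable": trainable,
        "non_trainable": total - trainable,
        "per_layer": per_layer,
    }


def predict(model: DualStreamModel, batch: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Per-sample probabilities in (0,1); deterministic (dropout inactive)."""
    batch = np.asarray(batch, dtype=float)
    s = model.config.input_size
    if batch.ndim != 4 or batch.shape[1:] != (s, s, 3):
        raise ValueError(f"expected input of shape (N, {s}, {s}, 3), got {batch.shape}")
    out = np.empty(batch.shape[0])
    for lo in range(0, batch.shape[0], batch_size):
        chunk = batch[lo : lo + batch_size]
        out[lo : lo + chunk.shape[0]] = model.forward(Tensor(chunk), training=False).data[:, 0]
    return out


def classify(p, threshold: float = 0.5):
    """Binary decision: 1 iff p >= threshold (high suspicion, PI-RADS 4-5)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0,1]")
    labels = (p >= threshold).astype(int)
    return labels if labels.ndim else int(labels)


def summary(model: DualStreamModel, as_json: bool = False):
    """Architecture table (layer, output shape, parameters, connectivity)."""
    rows = model.layer_table()
    counts = count_parameters(model)
    if as_json:
        return {"layers": rows, "total": counts["total"], "trainable": counts["trainable"], "non_trainable": counts["non_trainable"]}
    widths = (38, 22, 14)
    lines = [f"{'Layer':<{widths[0]}}{'Output Shape':<{widths[1]}}{'Parameters':>{widths[2]}}  Connected To"]
    lines.append("-" * (sum(widths) + 30))
    for r in rows:
        shape = "(" + ", ".join(str(d) for d in r["output_shape"]) + ")"
        lines.append(f"{r['layer']:<{widths[0]}}{shape:<{widths[1]}}{r['parameters']:>{widths[2]},}  {r['connected_to']}")
    lines.append("-" * (sum(widths) + 30))
    lines.append(f"Total parameters: {counts['total']:,}")
    lines.append(f"Trainable parameters: {counts['trainable']:,}")
    lines.append(f"Non-trainable parameters: {counts['non_trainable']:,}")
    return "\n".join(lines)


def save_weights(model: DualStreamModel, path: str) -> None:
    np.savez(path, **model.get_weights())


def load_weights(model: DualStreamModel, path: str) -> None:
    archive = np.load(path)
    model.set_weights({k: archive[k] for k in archive.files})
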