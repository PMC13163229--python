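"""Grad-CAM attribution for the dual-stream classifier.

The class score is the pre-sigmoid logit (negated when the prediction is
low-suspicion, so the map always highlights evidence for the predicted
class). Channel weights are the spatial means of the score's gradient on the
target feature map; the weighted channel sum is rectified, bilinearly
upsampled to the input size and min-max normalized to [0, 1] (an all-zero
map stays all-zero).

Any block output can serve as the target layer. The default is the local
stream's attention output (``channel_spatial_attention_1``): on hypointense
focal lesions the fused-map CAM is unreliable, because lesion evidence often
enters the fused representation with negative sign and is removed by the
rectification, whereas the local stream carries positively activated lesion
responses (see the methods note for the measurements behind this choice).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from skimage.transform import resize

from .network import DualStreamModel
from .tensor import Tensor

__all__ = ["GradCamResult", "grad_cam", "overlay", "save_panel"]


@dataclass
class GradCamResult:
    heatmap: np.ndarray  # (input_size, input_size), values in [0, 1]
    raw_map: np.ndarray  # pre-upsampling class-activation map
    target_layer: str
    prediction: float


def grad_cam(model: DualStreamModel, image: np.ndarray, target_layer: str = "channel_spatial_attention_1") -> GradCamResult:
    """Class-activation heatmap for one preprocessed image (H, W, 3)."""
    size = model.config.input_size
    image = np.asarray(image, dtype=float)
    if image.shape != (size, size, 3):
        raise ValueError(f"expected preprocessed image of shape ({size}, {size}, 3), got {image.shape}")
    capture: dict = {}
    x = Tensor(image[None])
    prob = model.forward(x, training=False, capture=capture)
    if target_layer not in capture:
        raise KeyError(f"unknown target layer {target_layer!r}; capturable: {sorted(k for k in capture if k != 'logit')}")
    feats = capture[target_layer]
    logit = capture["logit"]
    p = float(prob.data[0, 0])
    sign = 1.0 if p >= 0.5 else -1.0  # evidence for the predicted class
    logit.backward(np.full_like(logit.data, sign))
    grad = feats.grad
    if grad is None or not np.any(grad):
        warnings.warn("zero gradient everywhere; returning an all-zero heatmap", stacklevel=2)
        raw = np.zeros(feats.data.shape[1:3])
    else:
        weights = grad[0].mean(axis=(0, 1))  # spatial mean per channel
        raw = np.maximum((feats.data[0] * weights).sum(axis=2), 0.0)
    heatmap = resize(raw, (size, size), order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    peak = heatmap.max()
    if peak > 0:
        heatmap = heatmap / peak
    return GradCamResult(heatmap=heatmap, raw_map=raw, target_layer=target_layer, prediction=p)


def overlay(image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.4) -> np.ndarray:
    """Jet-colormapped heatmap alpha-blended onto the grayscale slice (uint8 RGB)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0,1], got {alpha}")
    from matplotlib import colormaps

    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = image.mean(axis=2)
    heatmap = np.broadcast_to(np.asarray(heatmap, dtype=float), image.shape)
    lo, hi = image.min(), image.max()
    gray = np.zeros_like(image) if hi == lo else (image - lo) / (hi - lo)
    base = np.repeat(gray[:, :, None], 3, axis=2)
    colored = colormaps["jet"](np.clip(heatmap, 0.0, 1.0))[:, :, :3]
    blended = (1.0 - alpha) * base + alpha * colored
    return np.clip(np.round(blended * 255.0), 0, 255).astype(np.uint8)


def save_panel(image, result: GradCamResult, path, alpha: float = 0.4, title: str | None = None) -> None:
    """Three-panel PNG: original slice, raw heatmap, overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = image.mean(axis=2)
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    axes[0].imshow(image, cmap="gray")
    axes[0].set_title(title or "original")
    axes[1].imshow(result.heatmap, cmap="jet", vmin=0, vmax=1)
    axes[1].set_title(f"heatmap (p={result.prediction:.4f})")
    axes[2].imshow(overlay(image, result.heatmap, alpha=alpha))
    axes[2].set_title("overlay")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
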