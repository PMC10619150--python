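"""Grad-CAM heat maps for lesion-localization inspection.

Grad-CAM weights each channel of a chosen convolutional feature map by the
spatial average of the target-class score's gradient at that layer, sums the
weighted channels, rectifies, normalizes by the maximum (a zero map stays
zero) and upsamples bilinearly to the input size.  The result highlights the
image regions whose activation pushed the class score up — for the leaf task,
ideally the lesions themselves.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .models import MobileNetClassifier
from .nn import Tensor


@dataclass(frozen=True)
class Heatmap:
    """H×W map in [0, 1]; max is 1 unless the raw map was identically zero."""
    values: np.ndarray
    target_class: int
    layer_name: str

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.min() < 0 or v.max() > 1 + 1e-6:
            raise ValueError("heatmap must be a 2-d array within [0, 1]")


def gradcam(model: MobileNetClassifier, image: np.ndarray, target_class: int,
            layer_name: str | None = None) -> Heatmap:
    """Class-activation heat map for one preprocessed image.

    ``image`` is (3, H, W) or (1, 3, H, W), already normalized as in
    training.  ``layer_name`` defaults to the last bottleneck's output (the
    deepest spatial map); available names come from
    ``model.feature_layer_names()``.
    """
    names = model.feature_layer_names()
    if layer_name is None:
        layer_name = f"bneck{len(model.blocks) - 1}"
    if layer_name not in names:
        raise KeyError(f"unknown layer {layer_name!r}; available: {names}")
    if not 0 <= target_class < model.spec.num_classes:
        raise IndexError(
            f"target_class {target_class} out of range "
            f"[0, {model.spec.num_classes})")
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[0] != 1:
        raise ValueError("expected one image of shape (3, H, W)")
    in_hw = x.shape[2:]

    model.eval()
    xt = Tensor(x, requires_grad=True)
    logits, acts = model.forward(xt, return_activations=True)
    seed = np.zeros_like(logits.data)
    seed[0, target_class] = 1.0
    logits.backward(seed)

    layer = acts[layer_name]
    if layer.grad is None:  # score constant in the input -> zero map
        raw = np.zeros(layer.data.shape[2:], dtype=np.float32)
    else:
        weights = layer.grad[0].mean(axis=(1, 2))            # (C,)
        raw = np.maximum((weights[:, None, None] * layer.data[0]).sum(axis=0),
                         0.0)
    peak = raw.max()
    if peak > 0:
        raw = raw / peak
    zoom = (in_hw[0] / raw.shape[0], in_hw[1] / raw.shape[1])
    up = ndimage.zoom(raw, zoom, order=1, mode="nearest")
    up = np.clip(up, 0.0, 1.0)
    if up.max() > 0:   # interpolation can shave the peak; renormalize
        up = up / up.max()
    return Heatmap(values=up.astype(np.float32), target_class=target_class,
                   layer_name=layer_name)


def overlay(heatmap: Heatmap, image: np.ndarray, alpha: float = 0.5,
            colormap: str = "jet") -> np.ndarray:
    """Alpha-blend the color-mapped heat map onto an RGB image.

    ``image`` is H×W×3 uint8 (or float in [0, 1]); returns uint8 H×W×3.
    ``alpha=0`` reproduces the image, ``alpha=1`` the pure color map.
    """
    import matplotlib

    hm = heatmap.values
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be HxWx3")
    if img.shape[:2] != hm.shape:
        raise ValueError(
            f"size mismatch: heatmap {hm.shape} vs image {img.shape[:2]}")
    if img.dtype != np.uint8:
        img = np.clip(img * 255.0, 0, 255).astype(np.uint8)
    colored = (matplotlib.colormaps[colormap](hm)[..., :3] * 255.0) \
        .astype(np.float32)
    blended = (1.0 - alpha) * img.astype(np.float32) + alpha * colored
    return np.clip(blended + 0.5, 0, 255).astype(np.uint8)
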