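"""Interpretability: Grad-CAM overlays and LSBDU spectral attention panels.

Grad-CAM weights each channel of a chosen convolutional feature map by the
spatial mean of the class-logit gradient at that layer, forms the rectified
weighted sum of activations, upsamples it bilinearly to the input size, and
min–max rescales to [0, 1]. The spectral attention map visualizes the
magnitude of the first LSBDU's gated high-frequency branch — the band a
plain max pool would discard.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import ndimage

from ._nn import LSBDULayer, Model
from .architecture import default_cam_layer, first_lsbdu_name

__all__ = ["SaliencyMap", "grad_cam", "lsbdu_attention_map", "fig_panel"]


@dataclass
class SaliencyMap:
    """(H, W) map in [0, 1] tied to a class and a layer."""

    values: np.ndarray
    target_class: int
    layer_name: str


def _rescale01(m: np.ndarray) -> np.ndarray:
    m = np.maximum(m, 0.0)
    mx = m.max()
    return m / mx if mx > 0 else m


def _upsample(m: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    zoom = (out_hw[0] / m.shape[0], out_hw[1] / m.shape[1])
    return ndimage.zoom(m, zoom, order=1)


def grad_cam(model: Model, image: np.ndarray, class_index: int,
             layer_name: str | None = None) -> SaliencyMap:
    """Grad-CAM saliency for one (H, W, 3) image.

    Raises ``KeyError`` for an unknown layer and ``ValueError`` for a class
    index outside the head's range.
    """
    if layer_name is None:
        layer_name = default_cam_layer(model)
    if layer_name not in model.layer_names:
        raise KeyError(f"unknown layer {layer_name!r}")
    x = np.asarray(image, dtype=np.float32)[None].transpose(0, 3, 1, 2)
    logits = model.forward(x, train=False)
    if not 0 <= class_index < logits.shape[1]:
        raise ValueError("class index out of range")
    acts = model.activation(layer_name)
    if acts.ndim != 4:
        raise KeyError(f"layer {layer_name!r} is not a spatial feature map")
    dlogits = np.zeros_like(logits)
    dlogits[0, class_index] = 1.0
    grads = model.backward(dlogits, capture={layer_name})[layer_name]
    weights = grads[0].mean(axis=(1, 2))                      # (C,)
    cam = np.maximum((weights[:, None, None] * acts[0]).sum(axis=0), 0.0)
    cam = _upsample(cam, image.shape[:2])
    return SaliencyMap(values=_rescale01(cam), target_class=class_index,
                       layer_name=layer_name)


def lsbdu_attention_map(model: Model, image: np.ndarray,
                        lsbdu_name: str | None = None) -> np.ndarray:
    """First-LSBDU spectral attention, upsampled to the input size, in [0,1]."""
    if lsbdu_name is None:
        lsbdu_name = first_lsbdu_name(model)
    layer = model[lsbdu_name]
    if not isinstance(layer, LSBDULayer):
        raise KeyError(f"{lsbdu_name!r} is not an LSBDU layer")
    x = np.asarray(image, dtype=np.float32)[None].transpose(0, 3, 1, 2)
    model.forward(x, train=False)
    idx = model.layer_names.index(lsbdu_name)
    feed = x if idx == 0 else model.activation(model.layer_names[idx - 1])
    att = layer.attention(feed)[0]
    return np.clip(_upsample(att, image.shape[:2]), 0.0, 1.0)


def fig_panel(model: Model, image: np.ndarray, class_index: int,
              out_path: str, layer_name: str | None = None,
              overlay_alpha: float = 0.5, title: str | None = None) -> str:
    """Write the three-panel figure: original | spectral attention | Grad-CAM.

    Panel (a) is the raw input, (b) the first LSBDU's attention heatmap and
    (c) the Grad-CAM overlay at the given opacity. Deterministic given the
    model and image. Returns the output path.
    """
    cam = grad_cam(model, image, class_index, layer_name)
    att = lsbdu_attention_map(model, image)
    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    axes[0].imshow(np.clip(image, 0, 1))
    axes[0].set_title("input")
    axes[1].imshow(att, cmap="magma", vmin=0.0, vmax=1.0)
    axes[1].set_title("LSBDU spectral attention")
    axes[2].imshow(np.clip(image, 0, 1))
    axes[2].imshow(cam.values, cmap="jet", alpha=overlay_alpha, vmin=0.0, vmax=1.0)
    axes[2].set_title("Grad-CAM overlay")
    for ax in axes:
        ax.axis("off")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return str(out_path)
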