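"""Gradient-weighted class activation mapping (Grad-CAM).

For a chosen convolutional layer with activations A^k, Grad-CAM forms
per-channel weights as the spatial global average of the gradient of the
(pre-softmax) class score y_c,

    w_k = (1 / Z) * sum_ij  d y_c / d A^k_ij,

and the class-discriminative localization map as ReLU(sum_k w_k A^k).
The map is bilinearly upsampled to the input size and min-max normalized
to [0, 1]; an all-zero map (class evidence nowhere positive) stays zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .cnn import Model


@dataclass(frozen=True)
class Heatmap:
    values: np.ndarray  # (H, W) in [0, 1]
    source_layer: str
    target_class: int
    input_size: int


def gradcam(model: Model, image: np.ndarray, target_class: int,
            layer: str | None = None) -> Heatmap:
    """Grad-CAM heatmap for one grayscale image.

    ``layer`` defaults to the model's last convolutional (or
    convolution-bearing block) layer — the standard choice, trading
    spatial resolution for high-level semantics.
    """
    conv_names = model.conv_layer_names()
    if not conv_names:
        raise ValueError("model has no convolutional layers")
    if layer is None:
        layer = conv_names[-1]
    elif layer not in model.layer_names():
        raise KeyError(f"unknown layer: {layer!r}")

    image = np.asarray(image, dtype=np.float64)
    if image.shape != (model.input_size, model.input_size):
        raise ValueError(
            f"image shape {image.shape} does not match model input size {model.input_size}")

    x = model.prepare(image)
    logits = model.forward(x, train=False, keep_activations=True)
    if not 0 <= target_class < logits.shape[1]:
        raise ValueError(f"target_class {target_class} out of range")

    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0  # gradient of the raw class score
    grad = model.backward(dlogits, to_layer=layer)  # d y_c / d A, at layer output
    acts = model.activation(layer)

    weights = grad[0].mean(axis=(1, 2))  # (channels,)
    cam = np.maximum((weights[:, None, None] * acts[0]).sum(axis=0), 0.0)
    cam = resize(cam, (model.input_size, model.input_size), order=1,
                 mode="edge", anti_aliasing=False, preserve_range=True)
    lo, hi = cam.min(), cam.max()
    if hi > lo:
        cam = (cam - lo) / (hi - lo)
    elif hi > 0:
        cam = np.ones_like(cam)
    else:
        cam = np.zeros_like(cam)
    return Heatmap(values=cam, source_layer=layer, target_class=int(target_class),
                   input_size=model.input_size)


def raw_cam(model: Model, image: np.ndarray, target_class: int, layer: str) -> np.ndarray:
    """The un-normalized, un-upsampled ReLU'd weighted channel sum at the
    layer's native resolution; exposed for exact regression checks."""
    x = model.prepare(np.asarray(image, dtype=np.float64))
    logits = model.forward(x, train=False, keep_activations=True)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    grad = model.backward(dlogits, to_layer=layer)
    acts = model.activation(layer)
    weights = grad[0].mean(axis=(1, 2))
    return np.maximum((weights[:, None, None] * acts[0]).sum(axis=0), 0.0)


def overlay(heatmap: Heatmap, image: np.ndarray, colormap: str = "jet",
            alpha: float = 0.6) -> np.ndarray:
    """Alpha-blended color rendering of a heatmap over a grayscale image.

    The blend weight at each pixel is ``alpha * heat``, so zero-heat
    pixels reproduce the input exactly.  Returns an (H, W, 3) float
    raster in [0, 1]; purely for reports, never for quantification.
    """
    import matplotlib

    h = heatmap.values
    img = np.asarray(image, dtype=np.float64)
    if img.shape != h.shape:
        raise ValueError(f"image shape {img.shape} != heatmap shape {h.shape}")
    cmap = matplotlib.colormaps[colormap]
    color = cmap(h)[..., :3]
    base = np.clip(img, 0, 1)[..., None].repeat(3, axis=-1)
    w = (alpha * h)[..., None]
    return (1 - w) * base + w * color


def save_heatmap_png(heatmap: Heatmap, path) -> None:
    """16-bit grayscale PNG (values scaled by 65535)."""
    import imageio.v3 as iio

    iio.imwrite(path, np.round(heatmap.values * 65535).astype(np.uint16))


def save_heatmap_csv(heatmap: Heatmap, path) -> None:
    np.savetxt(path, heatmap.values, delimiter=",", fmt="%.8f")


def load_heatmap_csv(path, source_layer: str = "", target_class: int = 0) -> Heatmap:
    vals = np.atleast_2d(np.loadtxt(path, delimiter=","))
    return Heatmap(values=vals, source_layer=source_layer,
                   target_class=target_class, input_size=vals.shape[0])
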