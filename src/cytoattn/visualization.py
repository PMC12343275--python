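"""Attention-map rendering: colormaps, overlays, Grad-CAM and figure panels.

The attention map A produced after stage 1 lives at feature-map resolution;
for display it is bilinearly upsampled to image resolution, min-max
normalized, mapped through a blue-cyan-green-yellow-red colormap (warm =
high attention) and alpha-blended onto the original image. Grad-CAM maps
for the comparison models go through the same display path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import relu

logger = logging.getLogger(__name__)

__all__ = [
    "ColorMapSpec",
    "AttentionOverlay",
    "upsample_map",
    "normalize_map",
    "apply_colormap",
    "overlay",
    "grad_cam",
    "attention_overlay",
    "save_panel",
]


@dataclass(frozen=True)
class ColorMapSpec:
    """Piecewise-linear colormap through ordered (position, RGB) anchors."""

    anchors: tuple[tuple[float, tuple[int, int, int]], ...] = (
        (0.00, (0, 0, 255)),  # blue: lowest attention
        (0.25, (0, 255, 255)),  # cyan
        (0.50, (0, 255, 0)),  # green
        (0.75, (255, 255, 0)),  # yellow
        (1.00, (255, 0, 0)),  # red: highest attention
    )

    def __post_init__(self) -> None:
        pos = [p for p, _ in self.anchors]
        if pos != sorted(set(pos)) or pos[0] != 0.0 or pos[-1] != 1.0:
            raise ValueError("anchor positions must strictly increase from 0 to 1")


@dataclass
class AttentionOverlay:
    heatmap: np.ndarray  # (rows, cols, 3) uint8
    composite: np.ndarray  # (rows, cols, 3) uint8
    alpha: float


def upsample_map(a: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Bilinear upsampling with corner alignment.

    Output values are convex combinations of input values, so they stay
    within ``[a.min(), a.max()]``.
    """
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValueError("cannot upsample an empty map")
    rows, cols = target_size
    src_r, src_c = a.shape

    def coords(n_out: int, n_in: int) -> np.ndarray:
        if n_out == 1 or n_in == 1:
            return np.zeros(n_out)
        return np.arange(n_out) * (n_in - 1) / (n_out - 1)

    ry = coords(rows, src_r)
    cx = coords(cols, src_c)
    y0 = np.clip(np.floor(ry).astype(int), 0, max(src_r - 2, 0))
    x0 = np.clip(np.floor(cx).astype(int), 0, max(src_c - 2, 0))
    wy = (ry - y0)[:, None]
    wx = (cx - x0)[None, :]
    y1 = np.minimum(y0 + 1, src_r - 1)
    x1 = np.minimum(x0 + 1, src_c - 1)
    return (
        a[np.ix_(y0, x0)] * (1 - wy) * (1 - wx)
        + a[np.ix_(y0, x1)] * (1 - wy) * wx
        + a[np.ix_(y1, x0)] * wy * (1 - wx)
        + a[np.ix_(y1, x1)] * wy * wx
    )


def normalize_map(a: np.ndarray) -> np.ndarray:
    """Min-max rescale into [0, 1]; a constant map becomes 0.5 everywhere."""
    a = np.asarray(a, dtype=float)
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        return np.full_like(a, 0.5)
    return (a - lo) / (hi - lo)


_clip_warned = False


def apply_colormap(v, spec: ColorMapSpec = ColorMapSpec()) -> np.ndarray:
    """Map values in [0, 1] to RGB by interpolating the anchor colors.

    Accepts a scalar or an array; values outside [0, 1] are clipped (logged
    once). Returns uint8 RGB with half-up rounding; the trailing axis is the
    channel axis.
    """
    global _clip_warned
    arr = np.asarray(v, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        if not _clip_warned:
            logger.warning("colormap input outside [0, 1]; clipping")
            _clip_warned = True
        arr = np.clip(arr, 0.0, 1.0)
    pos = np.array([p for p, _ in spec.anchors])
    rgb = np.array([c for _, c in spec.anchors], dtype=float)
    out = np.stack([np.interp(arr, pos, rgb[:, ch]) for ch in range(3)], axis=-1)
    return np.floor(out + 0.5).astype(np.uint8)


def overlay(image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.4) -> np.ndarray:
    """Alpha blend: ``(1 - alpha) * image + alpha * heatmap`` per channel."""
    image = np.asarray(image)
    heatmap = np.asarray(heatmap)
    if image.shape != heatmap.shape:
        raise ValueError(f"image shape {image.shape} != heatmap shape {heatmap.shape}")
    if alpha == 0.0:
        return image.copy()
    blended = (1.0 - alpha) * image.astype(float) + alpha * heatmap.astype(float)
    return np.floor(blended + 0.5).astype(np.uint8)


def grad_cam(model, image: np.ndarray, target_class: int, layer_tag: str) -> np.ndarray:
    """Gradient-weighted class activation map at a tagged layer.

    Runs one forward pass on a single preprocessed image ``(3, H, W)``,
    backpropagates the raw class score, weights each channel of the tagged
    activation by the spatial mean of its gradient and rectifies the
    weighted sum. The returned map is at the layer's resolution and is not
    yet display-normalized.
    """
    if layer_tag not in model.LAYER_TAGS:
        raise KeyError(f"unknown layer tag {layer_tag!r}; available: {model.LAYER_TAGS}")
    x = image[None] if image.ndim == 3 else image
    scores = model.forward(x, training=True)
    dscores = np.zeros_like(scores)
    dscores[0, target_class] = 1.0
    model.zero_grads()
    model.backward(dscores)
    act = model.activations[layer_tag][0]
    grad = model.activation_grads[layer_tag][0]
    weights = grad.mean(axis=(1, 2))
    return relu(np.tensordot(weights, act, axes=(0, 0)))


def attention_overlay(
    image: np.ndarray,
    attention: np.ndarray,
    alpha: float = 0.4,
    cmap: ColorMapSpec = ColorMapSpec(),
) -> AttentionOverlay:
    """Full display path: upsample, normalize, colorize, blend."""
    up = upsample_map(attention, image.shape[:2])
    heat = apply_colormap(normalize_map(up), cmap)
    comp = overlay(image, heat, alpha)
    return AttentionOverlay(heatmap=heat, composite=comp, alpha=alpha)


def attention_localization_fraction(model, samples, input_size, batch_size: int = 64) -> float:
    """Fraction of samples whose attention concentrates on the cell.

    For each sample the attention map is upsampled to image resolution and
    min-max normalized; the sample counts as localized when the mean
    normalized attention inside the ground-truth ``cell_mask`` exceeds the
    mean outside it.
    """
    from .training import preprocess_images

    x = preprocess_images([s.pixels for s in samples], input_size)
    hits = 0
    for start in range(0, len(samples), batch_size):
        _, _, att = model.predict(x[start : start + batch_size])
        for a, sample in zip(att, samples[start : start + batch_size]):
            norm = normalize_map(upsample_map(a, sample.pixels.shape[:2]))
            inside = norm[sample.cell_mask].mean()
            outside = norm[~sample.cell_mask].mean()
            hits += inside > outside
    return hits / len(samples)


def save_panel(path, originals, overlays: list[AttentionOverlay], titles=None) -> None:
    """Write a three-row figure: originals / heatmaps / composites."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(originals)
    fig, axes = plt.subplots(3, n, figsize=(2.2 * n, 6.8), squeeze=False)
    for j, (img, ov) in enumerate(zip(originals, overlays)):
        for i, panel in enumerate((img, ov.heatmap, ov.composite)):
            axes[i][j].imshow(panel)
            axes[i][j].axis("off")
        if titles is not None:
            axes[0][j].set_title(titles[j], fontsize=8)
    axes[0][0].set_ylabel("original")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
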