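"""Comparison architectures and the attention-stability measurement.

Two models are provided for side-by-side experiments against the primary
spatial-attention CNN:

* :class:`SelfAttentionResNet` — a residual backbone of the same family as
  the primary model with a residual query/key/value self-attention block
  inserted before the final residual stage. The original comparison used an
  ImageNet-pretrained ResNet50; pretrained weights are out of scope here,
  so the backbone is a small randomly initialized residual network of the
  same family. Its focus regions are visualized with Grad-CAM rather than
  an explicit attention map.
* :class:`MultiLayerCNN` — a plain stack of conv+BN+ReLU layers (no
  shortcuts) with one spatial attention gate mid-stack.

Both expose the same forward/backward, tagging and checkpoint surface as
the primary model. The module also quantifies the qualitative claim that
some models' regions of interest drift during training: the stability
metric is the mean per-pixel absolute change of the display-normalized
attention (or Grad-CAM) map between consecutive epochs, averaged over a
fixed set of probe images.
"""

from __future__ import annotations

import numpy as np

from .model import ArchitectureConfig
from .nn import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    ReLU,
    ResidualBlock,
    SelfAttentionBlock,
    SpatialAttention,
    softmax,
)
from .nn.layers import Layer
from .visualization import normalize_map

__all__ = ["SelfAttentionResNet", "MultiLayerCNN", "attention_stability", "AttentionProbe"]


class SelfAttentionResNet(Layer):
    """Residual backbone with a QKV self-attention block before the last stage."""

    LAYER_TAGS = ("stem", "stage1", "stage2", "self_attention", "stage3")

    def __init__(self, config: ArchitectureConfig, rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        c1, c2, c3 = config.stage_channels
        self.stem_conv = Conv2d(3, config.stem_channels, 3, stride=config.stem_stride, rng=rng, dtype=dtype)
        self.stem_bn = BatchNorm2d(config.stem_channels, dtype=dtype)
        self.stem_relu = ReLU()
        self.stage1 = ResidualBlock(config.stem_channels, c1, stride=1, rng=rng, dtype=dtype)
        self.stage2 = ResidualBlock(c1, c2, stride=2, rng=rng, dtype=dtype)
        self.self_attention = SelfAttentionBlock(c2, rng=rng, dtype=dtype)
        self.stage3 = ResidualBlock(c2, c3, stride=2, rng=rng, dtype=dtype)
        self.pool = GlobalAvgPool()
        self.fc = Linear(c3, config.num_classes, rng=rng, dtype=dtype)
        self.activations: dict[str, np.ndarray] = {}
        self.activation_grads: dict[str, np.ndarray] = {}

    def children(self):
        return (
            self.stem_conv, self.stem_bn, self.stem_relu,
            self.stage1, self.stage2, self.self_attention, self.stage3,
            self.pool, self.fc,
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected input of shape (N, 3, H, W), got {x.shape}")
        h = self.stem_relu.forward(self.stem_bn.forward(self.stem_conv.forward(x, training), training), training)
        self.activations["stem"] = h
        h = self.stage1.forward(h, training)
        self.activations["stage1"] = h
        h = self.stage2.forward(h, training)
        self.activations["stage2"] = h
        h = self.self_attention.forward(h, training)
        self.activations["self_attention"] = h
        h = self.stage3.forward(h, training)
        self.activations["stage3"] = h
        return self.fc.forward(self.pool.forward(h, training), training)

    def backward(self, dscores: np.ndarray) -> np.ndarray:
        d = self.pool.backward(self.fc.backward(dscores))
        self.activation_grads["stage3"] = d
        d = self.stage3.backward(d)
        self.activation_grads["self_attention"] = d
        d = self.self_attention.backward(d)
        self.activation_grads["stage2"] = d
        d = self.stage2.backward(d)
        self.activation_grads["stage1"] = d
        d = self.stage1.backward(d)
        self.activation_grads["stem"] = d
        return self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(d)))

    def predict(self, x: np.ndarray):
        scores = self.forward(x, training=False)
        return scores, softmax(scores, axis=-1)


class MultiLayerCNN(Layer):
    """Plain multi-layer CNN with one spatial attention gate mid-stack.

    ``depth`` conv+BN+ReLU layers without shortcuts; the attention gate sits
    after layer ``depth // 2``. Downsampling strides are placed at layers 1,
    depth//2 + 1 and depth - 1 (0-based) so the final map is pooled from a
    small grid, mirroring the primary model's resolution schedule.
    """

    def __init__(
        self,
        config: ArchitectureConfig,
        depth: int = 6,
        width: int = 32,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if depth < 2:
            raise ValueError("depth must be at least 2")
        self.config = config
        self.depth = depth
        self.attention_index = depth // 2  # attention applied after this many conv layers
        stride_layers = {1, depth // 2 + 1, depth - 1}
        self.convs: list[Conv2d] = []
        self.bns: list[BatchNorm2d] = []
        self.relus: list[ReLU] = []
        in_c = 3
        for i in range(depth):
            stride = 2 if i in stride_layers else 1
            self.convs.append(Conv2d(in_c, width, 3, stride=stride, rng=rng, dtype=dtype))
            self.bns.append(BatchNorm2d(width, dtype=dtype))
            self.relus.append(ReLU())
            in_c = width
        self.attention = SpatialAttention(width, config.attention_kernel, rng=rng, dtype=dtype)
        self.pool = GlobalAvgPool()
        self.fc = Linear(width, config.num_classes, rng=rng, dtype=dtype)
        self.activations: dict[str, np.ndarray] = {}
        self.activation_grads: dict[str, np.ndarray] = {}

    @property
    def LAYER_TAGS(self):
        return tuple(f"conv{i}" for i in range(self.depth)) + ("attended",)

    def children(self):
        kids: list[Layer] = []
        for conv, bn, relu_ in zip(self.convs, self.bns, self.relus):
            kids += [conv, bn, relu_]
        kids += [self.attention, self.pool, self.fc]
        return tuple(kids)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected input of shape (N, 3, H, W), got {x.shape}")
        h = x
        for i in range(self.depth):
            h = self.relus[i].forward(self.bns[i].forward(self.convs[i].forward(h, training), training), training)
            self.activations[f"conv{i}"] = h
            if i + 1 == self.attention_index:
                h = self.attention.forward(h, training)
                self.activations["attended"] = h
        return self.fc.forward(self.pool.forward(h, training), training)

    def backward(self, dscores: np.ndarray) -> np.ndarray:
        d = self.pool.backward(self.fc.backward(dscores))
        for i in reversed(range(self.depth)):
            if i + 1 == self.attention_index:
                self.activation_grads["attended"] = d
                d = self.attention.backward(d)
            self.activation_grads[f"conv{i}"] = d
            d = self.convs[i].backward(self.bns[i].backward(self.relus[i].backward(d)))
        return d

    @property
    def attention_map(self) -> np.ndarray | None:
        return self.attention.last_attention

    def predict(self, x: np.ndarray):
        scores = self.forward(x, training=False)
        return scores, softmax(scores, axis=-1)


class AttentionProbe:
    """Epoch callback collecting display-normalized maps on fixed probes.

    ``map_fn(model, probe_batch)`` must return one single-channel map per
    probe image; for the primary model this is the attention map, for the
    comparison models a Grad-CAM map.
    """

    def __init__(self, probe_batch: np.ndarray, map_fn) -> None:
        self.probe_batch = probe_batch
        self.map_fn = map_fn
        self.maps: list[np.ndarray] = []  # one (P, h, w) array per epoch

    def __call__(self, epoch: int, model) -> None:
        raw = self.map_fn(model, self.probe_batch)
        self.maps.append(np.stack([normalize_map(m) for m in raw]))


def attention_stability(maps_per_epoch: list[np.ndarray]) -> float:
    """Mean per-pixel absolute change of the map between consecutive epochs.

    Lower values mean the model's focus regions settle; higher values mean
    the visualized regions keep drifting during training.
    """
    if len(maps_per_epoch) < 2:
        raise ValueError("need maps from at least two epochs")
    diffs = [
        float(np.mean(np.abs(a.astype(float) - b.astype(float))))
        for a, b in zip(maps_per_epoch[:-1], maps_per_epoch[1:])
    ]
    return float(np.mean(diffs))
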