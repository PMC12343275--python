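"""The spatial-attention residual CNN classifier.

Architecture (bottom to top):

1. stem: 3x3 convolution (stride 2 by default) + batch norm + ReLU on the
   RGB input;
2. stage 1: residual block at the stem resolution;
3. spatial attention gate on the stage-1 output (the attention map A that
   all visualization derives from);
4. stages 2 and 3: residual blocks with stride 2, doubling channels;
5. global average pooling, flatten, fully connected layer to class scores.

The model exposes class scores, softmax probabilities and the attention map
from a single forward pass, and records tagged intermediate activations and
their gradients so Grad-CAM can be computed at any stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    ReLU,
    ResidualBlock,
    SpatialAttention,
    softmax,
)
from .nn.layers import Layer

#: The five fusion-gene subtype labels, in canonical order.
CLASS_NAMES = ("PML-RARA", "TTMV-RARA", "NPM1-RARA", "STAT5B-RARA", "NUP98-RARG")


@dataclass(frozen=True)
class ArchitectureConfig:
    """Hyper-configuration of the network.

    ``stage_channels`` must be nondecreasing; ``attention_kernel`` must be
    odd (1 collapses channels pointwise).
    """

    input_size: tuple[int, int] = (64, 64)
    stem_channels: int = 32
    stem_stride: int = 2
    stage_channels: tuple[int, int, int] = (32, 64, 128)
    attention_kernel: int = 1
    num_classes: int = 5

    def __post_init__(self) -> None:
        if list(self.stage_channels) != sorted(self.stage_channels):
            raise ValueError("stage_channels must be nondecreasing")
        if self.attention_kernel % 2 != 1:
            raise ValueError("attention_kernel must be odd")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        d = dict(d)
        d["input_size"] = tuple(d["input_size"])
        d["stage_channels"] = tuple(d["stage_channels"])
        return cls(**d)


class AttentionResNet(Layer):
    """CNN with a spatial attention gate after the first residual stage."""

    #: Layer tags at which activations/gradients are recorded for Grad-CAM.
    LAYER_TAGS = ("stem", "stage1", "attended", "stage2", "stage3")

    def __init__(self, config: ArchitectureConfig, rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        c1, c2, c3 = config.stage_channels
        self.stem_conv = Conv2d(3, config.stem_channels, 3, stride=config.stem_stride, rng=rng, dtype=dtype)
        self.stem_bn = BatchNorm2d(config.stem_channels, dtype=dtype)
        self.stem_relu = ReLU()
        self.stage1 = ResidualBlock(config.stem_channels, c1, stride=1, rng=rng, dtype=dtype)
        self.attention = SpatialAttention(c1, config.attention_kernel, rng=rng, dtype=dtype)
        self.stage2 = ResidualBlock(c1, c2, stride=2, rng=rng, dtype=dtype)
        self.stage3 = ResidualBlock(c2, c3, stride=2, rng=rng, dtype=dtype)
        self.pool = GlobalAvgPool()
        self.fc = Linear(c3, config.num_classes, rng=rng, dtype=dtype)
        self.activations: dict[str, np.ndarray] = {}
        self.activation_grads: dict[str, np.ndarray] = {}

    def children(self):
        return (
            self.stem_conv,
            self.stem_bn,
            self.stem_relu,
            self.stage1,
            self.attention,
            self.stage2,
            self.stage3,
            self.pool,
            self.fc,
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map a ``(N, 3, H, W)`` batch to ``(N, num_classes)`` scores."""
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected input of shape (N, 3, H, W), got {x.shape}")
        h = self.stem_conv.forward(x, training=training)
        h = self.stem_bn.forward(h, training=training)
        h = self.stem_relu.forward(h, training=training)
        self.activations["stem"] = h
        h = self.stage1.forward(h, training=training)
        self.activations["stage1"] = h
        h = self.attention.forward(h, training=training)
        self.activations["attended"] = h
        h = self.stage2.forward(h, training=training)
        self.activations["stage2"] = h
        h = self.stage3.forward(h, training=training)
        self.activations["stage3"] = h
        pooled = self.pool.forward(h, training=training)
        return self.fc.forward(pooled, training=training)

    def backward(self, dscores: np.ndarray) -> np.ndarray:
        d = self.fc.backward(dscores)
        d = self.pool.backward(d)
        self.activation_grads["stage3"] = d
        d = self.stage3.backward(d)
        self.activation_grads["stage2"] = d
        d = self.stage2.backward(d)
        self.activation_grads["attended"] = d
        d = self.attention.backward(d)
        self.activation_grads["stage1"] = d
        d = self.stage1.backward(d)
        self.activation_grads["stem"] = d
        d = self.stem_relu.backward(d)
        d = self.stem_bn.backward(d)
        return self.stem_conv.backward(d)

    @property
    def attention_map(self) -> np.ndarray | None:
        """Attention map A from the most recent forward pass, ``(N, H, W)``."""
        return self.attention.last_attention

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Inference pass returning ``(scores, probabilities, attention_map)``."""
        scores = self.forward(x, training=False)
        return scores, softmax(scores, axis=-1), self.attention.last_attention


def save_checkpoint(path, model: Layer, config: ArchitectureConfig, extra: dict | None = None) -> None:
    """Serialize parameters, batch-norm statistics and the config to one file."""
    arrays = {}
    for name, layer, key in model.named_parameters():
        arrays["param:" + name] = layer.params[key]
    for name, layer, key in model.named_buffers():
        arrays["buffer:" + name] = layer.buffers[key]
    meta = {"config": config.to_dict(), "extra": extra or {}}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, model_factory=None) -> tuple[Layer, ArchitectureConfig, dict]:
    """Rebuild a model from :func:`save_checkpoint` output.

    ``model_factory`` maps an :class:`ArchitectureConfig` to a fresh model;
    it defaults to :class:`AttentionResNet`.
    """
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        config = ArchitectureConfig.from_dict(meta["config"])
        factory = model_factory or AttentionResNet
        model = factory(config)
        for name, layer, key in model.named_parameters():
            layer.params[key] = data["param:" + name].copy()
        for name, layer, key in model.named_buffers():
            layer.buffers[key][...] = data["buffer:" + name]
    model.zero_grads()
    return model, config, meta["extra"]
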