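"""Data splitting, preprocessing, Adam optimization and the LR schedule.

Training follows the study protocol: stratified 50/50 train/test split,
cross-entropy loss, Adam, and a step schedule that halves the learning rate
every ``lr_halving_period`` epochs. All randomness (split, shuffling,
weight initialization) derives from one master seed so a run is fully
reproducible on a single device.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .model import ArchitectureConfig, AttentionResNet, CLASS_NAMES
from .nn import softmax
from .nn.layers import Layer
from .synthetic import ImageSample

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "stratified_split",
    "lr_at_epoch",
    "preprocess_images",
    "Adam",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    base_lr: float = 1e-3
    lr_halving_period: int = 10
    seed: int = 0
    split_fraction: float = 0.5  # fraction assigned to the training set
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")


@dataclass
class TrainHistory:
    """Per-epoch record of mean loss, learning rate and training accuracy."""

    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": np.arange(len(self.loss)), "loss": self.loss, "lr": self.lr, "accuracy": self.accuracy}
        )


def stratified_split(
    manifest: pd.DataFrame, fraction: float = 0.5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a manifest per class into train/test parts.

    Per class, ``round-down(count * (1 - fraction))`` samples go to the test
    set and the remainder — including the extra sample when the count is odd
    at fraction 0.5 — to the training set. The two parts are disjoint and
    their union is the input; the assignment is deterministic per seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for label, group in manifest.groupby("label", sort=True):
        n = len(group)
        if n < 2:
            raise ValueError(f"class {label!r} has only {n} sample(s); need at least 2 to split")
        n_test = int(np.floor(n * (1.0 - fraction)))
        n_test = min(max(n_test, 1), n - 1)  # both sides nonempty
        perm = rng.permutation(n)
        test_parts.append(group.iloc[perm[:n_test]])
        train_parts.append(group.iloc[perm[n_test:]])
    train = pd.concat(train_parts).sort_index()
    test = pd.concat(test_parts).sort_index()
    return train, test


def lr_at_epoch(epoch: int, config: TrainConfig) -> float:
    """Step schedule: ``base_lr * 0.5 ** floor(epoch / halving_period)``."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    return config.base_lr * 0.5 ** (epoch // config.lr_halving_period)


def preprocess_images(
    images: list[np.ndarray], size: tuple[int, int], dtype=np.float32
) -> np.ndarray:
    """Resize (bilinear), scale to [0, 1], standardize with mean/std 0.5.

    Returns a ``(N, 3, rows, cols)`` array ready for the network.
    """
    rows, cols = size
    out = np.empty((len(images), 3, rows, cols), dtype=dtype)
    for i, img in enumerate(images):
        if img.shape[:2] != (rows, cols):
            img = np.asarray(Image.fromarray(img).resize((cols, rows), Image.BILINEAR))
        arr = img.astype(dtype) / 255.0
        out[i] = ((arr - 0.5) / 0.5).transpose(2, 0, 1)
    return out


class Adam:
    """Adam optimizer over a model's named parameters."""

    def __init__(self, model: Layer, betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.model = model
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = {name: np.zeros_like(layer.params[key]) for name, layer, key in model.named_parameters()}
        self.v = {name: np.zeros_like(layer.params[key]) for name, layer, key in model.named_parameters()}

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name, layer, key in self.model.named_parameters():
            g = layer.grads[key]
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            layer.params[key] -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def load_manifest_images(manifest: pd.DataFrame, root) -> list[np.ndarray]:
    """Read the RGB images a manifest points at, in manifest order."""
    root = Path(root)
    out = []
    for path in manifest["path"]:
        with Image.open(root / path) as im:
            out.append(np.asarray(im.convert("RGB")))
    return out


def _as_arrays(
    data: list[ImageSample] | pd.DataFrame,
    root,
    class_names: tuple[str, ...],
    input_size: tuple[int, int],
    dtype,
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        images = load_manifest_images(data, root)
        labels = list(data["label"])
    else:
        images = [s.pixels for s in data]
        labels = [s.label for s in data]
    unknown = set(labels) - set(class_names)
    if unknown:
        raise ValueError(f"labels not in class list: {sorted(unknown)}")
    x = preprocess_images(images, input_size, dtype=dtype)
    y = np.array([class_names.index(l) for l in labels], dtype=int)
    return x, y


def train(
    model_config: ArchitectureConfig,
    train_data: list[ImageSample] | pd.DataFrame,
    config: TrainConfig,
    root=None,
    class_names: tuple[str, ...] = CLASS_NAMES,
    model: Layer | None = None,
    epoch_callback=None,
) -> tuple[Layer, TrainHistory]:
    """Train the spatial-attention CNN (or a caller-supplied model).

    Parameters
    ----------
    train_data
        Either in-memory :class:`ImageSample` objects or a manifest
        DataFrame (with ``root`` pointing at the image directory).
    config
        Optimization settings; ``config.seed`` drives weight initialization
        and per-epoch shuffling.
    model
        Optional pre-built model (used for the comparison architectures);
        defaults to a freshly initialized :class:`AttentionResNet`.
    epoch_callback
        Optional ``f(epoch, model)`` hook run after each epoch (used by the
        attention-stability probe).

    Returns the trained model and the per-epoch :class:`TrainHistory`.
    Aborts with a diagnostic if the loss goes non-finite.
    """
    if (isinstance(train_data, pd.DataFrame) and train_data.empty) or len(train_data) == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = AttentionResNet(model_config, rng=rng)
    x, y = _as_arrays(train_data, root, class_names, model_config.input_size, np.float32)
    n = x.shape[0]
    optimizer = Adam(model, betas=config.adam_betas, eps=config.adam_eps)
    history = TrainHistory()
    for epoch in range(config.epochs):
        lr = lr_at_epoch(epoch, config)
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            model.zero_grads()
            scores = model.forward(xb, training=True)
            probs = softmax(scores, axis=-1)
            picked = np.maximum(probs[np.arange(len(idx)), yb], 1e-12)
            loss = float(-np.mean(np.log(picked)))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss!r}; check learning rate and inputs"
                )
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(idx)), yb] = 1.0
            model.backward((probs - onehot) / len(idx))
            optimizer.step(lr)
            losses.append(loss)
            correct += int((scores.argmax(axis=1) == yb).sum())
        history.loss.append(float(np.mean(losses)))
        history.lr.append(lr)
        history.accuracy.append(correct / n)
        logger.info("epoch %d: loss=%.4f lr=%.2e acc=%.3f", epoch, history.loss[-1], lr, history.accuracy[-1])
        if epoch_callback is not None:
            epoch_callback(epoch, model)
    return model, history
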