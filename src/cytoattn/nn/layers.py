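"""Trainable layers with explicit forward and backward passes.

The network code in this package is a small self-contained NumPy framework:
each layer owns its parameters and gradients in plain dicts, caches what it
needs during ``forward`` and returns the input gradient from ``backward``.
Feature maps follow the ``(batch, channels, rows, cols)`` convention.

Convolutions are evaluated as matrix products over im2col patch matrices so
that the heavy lifting goes through BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: parameter/gradient bookkeeping plus the pass protocol."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}  # non-trainable state, e.g. BN running moments

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def children(self):
        return ()

    def zero_grads(self) -> None:
        for key, p in self.params.items():
            self.grads[key] = np.zeros_like(p)
        for child in self.children():
            child.zero_grads()

    def named_parameters(self, prefix: str = ""):
        """Yield ``(name, layer, key)`` triples in a stable order."""
        for key in self.params:
            yield f"{prefix}{key}", self, key
        for i, child in enumerate(self.children()):
            yield from child.named_parameters(f"{prefix}{type(child).__name__.lower()}{i}.")

    def named_buffers(self, prefix: str = ""):
        for key in self.buffers:
            yield f"{prefix}{key}", self, key
        for i, child in enumerate(self.children()):
            yield from child.named_buffers(f"{prefix}{type(child).__name__.lower()}{i}.")


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Extract patches from a padded input.

    Returns an array of shape ``(N, C, out_h, out_w, kh, kw)`` that is a view
    when ``stride == 1`` and a strided view otherwise.
    """
    windows = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return windows[:, :, ::stride, ::stride]


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with 'same'-style zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int | None = None,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.params = {
            "w": rng.normal(0.0, scale, (out_channels, in_channels, kernel_size, kernel_size)).astype(dtype),
            "b": np.zeros(out_channels, dtype=dtype),
        }
        self.zero_grads()
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"Conv2d expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, k, k, s)  # (N, C, oh, ow, k, k)
        n, c, oh, ow = cols.shape[:4]
        flat = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        wf = self.params["w"].reshape(self.out_channels, -1)
        out = flat @ wf.T + self.params["b"]
        if training:
            self._cache = (flat, x.shape, xp.shape, oh, ow)
        return out.reshape(n, oh, ow, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        flat, x_shape, xp_shape, oh, ow = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        n = x_shape[0]
        dflat_out = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_channels)
        wf = self.params["w"].reshape(self.out_channels, -1)
        self.grads["w"] += (dflat_out.T @ flat).reshape(self.params["w"].shape)
        self.grads["b"] += dflat_out.sum(axis=0)
        dcols = (dflat_out @ wf).reshape(n, oh, ow, x_shape[1], k, k)
        dxp = np.zeros(xp_shape, dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    Training mode normalizes with batch moments and updates exponential
    running estimates; inference mode uses the running estimates, making the
    forward pass deterministic sample-by-sample.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32) -> None:
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.buffers = {
            "running_mean": np.zeros(channels, dtype=dtype),
            "running_var": np.ones(channels, dtype=dtype),
        }
        self.zero_grads()
        self._cache: tuple | None = None

    @property
    def running_mean(self) -> np.ndarray:
        return self.buffers["running_mean"]

    @property
    def running_var(self) -> np.ndarray:
        return self.buffers["running_var"]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            rm, rv = self.buffers["running_mean"], self.buffers["running_var"]
            rm *= 1 - m
            rm += m * mean.astype(rm.dtype)
            rv *= 1 - m
            rv += m * var.astype(rv.dtype)
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
            self._cache = (xhat, invstd)
            return g * xhat + b
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * invstd[None, :, None, None]
        return g * xhat + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.params["gamma"][None, :, None, None]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd[None, :, None, None] / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(0.0, x)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class GlobalAvgPool(Layer):
    """Average pooling over the full spatial extent; output ``(N, C)``."""

    def __init__(self) -> None:
        super().__init__()
        self._spatial: tuple[int, int] | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._spatial = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._spatial
        return np.broadcast_to(dout[:, :, None, None], dout.shape + (h, w)).copy() / (h * w)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.params = {
            "w": rng.normal(0.0, scale, (out_features, in_features)).astype(dtype),
            "b": np.zeros(out_features, dtype=dtype),
        }
        self.zero_grads()
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["w"] += dout.T @ self._x
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["w"]
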