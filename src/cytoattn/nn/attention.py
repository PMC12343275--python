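"""Attention modules: the spatial attention gate and a QKV self-attention block.

The spatial attention module compresses a multi-channel feature map X into a
single-channel map M with one convolution, squashes it through a sigmoid to
the attention map A in (0, 1), and rescales every channel of X by A:

    Y[k, i, j] = X[k, i, j] * A[i, j]

so positions with A near 1 are emphasised and positions near 0 suppressed.
The self-attention block is the comparison-model variant: attention weights
over spatial positions from query/key dot products, applied to values and
added back to the input as a residual.
"""

from __future__ import annotations

import numpy as np

from .functional import sigmoid, softmax
from .layers import Conv2d, Layer


class SpatialAttention(Layer):
    """Single-channel convolutional attention gate.

    Parameters
    ----------
    in_channels
        Channel count of the incoming feature map.
    kernel_size
        Spatial extent of the compressing convolution; 1 collapses channels
        pointwise, odd sizes > 1 also mix a local neighbourhood.
    """

    def __init__(self, in_channels: int, kernel_size: int = 1, rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("attention kernel size must be odd")
        self.conv = Conv2d(in_channels, 1, kernel_size, rng=rng, dtype=dtype)
        self._cache: tuple | None = None
        self.last_attention: np.ndarray | None = None

    def children(self):
        return (self.conv,)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        m = self.conv.forward(x, training=training)  # (N, 1, H, W)
        a = sigmoid(m)
        self.last_attention = a[:, 0]
        if training:
            self._cache = (x, a)
        return x * a

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, a = self._cache
        dx = dout * a
        da = (dout * x).sum(axis=1, keepdims=True)
        dm = da * a * (1.0 - a)
        dx += self.conv.backward(dm)
        return dx


class SelfAttentionBlock(Layer):
    """Residual QKV self-attention over spatial positions.

    Queries, keys and values are 1x1 convolutions of the input. With the
    feature map flattened to ``d x (H*W)``, attention weights are a softmax
    over key positions of the scaled query-key dot products, the weighted
    values are reshaped back to the map and added to the input, so zero value
    weights make the block an exact identity.
    """

    def __init__(self, channels: int, qk_channels: int | None = None, rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        dk = qk_channels or max(1, channels // 4)
        self.q = Conv2d(channels, dk, 1, rng=rng, dtype=dtype)
        self.k = Conv2d(channels, dk, 1, rng=rng, dtype=dtype)
        self.v = Conv2d(channels, channels, 1, rng=rng, dtype=dtype)
        self.scale = 1.0 / np.sqrt(dk)
        self._cache: tuple | None = None

    def children(self):
        return (self.q, self.k, self.v)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        p = h * w
        q = self.q.forward(x, training=training).reshape(n, -1, p)
        k = self.k.forward(x, training=training).reshape(n, -1, p)
        v = self.v.forward(x, training=training).reshape(n, c, p)
        # attn[b, i, j]: weight of position j when aggregating for position i
        scores = np.einsum("bdi,bdj->bij", q, k) * self.scale
        attn = softmax(scores, axis=-1)
        weighted = np.einsum("bcj,bij->bci", v, attn)
        if training:
            self._cache = (q, k, v, attn, x.shape)
        return x + weighted.reshape(n, c, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        q, k, v, attn, x_shape = self._cache
        n, c, h, w = x_shape
        p = h * w
        dw = dout.reshape(n, c, p)  # gradient of the weighted-value term
        dv = np.einsum("bci,bij->bcj", dw, attn)
        dattn = np.einsum("bci,bcj->bij", dw, v)
        # softmax Jacobian along the key axis
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores *= self.scale
        dq = np.einsum("bij,bdj->bdi", dscores, k)
        dk = np.einsum("bij,bdi->bdj", dscores, q)
        dx = dout.copy()
        dx += self.q.backward(dq.reshape(n, -1, h, w))
        dx += self.k.backward(dk.reshape(n, -1, h, w))
        dx += self.v.backward(dv.reshape(n, c, h, w))
        return dx
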