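"""Residual building block: conv-BN-ReLU-conv-BN plus an additive shortcut.

The shortcut is the identity when shapes allow it and a 1x1 strided
projection (with its own batch norm) when the channel count or stride
changes, preserving the block's ability to learn the identity mapping.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm2d, Conv2d, Layer, ReLU


class ResidualBlock(Layer):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride=stride, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(out_channels, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(out_channels, dtype=dtype)
        self.relu_out = ReLU()
        if stride != 1 or in_channels != out_channels:
            self.proj: Conv2d | None = Conv2d(in_channels, out_channels, 1, stride=stride, padding=0, rng=rng, dtype=dtype)
            self.proj_bn: BatchNorm2d | None = BatchNorm2d(out_channels, dtype=dtype)
        else:
            self.proj = None
            self.proj_bn = None

    def children(self):
        kids = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu_out]
        if self.proj is not None:
            kids += [self.proj, self.proj_bn]
        return tuple(kids)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = self.conv1.forward(x, training=training)
        out = self.bn1.forward(out, training=training)
        out = self.relu1.forward(out, training=training)
        out = self.conv2.forward(out, training=training)
        out = self.bn2.forward(out, training=training)
        if self.proj is not None:
            shortcut = self.proj_bn.forward(self.proj.forward(x, training=training), training=training)
        else:
            shortcut = x
        if shortcut.shape != out.shape:
            raise ValueError(
                f"shortcut shape {shortcut.shape} does not match main path {out.shape}"
            )
        return self.relu_out.forward(out + shortcut, training=training)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dout)
        if self.proj is not None:
            dx = self.proj.backward(self.proj_bn.backward(dsum))
        else:
            dx = dsum
        d = self.bn2.backward(dsum)
        d = self.conv2.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        dx = dx + self.conv1.backward(d)
        return dx
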