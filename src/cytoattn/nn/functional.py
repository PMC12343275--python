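"""Elementwise activations and classification losses.

All functions operate on plain :class:`numpy.ndarray` inputs of any shape
unless stated otherwise and are pure (no state, no in-place mutation).
"""

from __future__ import annotations

import numpy as np

__all__ = ["relu", "sigmoid", "softmax", "cross_entropy"]

#: Floor applied to probabilities inside the log of the cross entropy so a
#: predicted probability of exactly zero at the true class yields a large but
#: finite loss instead of an infinity.
CROSS_ENTROPY_EPS = 1e-12


def relu(x: np.ndarray) -> np.ndarray:
    """Rectified linear unit, ``f(x) = max(0, x)`` elementwise."""
    return np.maximum(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function mapping reals into (0, 1)."""
    out = np.empty_like(x, dtype=np.result_type(x, np.float32))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax along ``axis``; rows sum to one up to floating-point error."""
    shifted = scores - np.max(scores, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def cross_entropy(probabilities: np.ndarray, true_label: int | np.ndarray) -> float:
    """Negative log-probability of the true class.

    Parameters
    ----------
    probabilities
        Either a single probability vector or a ``(batch, classes)`` matrix
        whose rows lie on the simplex.
    true_label
        Integer class index, or an integer array of per-row indices for the
        batched form. The batched form returns the mean loss.

    Probabilities are floored at ``CROSS_ENTROPY_EPS`` before the log so a
    degenerate zero at the true class stays finite.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim == 1:
        picked = p[int(true_label)]
        return float(-np.log(max(picked, CROSS_ENTROPY_EPS)))
    idx = np.asarray(true_label, dtype=int)
    picked = p[np.arange(p.shape[0]), idx]
    return float(np.mean(-np.log(np.maximum(picked, CROSS_ENTROPY_EPS))))
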