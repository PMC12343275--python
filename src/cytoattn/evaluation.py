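"""Statistical evaluation: confusion matrix, Wilson CIs, per-class metrics, ROC.

Every binomial proportion (per-class precision and recall, overall
accuracy) is reported with a 95% Wilson score interval

    center = (p + z^2/2n) / (1 + z^2/n)
    half   = z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n)

with ``z`` the exact normal quantile for the requested confidence, clipped
to [0, 1]. F1 is reported as a point value only. ROC curves are one-vs-rest
over class probabilities with tied scores grouped, and AUC is the
trapezoidal area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "ConfusionMatrix",
    "MetricWithCI",
    "EvalReport",
    "confusion_matrix",
    "wilson_interval",
    "precision_recall_f1",
    "roc_ovr",
    "evaluate",
    "evaluate_predictions",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 3) -> float:
    """Round to ``decimals`` places with ties going up, as in printed tables."""
    if x == 0:
        return 0.0
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (C, C) ints, rows = true class, cols = predicted
    class_names: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)


@dataclass(frozen=True)
class MetricWithCI:
    """A binomial proportion k/n with its Wilson confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    k: int
    n: int
    undefined: bool = False  # flagged when the denominator was zero

    def as_tuple(self) -> tuple[float, float, float]:
        return self.point, self.ci_low, self.ci_high


@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    precision: dict[str, MetricWithCI]
    recall: dict[str, MetricWithCI]
    f1: dict[str, float]
    overall_accuracy: MetricWithCI
    roc: dict[str, dict] = field(default_factory=dict)  # class -> {fpr, tpr, auc}

    def to_dict(self) -> dict:
        def metric(m: MetricWithCI) -> dict:
            return {
                "point": round_half_up(m.point),
                "ci_low": round_half_up(m.ci_low),
                "ci_high": round_half_up(m.ci_high),
                "k": m.k,
                "n": m.n,
                "undefined": m.undefined,
            }

        return {
            "class_names": list(self.confusion.class_names),
            "confusion": self.confusion.counts.tolist(),
            "precision": {c: metric(m) for c, m in self.precision.items()},
            "recall": {c: metric(m) for c, m in self.recall.items()},
            "f1": {c: round_half_up(v) for c, v in self.f1.items()},
            "overall_accuracy": metric(self.overall_accuracy),
            "roc": {
                c: {"fpr": list(map(float, r["fpr"])), "tpr": list(map(float, r["tpr"])),
                    "auc": (None if r["auc"] is None else float(r["auc"]))}
                for c, r in self.roc.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def confusion_matrix(true_labels, predicted_labels, class_names) -> ConfusionMatrix:
    """Count matrix with rows = true classes, columns = predictions."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for ``k`` successes in ``n`` trials."""
    if n < 1:
        raise ValueError("wilson_interval requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    z = float(norm.ppf(0.5 + confidence / 2.0))
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def _proportion(k: int, n: int, confidence: float) -> MetricWithCI:
    if n == 0:
        return MetricWithCI(point=0.0, ci_low=0.0, ci_high=1.0, k=0, n=0, undefined=True)
    low, high = wilson_interval(k, n, confidence)
    return MetricWithCI(point=k / n, ci_low=low, ci_high=high, k=int(k), n=int(n))


def precision_recall_f1(
    cm: ConfusionMatrix, confidence: float = 0.95
) -> tuple[dict[str, MetricWithCI], dict[str, MetricWithCI], dict[str, float]]:
    """Per-class precision and recall with Wilson CIs, plus point F1.

    A zero denominator (class never predicted, or absent from the truth)
    yields a flagged 0.0 metric; a zero precision+recall pair yields F1 0.0,
    the convention the comparison tables use for a class the model never
    gets right.
    """
    counts = cm.counts
    precision: dict[str, MetricWithCI] = {}
    recall: dict[str, MetricWithCI] = {}
    f1: dict[str, float] = {}
    for i, name in enumerate(cm.class_names):
        tp = int(counts[i, i])
        precision[name] = _proportion(tp, int(counts[:, i].sum()), confidence)
        recall[name] = _proportion(tp, int(counts[i, :].sum()), confidence)
        p, r = precision[name].point, recall[name].point
        f1[name] = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return precision, recall, f1


def roc_ovr(true_labels, probabilities: np.ndarray, class_index: int) -> tuple[np.ndarray, np.ndarray, float | None]:
    """One-vs-rest ROC for one class over its predicted probability.

    ``true_labels`` are integer class indices; ``probabilities`` is the
    ``(N, C)`` matrix of class probabilities. Returns ``(fpr, tpr, auc)``
    with tied scores grouped into single operating points and the curve
    anchored at (0,0) and (1,1). If the class has no positives or no
    negatives the AUC is undefined and returned as None.
    """
    y = np.asarray(true_labels) == class_index
    scores = np.asarray(probabilities)[:, class_index]
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    # group ties: keep only the last index of each distinct score
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    if n_pos == 0 or n_neg == 0:
        fpr = np.r_[0.0, fp / max(n_neg, 1)]
        tpr = np.r_[0.0, tp / max(n_pos, 1)]
        return fpr, tpr, None
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def evaluate_predictions(
    true_labels,
    predicted_labels,
    class_names,
    probabilities: np.ndarray | None = None,
    confidence: float = 0.95,
) -> EvalReport:
    """Assemble an :class:`EvalReport` from labels (and optional probabilities)."""
    cm = confusion_matrix(true_labels, predicted_labels, class_names)
    precision, recall, f1 = precision_recall_f1(cm, confidence)
    overall = _proportion(int(np.trace(cm.counts)), cm.total, confidence)
    report = EvalReport(confusion=cm, precision=precision, recall=recall, f1=f1, overall_accuracy=overall)
    if probabilities is not None:
        index = {c: i for i, c in enumerate(class_names)}
        yidx = np.array([index[t] for t in true_labels])
        for i, name in enumerate(class_names):
            fpr, tpr, auc = roc_ovr(yidx, probabilities, i)
            report.roc[name] = {"fpr": fpr, "tpr": tpr, "auc": auc}
    return report


def evaluate(model, samples, class_names, input_size, batch_size: int = 64) -> EvalReport:
    """Run a trained model over a test set and assemble the full report."""
    from .nn import softmax
    from .training import preprocess_images

    if len(samples) == 0:
        raise ValueError("test set is empty")
    x = preprocess_images([s.pixels for s in samples], input_size)
    probs = []
    for start in range(0, x.shape[0], batch_size):
        scores = model.forward(x[start : start + batch_size], training=False)
        probs.append(softmax(scores, axis=-1))
    probabilities = np.vstack(probs)
    predicted = [class_names[i] for i in probabilities.argmax(axis=1)]
    true_labels = [s.label for s in samples]
    return evaluate_predictions(true_labels, predicted, class_names, probabilities)
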