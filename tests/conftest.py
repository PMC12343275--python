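"""Shared fixtures: small in-memory datasets and the full training run.

The reduced-scale study dataset (class sizes 200/98/58/38/12, preserving
the 509:98:58:38:12 imbalance shape at a tractable size for the majority
class) is generated, split 50/50 and trained twice with the same seed at
session scope so several end-to-end assertions can share the cost.
"""

from __future__ import annotations

import numpy as np
import pytest

from cytoattn import (
    ArchitectureConfig,
    CLASS_NAMES,
    DatasetSpec,
    TrainConfig,
    evaluate,
    generate_dataset,
    stratified_split,
    train,
)

REDUCED_COUNTS = {
    "PML-RARA": 200,
    "TTMV-RARA": 98,
    "NPM1-RARA": 58,
    "STAT5B-RARA": 38,
    "NUP98-RARG": 12,
}


@pytest.fixture(scope="session")
def small_dataset():
    """60 images (12 per class) at generator resolution, with manifest."""
    spec = DatasetSpec(
        per_class_counts={c: 12 for c in CLASS_NAMES},
        image_size=(64, 64),
        master_seed=11,
    )
    samples, manifest = generate_dataset(spec)
    return samples, manifest


@pytest.fixture(scope="session")
def e2e_run():
    """Reduced-scale study pipeline: generate, split, train twice, evaluate."""
    spec = DatasetSpec(per_class_counts=dict(REDUCED_COUNTS), image_size=(128, 128), master_seed=0)
    samples, manifest = generate_dataset(spec)
    train_m, test_m = stratified_split(manifest, 0.5, seed=0)
    train_samples = [samples[i] for i in train_m.index]
    test_samples = [samples[i] for i in test_m.index]
    arch = ArchitectureConfig(input_size=(64, 64))
    tc = TrainConfig(epochs=30, seed=0)
    model, history = train(arch, train_samples, tc)
    _, history_repeat = train(arch, train_samples, tc)
    report = evaluate(model, test_samples, CLASS_NAMES, arch.input_size)
    return {
        "arch": arch,
        "train_config": tc,
        "model": model,
        "history": history,
        "history_repeat": history_repeat,
        "report": report,
        "test_samples": test_samples,
        "test_counts": test_m["label"].value_counts().to_dict(),
    }
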