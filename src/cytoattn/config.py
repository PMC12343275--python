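"""Run configuration: a validated YAML-backed bundle of all pipeline settings."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import ArchitectureConfig
from .training import TrainConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, resolvable from one YAML file."""

    data_dir: str = "data"
    output_dir: str = "runs"
    architecture: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    eval_batch_size: int = 64
    overlay_alpha: float = 0.4
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlay_alpha <= 1.0:
            raise ValueError("overlay_alpha must lie in [0, 1]")
        if self.eval_batch_size < 1:
            raise ValueError("eval_batch_size must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["architecture"] = self.architecture.to_dict()
        d["training"] = asdict(self.training)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "architecture" in d:
            d["architecture"] = ArchitectureConfig.from_dict(d["architecture"])
        if "training" in d:
            tc = dict(d["training"])
            if "adam_betas" in tc:
                tc["adam_betas"] = tuple(tc["adam_betas"])
            d["training"] = TrainConfig(**tc)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def write_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
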