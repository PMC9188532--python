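"""Run configuration: one serializable object that reproduces a run."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentationConfig
from .phantom import PhantomConfig
from .training import TrainConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; round-trips through YAML."""

    district: str = "thigh"
    data_dir: str = "data"
    checkpoint_dir: str = "checkpoints"
    report_dir: str = "reports"
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    width_multiplier: float = 1.0
    image_size: int = 432
    classifier_size: int = 128
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        # derived phantom fields are reconstructed by __post_init__
        d["phantom"].pop("muscles_per_side", None)
        d["phantom"].pop("bones_per_side", None)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["phantom"] = PhantomConfig(**d.get("phantom", {}))
        aug = d.get("augmentation", {})
        for key in ("rotation_range", "pw_affine_scale_range",
                    "elastic_strength_range", "elastic_kernel_sd_range"):
            if key in aug and isinstance(aug[key], list):
                aug[key] = tuple(aug[key])
        d["augmentation"] = AugmentationConfig(**aug)
        d["train"] = TrainConfig(**d.get("train", {}))
        return cls(**d)
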