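"""Run configuration: one serializable YAML document drives a whole run.

Defaults reproduce the study conditions (512 x 512 slices, 161 x 184
ROI, 224 x 256 patches, Adam 1e-3, 2000 epochs, dropout 0.3, 80/20
split, alpha 0.05). ``RunConfig.reduced()`` is the desk-scale preset
used for fast end-to-end runs: smaller slices and patches, shallower
nets, fewer epochs — same code path throughout.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

STRATA = ("normal", "displaced", "both")
DEFAULT_FAMILIES = ("threediscnet", "unet", "segnet_basic")


@dataclass
class CohortConfig:
    n_patients: int = 10
    n_controls: int = 10
    slices_per_subject: tuple[int, int] = (4, 7)
    image_size: tuple[int, int] = (512, 512)


@dataclass
class ModelConfig:
    families: tuple[str, ...] = DEFAULT_FAMILIES
    input_size: tuple[int, int] = (224, 256)
    depth: int = 4
    base_filters: int = 64
    kernel_size: int = 3
    dropout_rate: float = 0.3


@dataclass
class TrainSection:
    learning_rate: float = 1e-3
    epochs: int = 2000
    batch_size: int = 8
    loss: str = "bce"


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    data_dir: str | None = None  # existing cohort manifest dir; None -> generate
    cohort: CohortConfig = field(default_factory=CohortConfig)
    roi: dict | None = None  # None -> centered default box; else origin/height/width
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainSection = field(default_factory=TrainSection)
    split_fraction: float = 0.8
    strata: tuple[str, ...] = STRATA
    eval_threshold: float = 0.5
    alpha: float = 0.05
    figures: bool = False

    @classmethod
    def reduced(cls, seed: int = 0, **overrides) -> "RunConfig":
        """Desk-scale preset: 128 px slices, 64 x 64 patches, shallow nets."""
        cfg = cls(
            seed=seed,
            cohort=CohortConfig(image_size=(128, 128)),
            model=ModelConfig(input_size=(64, 64), depth=2, base_filters=8),
            train=TrainSection(epochs=60),
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("cohort", CohortConfig), ("model", ModelConfig),
                         ("train", TrainSection)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**_tuplify(d[key]))
        d = _tuplify(d)
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _tuplify(d: dict) -> dict:
    """YAML round-trips tuples as lists; restore tuples for list values."""
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
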