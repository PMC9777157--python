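"""Experiment configuration: nested dataclasses + YAML/JSON loading.

Defaults equal the published hyperparameters (CLAHE 5.0/(8,8), 80/20 split
with 10% validation carve-out, Adam 0.001/0.9/0.999, batch 256, 50 base /
20 fine-tune epochs, PCA 0.99, SVM C=1000 gamma=0.001), so a run with no
overrides is the published recipe at phantom scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class PhantomConfig:
    n_per_grade: tuple[int, ...] = (50, 50, 50, 50, 50)
    noise_sd: float = 8.0
    image_size: tuple[int, int] = (224, 224)


@dataclass
class PreprocSection:
    target_size: tuple[int, int] = (112, 112)
    clahe_clip_limit: float = 5.0
    clahe_tile_grid: tuple[int, int] = (8, 8)


@dataclass
class SplitSection:
    test_fraction: float = 0.20
    valid_fraction_of_train: float = 0.10
    stratified: bool = True


@dataclass
class TrainSection:
    epochs: int = 50
    tl_epochs: int = 20
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 256
    chunk_size: int = 16


@dataclass
class DHLSection:
    variance_target: float = 0.99
    C: float = 1000.0
    gamma: float = 0.001


@dataclass
class ExperimentConfig:
    seed: int = 0
    schemes: tuple[str, ...] = ("FOUR", "THREE", "TWO")
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocSection = field(default_factory=PreprocSection)
    split: SplitSection = field(default_factory=SplitSection)
    train: TrainSection = field(default_factory=TrainSection)
    dhl: DHLSection = field(default_factory=DHLSection)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data or {})
        sections = {
            "phantom": PhantomConfig,
            "preprocess": PreprocSection,
            "split": SplitSection,
            "train": TrainSection,
            "dhl": DHLSection,
        }
        kwargs = {}
        for key, klass in sections.items():
            sub = data.pop(key, {})
            if not isinstance(sub, dict):
                raise ConfigurationError(f"config section {key!r} must be a mapping")
            try:
                obj = klass(**sub)
            except TypeError as exc:
                raise ConfigurationError(f"bad config section {key!r}: {exc}") from exc
            for tup_field in ("n_per_grade", "image_size", "target_size",
                              "clahe_tile_grid"):
                if hasattr(obj, tup_field):
                    setattr(obj, tup_field, tuple(getattr(obj, tup_field)))
            kwargs[key] = obj
        if "schemes" in data:
            kwargs["schemes"] = tuple(str(s).upper() for s in data.pop("schemes"))
        if "seed" in data:
            kwargs["seed"] = int(data.pop("seed"))
        if data:
            raise ConfigurationError(f"unknown config keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh)  # JSON is a YAML subset
        return cls.from_dict(data or {})
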