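"""Experiment configuration: schema, defaults, validation, hashing.

Defaults reproduce the framework's stated operating point: 25 Hz low-pass,
T = 1084 steps, tremor sigma in [0.01, 0.05], 150 synthetic samples per
class, 5 evaluation folds with an 80/20 real train/test split, the fixed
baseline grids and the fixed hybrid architecture.  Unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import List, Optional, Union

import yaml


def _build(cls, data: dict, context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SimulateConfig:
    n_real_per_class: int = 50       # synthetic stand-in for the real cohort
    n_synthetic_per_class: int = 150
    task_mix: List[float] = field(default_factory=lambda: [1 / 3, 1 / 3, 1 / 3])
    noise_floor: List[float] = field(default_factory=lambda: [0.005, 0.5])
    mean_duration: float = 12.0


@dataclass
class PreprocessConfig:
    cutoff_hz: float = 25.0
    filter_order: int = 4
    rest_window: float = 0.5


@dataclass
class FeatureConfig:
    T: int = 1084
    detrend_window: Optional[float] = 2.0


@dataclass
class AugmentConfig:
    sigma_range: List[float] = field(default_factory=lambda: [0.01, 0.05])
    n_knots: int = 8
    ad_knot_jitter: float = 0.2
    cn_knot_jitter: float = 0.05


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1


@dataclass
class EvaluateConfig:
    n_folds: int = 5
    threshold: float = 0.5
    models: List[str] = field(default_factory=lambda: ["hybrid", "LR", "SVM", "RF", "kNN"])


@dataclass
class ExperimentConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    train: TrainingConfig = field(default_factory=TrainingConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data or {})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sections = {
            "simulate": SimulateConfig, "preprocess": PreprocessConfig,
            "features": FeatureConfig, "augment": AugmentConfig,
            "train": TrainingConfig, "evaluate": EvaluateConfig,
        }
        kwargs = {"seed": int(data.get("seed", 0))}
        for name, section_cls in sections.items():
            kwargs[name] = _build(section_cls, dict(data.get(name, {})), name)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration (for artifact stamps)."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
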