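"""Experiment configuration: YAML-backed, schema-validated, defaults filled.

Validation collects *all* offending fields before raising, so a bad config
reports every problem at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .phantom import SITE_CODES

__all__ = ["ExperimentConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration: " + "; ".join(problems))


@dataclass
class ExperimentConfig:
    # phantom
    severity: float = 1.0
    image_size: int = 512
    n_subjects: int = 27
    frames_per_subject: int = 40      # per site and label (B); captures for M
    base_seed: int = 0
    sites: list[str] = field(default_factory=lambda: list(SITE_CODES))
    # stages
    stage1: bool = True
    stage2: bool = True
    loso: bool = True
    explain: bool = True
    # budgets / scale
    scale: float = 1.0                # multiplies all sample budgets
    stage2_budget: int = 100
    loso_k: int = 5
    max_epochs: int = 100
    patience: int = 5
    mmode_sections: int = 25
    dropout_default: float = 0.5
    output_root: str = "runs"
    # None = full 54-run grid; otherwise parameter -> subset of values
    stage1_values: dict | None = None
    # user-supplied Stage-1 selection when stage1 is disabled
    train_config: dict | None = None
    architectures: list[str] = field(default_factory=lambda: [
        "simple_cnn", "optimized", "ShrapML", "MobileNetV2", "DarkNet53"])

    def validate(self) -> None:
        problems = []
        if not 0.0 <= self.severity <= 1.0:
            problems.append(f"severity must be in [0,1], got {self.severity}")
        if self.image_size < 8:
            problems.append(f"image_size must be >= 8, got {self.image_size}")
        if self.n_subjects < 0:
            problems.append("n_subjects must be non-negative")
        if self.frames_per_subject < 0:
            problems.append("frames_per_subject must be non-negative")
        bad = [s for s in self.sites if s not in SITE_CODES]
        if bad:
            problems.append(f"unknown sites {bad}; valid: {list(SITE_CODES)}")
        if self.scale <= 0:
            problems.append("scale must be positive")
        if self.stage2_budget < 1:
            problems.append("stage2_budget must be >= 1")
        if self.loso_k < 2:
            problems.append("loso_k must be >= 2")
        if self.max_epochs < 1:
            problems.append("max_epochs must be >= 1")
        if self.patience < 1:
            problems.append("patience must be >= 1")
        if not 0.1 <= self.dropout_default <= 0.9:
            problems.append(
                f"dropout_default must be in [0.1, 0.9], got {self.dropout_default}")
        if self.stage1_values is not None:
            from .stage1 import _CHOICES
            for name, vals in self.stage1_values.items():
                if name not in _CHOICES:
                    problems.append(f"stage1_values: unknown parameter {name!r}")
                else:
                    bad = [v for v in vals if v not in _CHOICES[name]]
                    if bad:
                        problems.append(
                            f"stage1_values.{name}: invalid values {bad}")
        known_arch = {"simple_cnn", "optimized", "ShrapML", "MobileNetV2",
                      "DarkNet53"}
        bad_arch = [a for a in self.architectures if a not in known_arch]
        if bad_arch:
            problems.append(f"unknown architectures {bad_arch}")
        if problems:
            raise ConfigError(problems)

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML experiment config; unknown keys rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    known = {f for f in ExperimentConfig.__dataclass_fields__}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError([f"unknown field {u!r}" for u in unknown])
    cfg = ExperimentConfig(**raw)
    cfg.validate()
    return cfg
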