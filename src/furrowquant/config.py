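"""Pipeline configuration: YAML/JSON loading and validation."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .io import config_digest

__all__ = ["ConfigError", "PipelineConfig", "load_config"]


class ConfigError(ValueError):
    """A configuration field is missing or invalid (named in the message)."""


_REQUIRED_POSITIVE = ("pixel_size", "dz", "frame_interval")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Per-stage parameter blocks are free-form mappings consumed by the
    corresponding modules; calibration fields are required and must be
    positive.
    """

    pixel_size: float
    dz: float
    frame_interval: float
    seed: int = 0
    tissue: dict = field(default_factory=dict)
    myosin: dict = field(default_factory=dict)
    rings: dict = field(default_factory=dict)
    pulses: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in _REQUIRED_POSITIVE:
            value = getattr(self, name)
            if value is None:
                raise ConfigError(f"missing required field: {name}")
            if not isinstance(value, (int, float)) or value <= 0:
                raise ConfigError(f"field {name} must be a positive number")

    def digest(self) -> str:
        return config_digest(asdict(self))

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON pipeline configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    raw: Mapping[str, Any]
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigError("config file must contain a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    missing = [f for f in _REQUIRED_POSITIVE if f not in raw]
    if missing:
        raise ConfigError(f"missing required field: {missing[0]}")
    return PipelineConfig(**raw)
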