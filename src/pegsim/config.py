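"""Run configuration: defaults, YAML overrides, strict validation.

A config file is a YAML mapping with optional sections ``physics``,
``noise``, ``pipeline``, ``stats`` and a top-level ``seed``.  Every field
has a default; unknown keys are rejected by name so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .breath_simulator import NoiseParams
from .errors import ConfigError
from .sensor_physics import PhysicsParams

__all__ = ["PipelineConfig", "StatsConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    window_points: int = 1000
    hi: float = 0.90
    lo: float = 0.20
    skip_after_peak_s: float = 30.0
    baseline_s: float = 120.0


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    lod_sd_multiplier: float = 3.0


@dataclass(frozen=True)
class RunConfig:
    physics: PhysicsParams = PhysicsParams()
    noise: NoiseParams = NoiseParams()
    pipeline: PipelineConfig = PipelineConfig()
    stats: StatsConfig = StatsConfig()
    seed: int = 0


_SECTIONS = {
    "physics": PhysicsParams,
    "noise": NoiseParams,
    "pipeline": PipelineConfig,
    "stats": StatsConfig,
}


def _build_section(cls, overrides: dict, section: str):
    valid = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in overrides.items():
        if key not in valid:
            raise ConfigError(f"unknown key {section}.{key!r}")
        expected = valid[key].type
        if expected in ("float", "int") and not isinstance(value, (int, float)):
            raise ConfigError(
                f"{section}.{key}: expected a number, got {type(value).__name__}"
            )
    try:
        return cls(**overrides)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a config file, merging overrides onto defaults.

    ``None`` or an empty file yields all defaults.  Unknown keys and type
    mismatches raise :class:`ConfigError` naming the offending key.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    kwargs = {}
    for key, value in data.items():
        if key == "seed":
            if not isinstance(value, int):
                raise ConfigError(f"seed: expected an integer, got {type(value).__name__}")
            kwargs["seed"] = value
        elif key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        else:
            raise ConfigError(f"unknown key {key!r}")
    return RunConfig(**kwargs)
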