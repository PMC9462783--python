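"""Pipeline configuration: typed sections, YAML loading, strict validation.

Unknown keys are rejected by name rather than silently ignored — a typo
in a Wiener constant should fail loudly, not reconstruct with defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .errors import ConfigError
from .reconstruction import ReconstructionConfig


@dataclass(frozen=True)
class OpticsConfig:
    na: float = 1.4
    wavelength_nm: float = 520.0
    pixel_nm: float = 45.0
    otf_path: str | None = None


@dataclass(frozen=True)
class IlluminationConfig:
    orientations_deg: tuple[float, float, float] = (0.0, 60.0, 120.0)
    phases_deg: tuple[float, float, float] = (0.0, 120.0, 240.0)
    period_px: int = 6
    duty_on_px: int = 3
    m: float = 0.8
    ktheta_frac: float = 0.8


@dataclass(frozen=True)
class PreprocessConfig:
    enabled: bool = True
    reference_index: int = 0
    median_window: int = 3


@dataclass(frozen=True)
class EstimationSection:
    r_inner_frac: float = 0.3
    r_outer_frac: float = 1.1
    sigma: float = 0.01
    upsample: int = 100
    estimate_m: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    illumination: IlluminationConfig = field(default_factory=IlluminationConfig)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    estimation: EstimationSection = field(default_factory=EstimationSection)
    backend: str = "serial"
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=_jsonify)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


_SECTIONS = {
    "optics": OpticsConfig,
    "illumination": IlluminationConfig,
    "reconstruction": ReconstructionConfig,
    "preprocess": PreprocessConfig,
    "estimation": EstimationSection,
}


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    """Build a validated config; unknown keys raise :class:`ConfigError`."""
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTIONS:
            kwargs[key] = _section_from_dict(_SECTIONS[key], key, value)
        elif key in ("backend", "seed"):
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown configuration key {key!r}")
    return PipelineConfig(**kwargs)


def _section_from_dict(cls: type, section: str, value: Any):
    if not isinstance(value, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(value) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r} "
            f"(known: {sorted(known)})"
        )
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
    }
    return cls(**coerced)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(json.loads(json.dumps(config.to_dict(), default=_jsonify)))
    )


def _jsonify(obj: Any):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
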