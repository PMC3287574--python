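"""Pipeline configuration: nested dataclasses, YAML round-trip, strict keys.

The effective configuration is always defaults merged with user overrides;
unknown keys are rejected rather than silently ignored so a typo in a YAML
file cannot change results unnoticed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["IOConfig", "DenoiseConfig", "MarkersConfig", "LevelSetConfig",
           "PipelineConfig", "load_config"]

_DENOISE_METHODS = ("none", "mean", "gaussian", "anisotropic")


@dataclass
class IOConfig:
    downsample_factor: int = 1  # 1 = process at native ROI resolution


@dataclass
class DenoiseConfig:
    method: str = "anisotropic"
    size: int = 5            # mean filter window
    sigma: float = 2.0       # gaussian
    iterations: int = 15     # anisotropic diffusion
    kappa: float = 30.0
    rate: float = 0.25
    conduction: str = "exponential"

    def __post_init__(self) -> None:
        if self.method not in _DENOISE_METHODS:
            raise ValueError(f"denoise.method must be one of {_DENOISE_METHODS}, "
                             f"got {self.method!r}")


@dataclass
class MarkersConfig:
    h: float = 20.0          # extended-maxima prominence threshold (gray levels)
    disk_radius: int = 0     # optional reconstruction pre-smoothing; 0 = off
    erosion_radius: int = 0
    min_area: int = 20
    bg_distance: int = 15


@dataclass
class LevelSetConfig:
    lambda1: float = 1.0
    lambda2: float = 1.0
    mu: float = 0.1
    epsilon: float = 1.0
    dt: float = 0.5
    max_iter: int = 200
    tol: float = 0.001
    reinit_every: int = 0  # 0 = no periodic signed-distance reinitialization


@dataclass
class PipelineConfig:
    io: IOConfig = field(default_factory=IOConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    markers: MarkersConfig = field(default_factory=MarkersConfig)
    levelset: LevelSetConfig = field(default_factory=LevelSetConfig)
    postprocess: bool = True  # fill holes + keep largest component of final mask

    @classmethod
    def from_dict(cls, data: dict[str, Any] | None) -> "PipelineConfig":
        """Merge ``data`` over the defaults; unknown keys raise ValueError."""
        cfg = cls()
        if not data:
            return cfg
        _merge(cfg, data, path="")
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def _merge(obj: Any, data: dict[str, Any], path: str) -> None:
    valid = {f.name for f in dataclasses.fields(obj)}
    for key, value in data.items():
        where = f"{path}{key}"
        if key not in valid:
            raise ValueError(f"unknown config key: {where!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            if not isinstance(value, dict):
                raise ValueError(f"config section {where!r} must be a mapping")
            _merge(current, value, path=where + ".")
        else:
            setattr(obj, key, value)
    if hasattr(obj, "__post_init__"):
        obj.__post_init__()


def load_config(path: str) -> PipelineConfig:
    """Load a YAML file into a validated :class:`PipelineConfig`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ValueError(f"config file {path!r} must contain a mapping")
    return PipelineConfig.from_dict(data)
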