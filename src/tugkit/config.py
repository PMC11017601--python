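"""YAML pipeline configuration.

One file configures every stage::

    signal:       {rate: 100, mounting: portrait_back, gravity: mean_subtract}
    filter:       {order: 4, cutoff: 20, zero_lag: true}
    orientation:  {gain: 0.01, init_window_s: 0.5}
    segmentation: {rms_window: 0.25, onset_k: 3.0, sustain: 0.2, ...}
    kinematics:   {stance_highpass: 0.05, gait_highpass: 0.3, ...}
    stats:        {alpha: 0.05, welch: false, tie_correction: false, ...}
    seed: 0
    log_level: INFO

Unknown keys are rejected with their full key path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from ._errors import ConfigError
from .kinematics import IntegrationConfig
from .preprocessing import FilterSpec
from .segmentation import SegmentationConfig
from .signal_model import MOUNTINGS


@dataclass(frozen=True)
class SignalConfig:
    rate: float = 100.0
    mounting: str = "portrait_back"
    gravity: str = "mean_subtract"  # {"mean_subtract", "none"}

    def __post_init__(self):
        if self.mounting not in MOUNTINGS:
            raise ConfigError(f"signal.mounting: unknown mounting {self.mounting!r}")
        if self.gravity not in ("mean_subtract", "none"):
            raise ConfigError(f"signal.gravity: must be mean_subtract or none")


@dataclass(frozen=True)
class OrientationConfig:
    gain: float = 0.01
    init_window_s: float = 0.5


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    normality_alpha: float = 0.05
    welch: bool = False
    tie_correction: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    signal: SignalConfig = field(default_factory=SignalConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    orientation: OrientationConfig = field(default_factory=OrientationConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    kinematics: IntegrationConfig = field(default_factory=IntegrationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    log_level: str = "INFO"


_BLOCKS = {
    "signal": SignalConfig,
    "filter": FilterSpec,
    "orientation": OrientationConfig,
    "segmentation": SegmentationConfig,
    "kinematics": IntegrationConfig,
    "stats": StatsConfig,
}


def _build_block(name: str, cls, data) -> object:
    if not isinstance(data, dict):
        raise ConfigError(f"config block {name!r} must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown key {name}.{unknown[0]}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config block {name!r}: {exc}") from exc


def config_from_dict(data: dict) -> PipelineConfig:
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("top-level config must be a mapping")
    top_known = set(_BLOCKS) | {"seed", "log_level"}
    unknown = sorted(set(data) - top_known)
    if unknown:
        raise ConfigError(f"unknown key {unknown[0]}")
    kwargs = {}
    for name, cls in _BLOCKS.items():
        if name in data:
            kwargs[name] = _build_block(name, cls, data[name])
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "log_level" in data:
        kwargs["log_level"] = str(data["log_level"])
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration file."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    return config_from_dict(data)
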