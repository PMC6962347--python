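"""Pipeline configuration: YAML-backed, validated, round-trippable.

A single global seed drives every stochastic stage; per-stage seeds are
derived from it deterministically, so one (config, seed) pair pins down
the whole run. Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "GridConfig",
    "SimulateConfig",
    "MotionConfig",
    "MapsConfig",
    "GroupVelocityConfig",
    "PhaseVelocityConfig",
    "EvaluateConfig",
    "PipelineConfig",
    "load_config",
]


def _from_dict(cls, data: dict, context: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f_ in fields(cls):
        if f_.name in data:
            val = data[f_.name]
            if isinstance(val, list):
                val = tuple(val)
            kwargs[f_.name] = val
    return cls(**kwargs)


@dataclass(frozen=True)
class GridConfig:
    n_depth: int = 40
    n_lateral: int = 128
    n_frames: int = 180
    depth_spacing: float = 0.3e-3
    lateral_spacing: float = 0.3e-3
    frame_interval: float = 1e-4
    center_frequency: float = 5e6
    sound_speed: float = 1540.0


@dataclass(frozen=True)
class SimulateConfig:
    n_plaques: int = 4
    acquisitions_per_plaque: int = 3
    views: tuple[str, ...] = ("L", "T")
    snr_db: Optional[float] = 20.0
    corrupt_acquisitions: int = 0  # acquisitions replaced by pure noise
    amplitude: float = 0.01
    push_time: float = 2.5e-3
    push_duration: float = 400e-6

    def __post_init__(self) -> None:
        if self.n_plaques < 1 or self.acquisitions_per_plaque < 1:
            raise ValueError("n_plaques and acquisitions_per_plaque must be >= 1")
        if self.corrupt_acquisitions < 0:
            raise ValueError("corrupt_acquisitions must be >= 0")
        bad = set(self.views) - {"L", "T"}
        if bad:
            raise ValueError(f"unknown views {sorted(bad)}")


@dataclass(frozen=True)
class MotionConfig:
    use_iq: bool = True  # run the IQ round trip instead of the raw field
    kernel: tuple[int, int, int] = (5, 1, 1)

    def __post_init__(self) -> None:
        if len(self.kernel) != 3 or any(int(k) < 1 for k in self.kernel):
            raise ValueError("kernel must be three counts >= 1")


@dataclass(frozen=True)
class MapsConfig:
    tukey_alpha: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.tukey_alpha <= 1:
            raise ValueError("tukey_alpha must be in [0, 1]")


@dataclass(frozen=True)
class GroupVelocityConfig:
    n_iter: int = 200
    residual_threshold: float = 0.5e-3
    min_samples: int = 2
    quality_gate: float = 0.5

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.min_samples < 2 or not self.residual_threshold > 0:
            raise ValueError("invalid RANSAC parameters")


@dataclass(frozen=True)
class PhaseVelocityConfig:
    pad_factor: int = 4
    v_min: float = 0.5
    v_max: float = 15.0
    prominence_threshold: float = 3.0
    min_valid_fraction: float = 0.5
    crop: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")
        if not 0 < self.v_min < self.v_max:
            raise ValueError("need 0 < v_min < v_max")
        if not 0 <= self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must be in [0, 1]")


@dataclass(frozen=True)
class EvaluateConfig:
    enabled: bool = True
    missing_fraction: float = 0.0


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    log_level: str = "INFO"
    grid: GridConfig = field(default_factory=GridConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    motion: MotionConfig = field(default_factory=MotionConfig)
    maps: MapsConfig = field(default_factory=MapsConfig)
    group_velocity: GroupVelocityConfig = field(default_factory=GroupVelocityConfig)
    phase_velocity: PhaseVelocityConfig = field(default_factory=PhaseVelocityConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if data is None:
            data = {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        sections = {
            "grid": GridConfig,
            "simulate": SimulateConfig,
            "motion": MotionConfig,
            "maps": MapsConfig,
            "group_velocity": GroupVelocityConfig,
            "phase_velocity": PhaseVelocityConfig,
            "evaluate": EvaluateConfig,
        }
        kwargs = {}
        for key, val in data.items():
            if key in sections:
                kwargs[key] = _from_dict(sections[key], val, key)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
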