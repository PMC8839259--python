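"""Run configuration: every exposed default in one YAML-serialisable object.

The configuration round-trips losslessly through YAML; unknown keys are
rejected so typos fail loudly rather than silently falling back to
defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .energy import EnergyParams
from .hierarchy import (
    DEFAULT_DELTAS,
    DEFAULT_MOVES,
    DEFAULT_SCALE_FACTORS,
    HierarchySchedule,
    HierarchyStep,
)


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping for {cls.__name__}, got {type(data)}")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown {cls.__name__} keys: {sorted(unknown)} "
            f"(known: {sorted(known)})"
        )
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if callable(f.default_factory) and isinstance(val, dict):
            # nested section
            kwargs[f.name] = _from_dict(type(f.default_factory()), val)
        else:
            kwargs[f.name] = val
    return cls(**kwargs)


@dataclass
class BackgroundConfig:
    rx: float = 15.0
    ry: float = 300.0
    rz: float = 40.0
    invert: bool = True
    max_halfwidth: int = 20


@dataclass
class EnergyConfig:
    wx: float = 5e-2
    wy: float = 2.5e-2
    p: float = 1.0
    min_overlap: int = 10

    def to_params(self) -> EnergyParams:
        return EnergyParams(self.wx, self.wy, self.p, self.min_overlap)


@dataclass
class ScheduleConfig:
    # one entry per hierarchical step
    scale_factors: list = field(
        default_factory=lambda: [list(x) for x in DEFAULT_SCALE_FACTORS]
    )
    deltas: list = field(default_factory=lambda: list(DEFAULT_DELTAS))
    moves: list = field(
        default_factory=lambda: [[list(g) for g in step] for step in DEFAULT_MOVES]
    )

    def to_schedule(self) -> HierarchySchedule:
        if not len(self.scale_factors) == len(self.deltas) == len(self.moves):
            raise ConfigError("schedule sections must have equal length")
        return HierarchySchedule(
            tuple(
                HierarchyStep(int(fr), int(fc), float(d),
                              tuple((int(r), int(c)) for r, c in mv))
                for (fr, fc), d, mv in zip(self.scale_factors, self.deltas,
                                           self.moves)
            )
        )


@dataclass
class PreprocessConfig:
    crop_top_px: int = 505
    crop_bottom_px: int = 100
    dpi: float = 600.0


@dataclass
class SimulateConfig:
    height: int = 500
    width: int = 150
    speckle_var: float = 0.01


@dataclass
class RunConfig:
    seed: int = 0
    max_passes: int = 100
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    energy: EnergyConfig = field(default_factory=EnergyConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_dict(cls, data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
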