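"""Pipeline configuration: strict YAML-backed settings for every stage.

Unknown keys are rejected rather than ignored, and a resolved copy of the
configuration (plus its hash) is written alongside every run's outputs so
any result can be traced to the exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "SimulateConfig", "ActigraphyConfig", "EstimatorConfig"]


def _from_mapping(cls, d: dict):
    if d is None:
        return cls()
    if not isinstance(d, dict):
        raise ValueError(f"{cls.__name__} section must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass
class SimulateConfig:
    n_subjects_per_group: int = 130
    n_days: int = 7
    beeps_per_day: int = 8
    missing_rate: float = 0.175
    sparsity: float = 0.3
    group_delta: dict | None = None  # {source, target, amount}
    random_effect_sd: float = 0.05
    subject_mean_sd: float = 1.0
    innovation_sd: float = 1.0
    spectral_cap: float = 0.9


@dataclass
class ActigraphyConfig:
    epoch_length: float = 5.0
    window_minutes: float = 60.0
    step_minutes: float = 15.0
    std_threshold_mg: float = 13.0
    range_threshold_mg: float = 50.0
    score_cutoff: int = 1
    min_coverage: float = 0.5


@dataclass
class EstimatorConfig:
    backend: str = "closed_form"
    random_slopes: bool = False


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/run"
    ema_csv: str | None = None  # load this file instead of simulating
    transform_per: str = "group"
    alpha: float = 0.05
    n_permutations: int = 2000
    statistics: tuple = ("edges", "strength", "connectivity")
    plots: bool = False
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    actigraphy: ActigraphyConfig = field(default_factory=ActigraphyConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)

    def __post_init__(self) -> None:
        self.statistics = tuple(self.statistics)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in (
            ("simulate", SimulateConfig),
            ("actigraphy", ActigraphyConfig),
            ("estimator", EstimatorConfig),
        ):
            d[key] = _from_mapping(sub, d.get(key))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def write_resolved(self, outdir) -> Path:
        path = Path(outdir) / "config.resolved.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path
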