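"""Run configuration: validated, serializable, hashable.

A run config bundles the geometry, domain bands, per-genotype force
schedules, solver settings and the pulse-analysis knobs.  Unknown keys are
rejected and every violation is reported with its key path, so a config file
documents exactly one reproducible run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .force_schedule import ScheduleParams, default_params
from .geometry import DomainBands, GeometryConfig
from .solver import SolverConfig

__all__ = ["RunConfig", "AnalysisConfig", "load_config", "save_config",
           "config_hash", "ConfigError"]


class ConfigError(ValueError):
    pass


class AnalysisConfig(BaseModel):
    """Pulse-analysis block (trace segmentation, fitting, filtering)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    dt_s: float = 12.0                 # imaging cadence for pulse movies
    initial_window: int = 3            # samples defining the initial value
    smooth_window: int = 3             # moving-average window for minima
    min_prominence: float = 0.1
    amplitude_threshold_frac: float = 0.25
    background_radius: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        if self.dt_s <= 0 or self.initial_window < 1 or self.smooth_window < 1:
            raise ValueError("analysis cadence and windows must be positive")
        if not (0 <= self.amplitude_threshold_frac <= 1):
            raise ValueError("amplitude_threshold_frac must be in [0, 1]")
        return self


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    geometry: GeometryConfig = GeometryConfig()
    domains: DomainBands = DomainBands()
    solver: SolverConfig = SolverConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    # Per-genotype schedule overrides; genotypes not listed use defaults.
    forces: dict[str, ScheduleParams] = Field(default_factory=dict)
    genotype: str = "wildtype"
    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "results"

    def schedule_params(self, genotype: str | None = None) -> ScheduleParams:
        genotype = genotype or self.genotype
        return self.forces.get(genotype, default_params(genotype))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run config.

    Raises :class:`ConfigError` listing every violation with its key path.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {problems}") from exc


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)
    return path


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical JSON form (stable across key order)."""
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()
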