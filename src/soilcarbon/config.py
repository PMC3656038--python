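"""Run configuration: a validated YAML key-value file.

Unknown keys are rejected by name so typos fail loudly; the seed is part of
the configuration and is recorded in every output the CLI writes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class RunConfig:
    """Configuration shared by the CLI commands."""

    seed: int = 0
    out_dir: str = "results"
    parameter_set: str = "modified"  # "modified" | "original"
    env_mode: str = "neutral"  # "neutral" | "climate"
    n_runs: int = 300
    input_halfwidth: float = 0.10
    spinup_years: int = 100
    n_years: int = 50
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.parameter_set not in ("modified", "original"):
            raise ConfigError(f"parameter_set must be modified/original, got {self.parameter_set!r}")
        if self.env_mode not in ("neutral", "climate"):
            raise ConfigError(f"env_mode must be neutral/climate, got {self.env_mode!r}")
        if self.n_runs < 1:
            raise ConfigError(f"n_runs must be >= 1, got {self.n_runs}")
        if not (0.0 <= self.input_halfwidth < 1.0):
            raise ConfigError("input_halfwidth outside [0, 1)")
        if self.spinup_years < 0:
            raise ConfigError("spinup_years must be >= 0")
        if self.n_years < 1:
            raise ConfigError("n_years must be >= 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigError("ci_level outside (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


_FIELD_TYPES = {f.name: f.type for f in fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML config; unknown keys raise ConfigError."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a mapping, got {type(raw).__name__}")
    unknown = sorted(set(raw) - set(_FIELD_TYPES))
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    coerced = {}
    for key, value in raw.items():
        expected = _FIELD_TYPES[key]
        try:
            if expected == "int":
                coerced[key] = int(value)
            elif expected == "float":
                coerced[key] = float(value)
            else:
                coerced[key] = str(value)
        except (TypeError, ValueError):
            raise ConfigError(f"config key {key!r} has ill-typed value {value!r}") from None
    return RunConfig(**coerced)


def save_config(config: RunConfig, path: str | Path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return p
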