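"""Run configuration: validated, serializable, round-trip safe.

A :class:`RunConfig` aggregates every knob of a simulation run — grid,
model parameters, sweep protocol, frequency list or log-grid spec, seed,
and the two physical scale factors (length per grid cell, seconds per
numerical time unit) that map dimensionless results onto laboratory units
at reporting time. The scale factors never enter the stepper; they only
relabel axes.

Configs are YAML on disk. Unknown keys are rejected loudly, every
constraint of the underlying types is checked at load time (before any
computation), and ``save(load(x)) == load(x)``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError
from .model import GridSpec, ModelParams, default_dt, stability_limit
from .spectra import log_frequency_grid
from .sweep import SweepProtocol

__all__ = ["RunConfig", "load_config", "save_config", "config_from_dict"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GridConfig(_Strict):
    nx: int = Field(50, ge=3)
    ny: int = Field(20, ge=3)
    h: float = Field(1.0, gt=0)


class ModelConfig(_Strict):
    kappa: float = Field(0.001, ge=0)
    amplitude: float = Field(0.01, ge=0)
    dt: float | None = Field(None, gt=0, description="default: 0.2 * h^2/4")
    normalization: str = "zero-mean"

    @model_validator(mode="after")
    def _check_mode(self):
        if self.normalization not in ("zero-mean", "none"):
            raise ValueError("normalization must be 'zero-mean' or 'none'")
        return self


class FrequencyGridConfig(_Strict):
    fmin: float = Field(gt=0)
    fmax: float = Field(gt=0)
    points_per_decade: int = Field(10, ge=1)


class SweepConfig(_Strict):
    frequencies: list[float] | None = None
    grid: FrequencyGridConfig | None = None
    transient_periods: int = Field(5, ge=2)
    measure_periods: int = Field(4, ge=2)
    settle_multiple: float = Field(10.0, ge=0)

    @model_validator(mode="after")
    def _check_freqs(self):
        if (self.frequencies is None) == (self.grid is None):
            raise ValueError("exactly one of 'frequencies' or 'grid' must be set")
        if self.frequencies is not None:
            f = self.frequencies
            if any(x <= 0 for x in f):
                raise ValueError("frequencies must be > 0")
            if any(b <= a for a, b in zip(f, f[1:])):
                raise ValueError("frequencies must be strictly increasing")
        elif self.grid.fmax < self.grid.fmin:
            raise ValueError("grid.fmax must be >= grid.fmin")
        return self


class ScaleConfig(_Strict):
    """Physical calibration hooks, applied at reporting time only."""

    length_per_cell: float = Field(1.0, gt=0)
    time_per_unit: float = Field(1.0, gt=0)


class RunConfig(_Strict):
    grid: GridConfig = GridConfig()
    model: ModelConfig = ModelConfig()
    sweep: SweepConfig = SweepConfig(grid=FrequencyGridConfig(fmin=1e-4, fmax=1e-2))
    seed: int = 0
    output: str | None = None
    scale: ScaleConfig = ScaleConfig()

    @model_validator(mode="after")
    def _check_stability(self):
        if self.model.dt is not None:
            limit = self.grid.h**2 / 4.0
            if self.model.dt > limit * (1 + 1e-12):
                raise ValueError(
                    f"model.dt={self.model.dt:g} exceeds the stability bound "
                    f"h^2/4={limit:g}"
                )
        return self

    # -- conversions to the runtime types -------------------------------

    def grid_spec(self) -> GridSpec:
        return GridSpec(nx=self.grid.nx, ny=self.grid.ny, h=self.grid.h)

    def model_params(self) -> ModelParams:
        g = self.grid_spec()
        dt = self.model.dt if self.model.dt is not None else default_dt(g)
        params = ModelParams(
            kappa=self.model.kappa,
            amplitude=self.model.amplitude,
            dt=dt,
            normalization=self.model.normalization,
        )
        params.validate_for_grid(g)
        return params

    def protocol(self) -> SweepProtocol:
        return SweepProtocol(
            transient_periods=self.sweep.transient_periods,
            measure_periods=self.sweep.measure_periods,
            settle_multiple=self.sweep.settle_multiple,
            seed=self.seed,
        )

    def frequency_list(self) -> np.ndarray:
        if self.sweep.frequencies is not None:
            return np.asarray(self.sweep.frequencies, dtype=float)
        g = self.sweep.grid
        return log_frequency_grid(g.fmin, g.fmax, g.points_per_decade)

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")


def config_from_dict(data: dict, source: str = "<dict>") -> RunConfig:
    """Build a validated RunConfig, converting validation failures to ConfigError."""
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "(top level)"
        raise ConfigError(f"{source}: invalid config at '{loc}': {first['msg']}")
    except TypeError as exc:
        raise ConfigError(f"{source}: {exc}")


def load_config(path: str | Path) -> RunConfig:
    """Load and fully validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse failure: {exc}")
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(data, source=str(path))


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config as YAML such that load(save(x)) == x."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True, default_flow_style=False)
    )
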