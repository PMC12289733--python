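"""Declarative run configuration and result export.

One YAML file describes one reproducible run: the model, its stimuli and
parameters, exactly one execution mode (single run, task, or sweep), a seed
and an output destination.  Unknown keys are rejected — a typo never runs
silently with defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import __version__
from .results import NDResult, NDResultCollection


class StimulusBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    modality: str
    position: float = 0.0
    onset: float = 0.0
    duration: float = 1.0
    intensity: float = 1.0
    noise: float = 0.0


class TaskBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["implicit_spatial", "explicit_spatial", "explicit_temporal"]


class SweepBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    parameter: str
    values: list[float]
    repeats: int = 1
    strategy: Literal["collect_all", "reduce_on_the_fly"] = "collect_all"
    metric: Literal["max_multi", "causes"] = "causes"


class OutputBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    path: str
    format: Literal["netcdf", "csv"] = "netcdf"


class RunConfig(BaseModel):
    """Schema-validated description of one reproducible run."""

    model_config = ConfigDict(extra="forbid", protected_namespaces=())

    model: str
    stimuli: list[StimulusBlock] = []
    params: dict[str, float] = {}
    task: Optional[TaskBlock] = None
    sweep: Optional[SweepBlock] = None
    seed: Optional[int] = None
    output: Optional[OutputBlock] = None

    @model_validator(mode="after")
    def _one_mode(self) -> "RunConfig":
        if self.task is not None and self.sweep is not None:
            raise ValueError("ambiguous mode: config has both task and sweep blocks")
        if self.task is None and self.sweep is None and not self.stimuli:
            raise ValueError("single-run mode requires a stimuli block")
        return self

    @property
    def mode(self) -> str:
        if self.task is not None:
            return "task"
        if self.sweep is not None:
            return "sweep"
        return "run"

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class ConfigError(ValueError):
    """Invalid configuration file, with the offending location."""


def load_config(path) -> RunConfig:
    """Parse and schema-validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        lines = [
            f"  at {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(f"invalid config {path}:\n" + "\n".join(lines)) from exc


def provenance(config: RunConfig | None, seed: int | None) -> dict:
    """Machine-readable record sufficient to regenerate an output."""
    return {
        "version": __version__,
        "seed": seed,
        "config_hash": config.content_hash() if config is not None else None,
        "config": config.model_dump() if config is not None else None,
    }


def export_result(obj, path, fmt: str = "netcdf", meta: dict | None = None) -> Path:
    """Write a result, collection, or table; NetCDF for N-D, CSV for tables.

    Re-import of an NDResult round-trips activity bit-exactly
    (:meth:`NDResult.from_netcdf`).
    """
    path = Path(path)
    if isinstance(obj, NDResult):
        if fmt != "netcdf":
            raise ValueError("NDResult export supports only netcdf")
        if meta:
            obj.metadata.update(meta)  # type: ignore[union-attr]
        obj.to_netcdf(path)
    elif isinstance(obj, NDResultCollection):
        if fmt != "netcdf":
            raise ValueError("tabular export undefined for collections")
        obj.to_netcdf(path)
    elif isinstance(obj, pd.DataFrame):
        if fmt != "csv":
            raise ValueError("tables export as csv")
        df = obj.copy()
        if meta:
            df.attrs.update(meta)
            header = "# " + json.dumps(meta, default=str)
            with open(path, "w") as fh:
                fh.write(header + "\n")
                df.to_csv(fh, index=False)
            return path
        df.to_csv(path, index=False)
    else:
        raise TypeError(f"cannot export object of type {type(obj).__name__}")
    return path


def read_observed_csv(path) -> pd.DataFrame:
    """Read an observed-data CSV with columns (disparity, value)."""
    df = pd.read_csv(path, comment="#")
    missing = {"disparity", "value"} - set(df.columns)
    if missing:
        raise ConfigError(
            f"{path}: observed data needs columns disparity,value "
            f"(missing {sorted(missing)})"
        )
    return df[["disparity", "value"]]
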