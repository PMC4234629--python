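"""Declarative run configuration with strict key validation."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import solar

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    """All pipeline parameters; unknown keys are rejected.

    The full, serialized configuration (plus its hash) is embedded in every
    output's provenance attributes, making a run a pure function of
    (inputs, config, seed).
    """

    model_config = ConfigDict(extra="forbid")

    # paths
    series_csv: Optional[str] = None
    events_csv: Optional[str] = None
    metadata_csv: Optional[str] = None
    environment_nc: Optional[str] = None
    points_csv: Optional[str] = None
    output_dir: str = "swordgrid_out"

    # grid / dynamics
    resolution_km: float = 9.0
    diffusivity_km2_day: float = 300.0
    fit_diffusivity: bool = False
    diffusivity_grid: list[float] = [100.0, 200.0, 300.0, 500.0, 700.0, 900.0]

    # observation model
    sigma_sst: float = 1.0
    sigma_event_min: float = 20.0
    h0_deg: float = solar.DEFAULT_TWILIGHT_DEG
    bathy_gate: bool = True

    # preprocessing
    vmax_km_day: float = 150.0
    k_sst: float = 3.0
    k_reject: float = 3.0
    min_deployment_days: int = 30

    # UD analysis
    hpd_levels: list[float] = [0.5, 0.75, 0.95]
    coverage_level: float = 0.95

    seed: int = 0
    log_level: str = "INFO"

    @field_validator("resolution_km", "sigma_sst", "sigma_event_min", "vmax_km_day")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v

    def to_dict(self) -> dict:
        return self.model_dump()


def load_config(path, **overrides) -> RunConfig:
    """Load a YAML config file, applying keyword overrides."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def ensure_output_dir(cfg: RunConfig) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out
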