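"""Run configuration: validated schema and builders for domains and step laws.

Configs are YAML (JSON accepted, being a YAML subset) with three blocks::

    domain:        {type: interval|polygon|disk, L | vertices | center+radius}
    distribution:  {family: parabolic|gaussian|uniform|tabulated, params: {...}}
    boundary_condition: no_go | stop_go | reflecting
    N, M, burn_in, seed, bins, shaper_floor, outdir

Validation is fail-fast with field-level messages (pydantic).  The
tabulated family may point at a two-column CSV (value, density) with a
header row via ``params: {csv: path}``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .distributions import step_distribution
from .geometry import ConvexPolygon, Disk, Interval

__all__ = ["DomainConfig", "DistributionConfig", "RunConfig", "load_config", "build_domain", "build_distribution"]


class DomainConfig(BaseModel):
    type: Literal["interval", "polygon", "disk"]
    L: Optional[float] = None
    vertices: Optional[list[list[float]]] = None
    vertices_csv: Optional[str] = None
    center: Optional[list[float]] = None
    radius: Optional[float] = None

    @model_validator(mode="after")
    def _check_fields(self):
        if self.type == "interval":
            if self.L is None or self.L <= 0:
                raise ValueError("interval domain requires positive L")
        elif self.type == "polygon":
            if self.vertices is None and self.vertices_csv is None:
                raise ValueError("polygon domain requires vertices or vertices_csv")
        elif self.type == "disk":
            if self.radius is None or self.radius <= 0:
                raise ValueError("disk domain requires positive radius")
        return self


class DistributionConfig(BaseModel):
    family: Literal["parabolic", "gaussian", "uniform", "tabulated"]
    params: dict = Field(default_factory=dict)


class RunConfig(BaseModel):
    domain: DomainConfig
    distribution: DistributionConfig
    boundary_condition: Literal["no_go", "stop_go", "reflecting"] = "no_go"
    N: int = Field(10_000, ge=1)
    M: int = Field(50, ge=1)
    burn_in: Optional[int] = Field(None, ge=0)
    seed: int = 0
    bins: int = Field(60, ge=2)
    shaper_floor: float = Field(0.01, gt=0.0, lt=1.0)
    outdir: str = "runs"

    @model_validator(mode="after")
    def _check(self):
        if self.burn_in is not None and self.burn_in >= self.N:
            raise ValueError("burn_in must be smaller than N")
        if self.domain.type != "interval" and self.boundary_condition != "no_go":
            raise ValueError(
                f"boundary condition {self.boundary_condition!r} is supported in 1D only"
            )
        return self


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig.model_validate(data)


def build_domain(cfg: DomainConfig):
    if cfg.type == "interval":
        return Interval(cfg.L)
    if cfg.type == "polygon":
        if cfg.vertices is not None:
            verts = np.asarray(cfg.vertices, dtype=float)
        else:
            import pandas as pd

            verts = pd.read_csv(cfg.vertices_csv).to_numpy(dtype=float)
        return ConvexPolygon(verts)
    center = cfg.center if cfg.center is not None else (0.0, 0.0)
    return Disk(radius=cfg.radius, center=center)


def build_distribution(cfg: DistributionConfig, dim: int):
    params = dict(cfg.params)
    if cfg.family == "tabulated" and "csv" in params:
        import pandas as pd

        table = pd.read_csv(params.pop("csv")).to_numpy(dtype=float)
        if dim == 1:
            params.update(grid=table[:, 0], density=table[:, 1])
        else:
            params.update(grid=table[:, 0], profile=table[:, 1])
    return step_distribution(cfg.family, dim=dim, **params)


def config_echo(cfg: RunConfig) -> dict:
    """Full-precision echo of a config for run manifests."""
    return json.loads(cfg.model_dump_json())
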