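"""Run configuration: validated, serializable settings for the pipeline.

Defaults are the standard simulation scenario: 20 sites with
environment-space covariance 0.7, a 500-species pure-birth phylogeny
(birth 0.1, death 0), a lognormal SAD, 10,000 individuals per site, and
an 11 x 11 process grid from 1e-4 to 10 with 100 replicates per cell.
Unknown keys are rejected, and a config round-trips losslessly through
YAML/JSON.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .betadiv import METRICS
from .gridinfer import GridConfig

__all__ = ["RunConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class LandscapeSettings(_Strict):
    n_sites: int = Field(default=20, ge=3)
    sigma_es: float = Field(default=0.7, ge=0.0, lt=1.0)
    D_S: int = Field(default=2, ge=1)
    D_E: int = Field(default=2, ge=1)


class TreeSettings(_Strict):
    n_species: int = Field(default=500, ge=2)
    birth: float = Field(default=0.1, gt=0.0)
    death: float = Field(default=0.0, ge=0.0)


class SADSettings(_Strict):
    meanlog: float = 0.0
    sdlog: float = Field(default=1.0, gt=0.0)
    uniform: bool = False


class AssemblySettings(_Strict):
    J: int = Field(default=10_000, ge=1)
    fixed_richness: int | None = None


class GridSettings(_Strict):
    exponent_min: float = -4.0
    exponent_max: float = 1.0
    n_points: int = Field(default=11, ge=1)
    replicates: int = Field(default=100, ge=1)
    fixed_landscape: bool = False

    def values(self) -> list[float]:
        if self.n_points == 1:
            return [10.0**self.exponent_min]
        return list(
            10.0 ** np.linspace(self.exponent_min, self.exponent_max, self.n_points)
        )


class RunConfig(_Strict):
    """Top-level configuration for simulations, grids and inference."""

    landscape: LandscapeSettings = Field(default_factory=LandscapeSettings)
    tree: TreeSettings = Field(default_factory=TreeSettings)
    sad: SADSettings = Field(default_factory=SADSettings)
    assembly: AssemblySettings = Field(default_factory=AssemblySettings)
    grid: GridSettings = Field(default_factory=GridSettings)
    metrics: list[str] = Field(default_factory=lambda: list(METRICS))
    functional_distance: str = Field(
        default="dendrogram", pattern="^(dendrogram|traits)$"
    )
    tolerance: float | None = None
    seed: int = 0
    output_dir: str = "."

    @field_validator("metrics")
    @classmethod
    def _known_metrics(cls, v: list[str]) -> list[str]:
        unknown = [m for m in v if m not in METRICS]
        if unknown:
            raise ValueError(f"unknown metrics: {unknown}")
        return v

    # -- serialization -------------------------------------------------------

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    # -- conversion ----------------------------------------------------------

    def to_grid_config(self) -> GridConfig:
        return GridConfig(
            n_values=np.asarray(self.grid.values()),
            d_values=np.asarray(self.grid.values()),
            replicates=self.grid.replicates,
            n_sites=self.landscape.n_sites,
            sigma_es=self.landscape.sigma_es,
            D_S=self.landscape.D_S,
            D_E=self.landscape.D_E,
            n_species=self.tree.n_species,
            birth=self.tree.birth,
            death=self.tree.death,
            sad_meanlog=self.sad.meanlog,
            sad_sdlog=self.sad.sdlog,
            uniform_sad=self.sad.uniform,
            J=self.assembly.J,
            metrics=tuple(self.metrics),
            functional_distance=self.functional_distance,
            master_seed=self.seed,
            fixed_landscape=self.grid.fixed_landscape,
        )
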