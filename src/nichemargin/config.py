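"""Validated run configuration for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .establishment import ModelSpec

__all__ = ["RunConfig", "MCMCSettings", "SyntheticSettings"]


class MCMCSettings(BaseModel):
    """Mirror of :class:`nichemargin.establishment.ModelSpec`."""

    model_config = ConfigDict(extra="forbid")

    prior_precision: float = Field(0.1, gt=0)
    sigma_scale: float = Field(5.0, gt=0)
    nu_prior_sd: float = Field(10.0, gt=0)
    chains: int = Field(2, ge=1)
    burn_in: int = Field(5000, ge=0)
    iterations: int = Field(20000, ge=1)
    thin: int = Field(20, ge=1)

    @model_validator(mode="after")
    def _thin_divides(self):
        if self.iterations % self.thin != 0:
            raise ValueError("thin must divide iterations")
        return self

    def to_model_spec(self, seed: int | None = None) -> ModelSpec:
        return ModelSpec(
            prior_precision=self.prior_precision,
            sigma_scale=self.sigma_scale,
            nu_prior_sd=self.nu_prior_sd,
            chains=self.chains,
            burn_in=self.burn_in,
            iterations=self.iterations,
            thin=self.thin,
            seed=seed,
        )


class SyntheticSettings(BaseModel):
    """Parameters of the synthetic landscape / species / event generator."""

    model_config = ConfigDict(extra="forbid")

    grid_rows: int = Field(60, ge=4)
    grid_cols: int = Field(120, ge=4)
    n_vars: int = Field(8, ge=2)
    noise_sd: float = Field(0.3, ge=0)
    n_species: int = Field(20, ge=1)
    n_events: int = Field(979, ge=10)
    missing_rate: float = Field(0.1, ge=0, lt=1)
    beta_nmi: float = 0.31


class RunConfig(BaseModel):
    """Full pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    # inputs: either file paths or the synthetic generator
    climate_raster: str | None = None
    ranges_dir: str | None = None  # one GeoJSON per species, <species>.geojson
    events: str | None = None
    synthetic: SyntheticSettings | None = None

    out_dir: str = "nmi_output"
    n_axes: int = Field(2, ge=1)
    scale_pca: bool = True
    aggregation_factor: int = Field(1, ge=1)
    envelope_method: str = "kde"
    envelope_level: float = Field(0.99, gt=0, le=1)
    kde_grid_n: int = Field(500, ge=50)
    kde_bandwidth: str = "normal-reference"
    kde_expand: float = Field(0.1, ge=0)
    nmi_lattice_points: int = Field(10000, ge=100)
    mcmc: MCMCSettings = MCMCSettings()
    run_cross_validation: bool = False
    cv_reps: int = Field(10, ge=1)
    cv_train_fraction: float = Field(0.8, gt=0, lt=1)
    seed: int = 0
    verbosity: int = Field(1, ge=0, le=2)

    @model_validator(mode="after")
    def _inputs(self):
        file_mode = self.climate_raster is not None
        if file_mode == (self.synthetic is not None):
            raise ValueError("provide either file inputs or a `synthetic` block")
        if file_mode and (self.ranges_dir is None or self.events is None):
            raise ValueError("file mode needs climate_raster, ranges_dir and events")
        if self.envelope_method not in ("kde", "mve"):
            raise ValueError("envelope_method must be 'kde' or 'mve'")
        if self.envelope_level not in (0.90, 0.95, 0.99) and not (0 < self.envelope_level <= 1):
            raise ValueError("envelope_level out of range")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        doc = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]
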