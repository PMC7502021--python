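"""Run configuration: parsing, validation, and conversion to model objects.

The config file (YAML; JSON is a YAML subset) mirrors the standard input
parameter table of the model, one block per parameter group::

    particle:
      input_mode: diameter            # or diffusion_coefficient
      value: 100.0                    # nm (or nm^2/s) - average mode...
      # distribution_file: sizes.csv  # ...or a measured distribution
      effective_density: 1.3          # g/cm^3 (agglomerate density!)
      characterization_temperature: 25.0   # degC
      characterization_viscosity: 0.89     # mPa s
    medium:
      density: 1.0                    # g/cm^3
      viscosity: 0.74                 # mPa s
      incubation_temperature: 37.0    # degC
    well:
      bottom_area: 0.32               # cm^2
      volume: 0.2                     # mL (or filling_level: 0.625 cm)
      wall_growth_height: 0.54        # cm; 0 for undifferentiated models
    simulation:
      n_particles: 10000              # default 10,000
      simulation_time: 24.0           # h
      snapshot_fraction: 0.25         # h; default 0.25 = every 15 min
      seed: 1
    output:
      directory: run_output
      plot: true

Validation errors name the offending parameter and its unit.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .geometry import WellGeometry, make_geometry
from .physics import CELSIUS_OFFSET, Conditions, MediumSpec
from .population import ParticleSpec, read_distribution
from .simulator import SimControls

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "write_config",
    "build_particle_spec",
    "build_medium",
    "build_geometry",
    "build_controls",
]

#: Units of each config field, used in validation error messages.
UNITS = {
    "particle.value": "nm or nm^2/s",
    "particle.effective_density": "g/cm^3",
    "particle.characterization_temperature": "degC",
    "particle.characterization_viscosity": "mPa s",
    "medium.density": "g/cm^3",
    "medium.viscosity": "mPa s",
    "medium.incubation_temperature": "degC",
    "well.bottom_area": "cm^2",
    "well.filling_level": "cm",
    "well.volume": "mL",
    "well.wall_growth_height": "cm",
    "simulation.simulation_time": "h",
    "simulation.snapshot_fraction": "h",
    "simulation.time_step": "s",
}


class ConfigError(ValueError):
    """Invalid or unreadable run configuration."""


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParticleConfig(_Block):
    input_mode: Literal["diameter", "diffusion_coefficient"]
    value: Optional[float] = Field(default=None, gt=0)
    distribution_file: Optional[str] = None
    effective_density: float = Field(gt=0)
    characterization_temperature: float = Field(gt=-CELSIUS_OFFSET)
    characterization_viscosity: float = Field(gt=0)

    @model_validator(mode="after")
    def _one_source(self) -> "ParticleConfig":
        if (self.value is None) == (self.distribution_file is None):
            raise ValueError(
                "give exactly one of 'value' (average) or 'distribution_file'"
            )
        return self


class MediumConfig(_Block):
    density: float = Field(gt=0)
    viscosity: float = Field(gt=0)
    incubation_temperature: float = Field(gt=-CELSIUS_OFFSET)


class WellConfig(_Block):
    bottom_area: float = Field(gt=0)
    filling_level: Optional[float] = Field(default=None, gt=0)
    volume: Optional[float] = Field(default=None, gt=0)
    wall_growth_height: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _one_height(self) -> "WellConfig":
        if (self.filling_level is None) == (self.volume is None):
            raise ValueError(
                "give exactly one of 'filling_level' [cm] or 'volume' [mL]"
            )
        height = (
            self.filling_level
            if self.filling_level is not None
            else self.volume / self.bottom_area
        )
        if self.wall_growth_height > height:
            raise ValueError(
                f"wall_growth_height ({self.wall_growth_height} cm) exceeds the "
                f"medium filling level ({height:g} cm)"
            )
        return self


class SimulationConfig(_Block):
    n_particles: int = Field(default=10_000, ge=1)
    simulation_time: float = Field(gt=0)
    snapshot_fraction: float = Field(default=0.25, gt=0)
    seed: int = 0
    time_step: Optional[float] = Field(default=None, gt=0)


class OutputConfig(_Block):
    directory: str = "run_output"
    plot: bool = True
    snapshots: bool = True


class RunConfig(_Block):
    """Validated run configuration, one block per parameter group."""

    particle: ParticleConfig
    medium: MediumConfig
    well: WellConfig
    simulation: SimulationConfig
    output: OutputConfig = OutputConfig()


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"])
        unit = UNITS.get(loc)
        suffix = f" [{unit}]" if unit else ""
        lines.append(f"{loc}{suffix}: {e['msg']}")
    return "invalid run configuration: " + "; ".join(lines)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML/JSON run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"{path}: cannot parse config: {e}") from e
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping of parameter blocks")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as e:
        raise ConfigError(_format_validation_error(e)) from e


def write_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize a config so that `load_config` round-trips it."""
    Path(path).write_text(
        yaml.safe_dump(cfg.model_dump(exclude_none=True), sort_keys=False)
    )


def build_particle_spec(cfg: RunConfig, base_dir: str | Path = ".") -> ParticleSpec:
    """Particle block -> `ParticleSpec` (reads the distribution file if any)."""
    p = cfg.particle
    if p.distribution_file is not None:
        dist_path = Path(p.distribution_file)
        if not dist_path.is_absolute():
            dist_path = Path(base_dir) / dist_path
        values = read_distribution(dist_path)
    else:
        values = ((p.value, 1.0),)
    return ParticleSpec(
        input_mode=p.input_mode,
        values=values,
        effective_density=p.effective_density,
        characterization=Conditions.from_user(
            p.characterization_temperature, p.characterization_viscosity
        ),
    )


def build_medium(cfg: RunConfig) -> MediumSpec:
    m = cfg.medium
    return MediumSpec.from_user(m.density, m.viscosity, m.incubation_temperature)


def build_geometry(cfg: RunConfig) -> WellGeometry:
    w = cfg.well
    return make_geometry(
        bottom_area=w.bottom_area,
        medium_height=w.filling_level,
        medium_volume=w.volume,
        wall_band_height=w.wall_growth_height,
    )


def build_controls(cfg: RunConfig, seed: int | None = None) -> SimControls:
    s = cfg.simulation
    return SimControls(
        total_time=s.simulation_time,
        n_particles=s.n_particles,
        snapshot_fraction=s.snapshot_fraction,
        time_step=s.time_step,
        seed=s.seed if seed is None else seed,
    )
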