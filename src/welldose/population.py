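"""Per-particle property ensembles.

A particle population is specified either by its hydrodynamic diameter (DLS or
NTA) or directly by its diffusion coefficient (NTA measures diffusion and only
derives the diameter from it, so diffusion input skips the conversion), as an
average value or a whole measured distribution.  The distribution is treated as
a weighted empirical distribution: ensemble members are resampled from the
support points with replacement, no parametric form is fitted.

From the sampled value each particle gets

* ``D_inc`` — diffusion coefficient corrected to incubation conditions,
* ``diameter`` — hydrodynamic diameter (given, or recovered from D via
  Stokes–Einstein at the characterization conditions),
* ``v`` — signed Stokes settling velocity from the single ensemble-wide
  effective agglomerate density (negative = floats upward).

Input distributions are assumed number-weighted.  DLS exports are often
intensity-weighted; no conversion is applied here, so convert before input if
needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .physics import (
    Conditions,
    MediumSpec,
    correct_diffusion,
    diameter_to_diffusion,
    diffusion_to_diameter,
    settling_velocity,
)

__all__ = [
    "ParticleSpec",
    "ParticleEnsemble",
    "read_distribution",
    "sample_ensemble",
    "generate_fixture_distribution",
]

INPUT_MODES = ("diameter", "diffusion_coefficient")


@dataclass(frozen=True)
class ParticleSpec:
    """User-facing particle description.

    Parameters
    ----------
    input_mode : {"diameter", "diffusion_coefficient"}
        Whether ``values`` are hydrodynamic diameters [nm] or diffusion
        coefficients [nm^2/s].
    values : tuple of (value, weight)
        Support points of the measured distribution with positive weights
        (normalized on construction); a single pair encodes average mode.
    effective_density : float
        Effective density of the particle agglomerates [g/cm^3] — a single
        average for the whole ensemble.
    characterization : Conditions
        Temperature/viscosity the size or diffusion measurement refers to.
    """

    input_mode: str
    values: tuple[tuple[float, float], ...]
    effective_density: float
    characterization: Conditions

    def __post_init__(self) -> None:
        if self.input_mode not in INPUT_MODES:
            raise ValueError(
                f"input_mode must be one of {INPUT_MODES}, got {self.input_mode!r}"
            )
        if len(self.values) == 0:
            raise ValueError("particle distribution needs at least one support point")
        vals = np.array([v for v, _ in self.values], dtype=float)
        wts = np.array([w for _, w in self.values], dtype=float)
        if np.any(~(vals > 0)):
            raise ValueError("all distribution values must be strictly positive")
        if np.any(~(wts > 0)):
            raise ValueError("all distribution weights must be strictly positive")
        if not self.effective_density > 0:
            raise ValueError(
                f"effective density must be positive, got {self.effective_density}"
            )
        wts = wts / wts.sum()
        object.__setattr__(self, "values", tuple(zip(vals.tolist(), wts.tolist())))

    @property
    def support(self) -> np.ndarray:
        return np.array([v for v, _ in self.values])

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.values])


@dataclass(frozen=True)
class ParticleEnsemble:
    """Per-particle physical properties, SI units, ready for the engine."""

    diameter: np.ndarray  #: hydrodynamic diameter [m]
    diffusion: np.ndarray  #: D at incubation conditions [m^2/s]
    velocity: np.ndarray  #: signed settling velocity [m/s], positive = down

    def __post_init__(self) -> None:
        n = len(self.diameter)
        if not (len(self.diffusion) == n and len(self.velocity) == n):
            raise ValueError("ensemble arrays must have equal length")
        if np.any(~(np.asarray(self.diffusion) > 0)):
            raise ValueError("all diffusion coefficients must be positive")

    @property
    def n(self) -> int:
        return len(self.diameter)


def read_distribution(path: str | Path) -> tuple[tuple[float, float], ...]:
    """Read a measured distribution from CSV.

    Accepts the common DLS/NTA export shapes: one numeric column (equal
    weights) or two columns ``value, weight``.  A single non-numeric header
    line is tolerated.  Returns normalized (value, weight) pairs suitable for
    `ParticleSpec.values`.

    Raises
    ------
    ValueError
        Naming the offending line for non-numeric rows, non-positive values or
        weights, or an empty file.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: distribution file is empty") from None
    if raw.empty:
        raise ValueError(f"{path}: distribution file is empty")
    if raw.shape[1] > 2:
        raise ValueError(
            f"{path}: expected 1 or 2 columns, found {raw.shape[1]}"
        )
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    header_offset = 0
    if numeric.iloc[0].isna().any():  # header line
        raw = raw.iloc[1:]
        numeric = numeric.iloc[1:]
        header_offset = 1
        if numeric.empty:
            raise ValueError(f"{path}: no data rows after the header")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 1 + header_offset
        raise ValueError(f"{path}: non-numeric entry at line {line}")
    values = numeric.iloc[:, 0].to_numpy(dtype=float)
    if numeric.shape[1] == 2:
        weights = numeric.iloc[:, 1].to_numpy(dtype=float)
    else:
        weights = np.full(len(values), 1.0 / len(values))
    nonpos = ~(values > 0) | ~(weights > 0)
    if nonpos.any():
        line = int(np.nonzero(nonpos)[0][0]) + 1 + header_offset
        raise ValueError(
            f"{path}: non-positive value or weight at line {line}"
        )
    weights = weights / weights.sum()
    return tuple(zip(values.tolist(), weights.tolist()))


def sample_ensemble(
    spec: ParticleSpec,
    medium: MediumSpec,
    n: int,
    seed: int | np.random.Generator,
) -> ParticleEnsemble:
    """Draw ``n`` particles i.i.d. from the weighted empirical distribution.

    Diameter mode converts each sampled diameter to a diffusion coefficient at
    the characterization conditions (Stokes–Einstein) before correcting to the
    incubation conditions; diffusion mode corrects the sampled coefficient
    directly and only recovers a diameter for the settling term.  Reproducible
    for a given integer seed.
    """
    if n < 1:
        raise ValueError(f"ensemble size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(spec.values), size=n, p=spec.weights)
    sampled = spec.support[idx]
    char = spec.characterization
    inc = medium.conditions
    if spec.input_mode == "diameter":
        d = sampled * 1e-9  # nm -> m
        D_char = diameter_to_diffusion(d, char)
    else:
        D_char = sampled * 1e-18  # nm^2/s -> m^2/s
        d = diffusion_to_diameter(D_char, char)
    D_inc = correct_diffusion(D_char, char, inc)
    rho_eff = spec.effective_density * 1e3  # g/cm^3 -> kg/m^3
    v = settling_velocity(d, rho_eff, medium)
    return ParticleEnsemble(
        diameter=np.asarray(d, dtype=float),
        diffusion=np.asarray(D_inc, dtype=float),
        velocity=np.asarray(v, dtype=float),
    )


def generate_fixture_distribution(
    median_nm: float,
    gsd: float,
    n_points: int,
    seed: int,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Generate a synthetic lognormal size distribution (DLS/NTA stand-in).

    ``median_nm`` is the geometric median and ``gsd`` the geometric standard
    deviation (``gsd = 1`` collapses to all points equal to the median).  The
    sample is written in the single-column dialect `read_distribution` accepts.
    """
    if not median_nm > 0:
        raise ValueError(f"median must be positive, got {median_nm}")
    if not gsd >= 1:
        raise ValueError(f"geometric standard deviation must be >= 1, got {gsd}")
    if n_points < 1:
        raise ValueError(f"n_points must be >= 1, got {n_points}")
    rng = np.random.default_rng(seed)
    values = median_nm * np.exp(rng.standard_normal(n_points) * np.log(gsd))
    df = pd.DataFrame({"value_nm": values})
    if path is not None:
        df.to_csv(path, index=False)
    return df
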