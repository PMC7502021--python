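"""Single-particle transport physics.

Three relations drive the whole model:

* Stokes–Einstein diffusion, ``D = k_B T / (3 pi eta d_h)``, linking the
  hydrodynamic diameter ``d_h`` of a (possibly agglomerated) particle to its
  Brownian diffusion coefficient in a fluid of viscosity ``eta`` at absolute
  temperature ``T``.
* The condition correction ``D_inc = D_char * (T_inc/T_char) * (eta_char/eta_inc)``,
  which transfers a diffusion coefficient measured under characterization
  conditions (e.g. NTA at room temperature) to incubation conditions, assuming
  the hydrodynamic diameter itself does not change.
* Stokes settling, ``v = g (rho_eff - rho_medium) d_h^2 / (18 eta)``, with the
  *effective* agglomerate density.  The sign of the density difference is kept:
  a negative velocity means the particle floats upward instead of sedimenting.

All functions work in SI units (m, s, kg, K, Pa*s) and accept scalars or numpy
arrays.  Conversion from the user-facing units (nm, g/cm^3, mPa*s, degC) happens
at the configuration boundary, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BOLTZMANN",
    "GRAVITY",
    "CELSIUS_OFFSET",
    "Conditions",
    "MediumSpec",
    "diameter_to_diffusion",
    "diffusion_to_diameter",
    "correct_diffusion",
    "settling_velocity",
    "is_buoyant",
]

#: Boltzmann constant [J/K] (2019 SI exact value).
BOLTZMANN = 1.380649e-23
#: Standard gravitational acceleration [m/s^2].
GRAVITY = 9.80665
#: Offset between Celsius and Kelvin scales.
CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class Conditions:
    """Thermodynamic conditions a diffusion coefficient refers to.

    Parameters
    ----------
    temperature : float
        Absolute temperature [K].
    viscosity : float
        Dynamic viscosity of the fluid [Pa s].
    """

    temperature: float
    viscosity: float

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(
                f"temperature must be positive in kelvin, got {self.temperature}"
            )
        if not self.viscosity > 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")

    @classmethod
    def from_user(cls, temperature_c: float, viscosity_mpas: float) -> "Conditions":
        """Build from user units: temperature [degC], viscosity [mPa s]."""
        return cls(temperature_c + CELSIUS_OFFSET, viscosity_mpas * 1e-3)


@dataclass(frozen=True)
class MediumSpec:
    """Cell-culture medium at incubation conditions (SI units).

    Parameters
    ----------
    density : float
        Medium density [kg/m^3].
    viscosity : float
        Medium dynamic viscosity at incubation temperature [Pa s].
    temperature : float
        Incubation temperature [K].
    """

    density: float
    viscosity: float
    temperature: float

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError(f"medium density must be positive, got {self.density}")
        # reuse Conditions validation for T and eta
        Conditions(self.temperature, self.viscosity)

    @classmethod
    def from_user(
        cls, density_g_cm3: float, viscosity_mpas: float, temperature_c: float
    ) -> "MediumSpec":
        """Build from user units: g/cm^3, mPa s, degC."""
        return cls(
            density=density_g_cm3 * 1e3,
            viscosity=viscosity_mpas * 1e-3,
            temperature=temperature_c + CELSIUS_OFFSET,
        )

    @property
    def conditions(self) -> Conditions:
        """Incubation `Conditions` (temperature, viscosity)."""
        return Conditions(self.temperature, self.viscosity)


def _require_positive(x, name: str):
    x = np.asarray(x, dtype=float)
    if np.any(~(x > 0)):
        raise ValueError(f"{name} must be strictly positive")
    return x


def diameter_to_diffusion(d_h, cond: Conditions):
    """Stokes–Einstein: hydrodynamic diameter [m] -> diffusion coefficient [m^2/s].

    ``D = k_B T / (3 pi eta d_h)``.  Strictly decreasing in ``d_h`` and in the
    viscosity, increasing in the temperature.
    """
    d_h = _require_positive(d_h, "hydrodynamic diameter")
    out = BOLTZMANN * cond.temperature / (3.0 * np.pi * cond.viscosity * d_h)
    return out if out.ndim else float(out)


def diffusion_to_diameter(D, cond: Conditions):
    """Inverse Stokes–Einstein: diffusion coefficient [m^2/s] -> diameter [m]."""
    D = _require_positive(D, "diffusion coefficient")
    out = BOLTZMANN * cond.temperature / (3.0 * np.pi * cond.viscosity * D)
    return out if out.ndim else float(out)


def correct_diffusion(D_char, char: Conditions, inc: Conditions):
    """Rescale a diffusion coefficient between condition sets.

    ``D_inc = D_char * (T_inc / T_char) * (eta_char / eta_inc)``; follows from
    Stokes–Einstein under the assumption that the hydrodynamic diameter is the
    same under both condition sets.  Identity when ``char == inc``.
    """
    D_char = _require_positive(D_char, "diffusion coefficient")
    out = D_char * (inc.temperature / char.temperature) * (
        char.viscosity / inc.viscosity
    )
    return out if out.ndim else float(out)


def settling_velocity(d_h, rho_eff, medium: MediumSpec):
    """Stokes settling velocity [m/s], signed; positive means downward.

    ``v = g (rho_eff - rho_medium) d_h^2 / (18 eta)`` with the effective
    agglomerate density ``rho_eff`` [kg/m^3].  Negative for buoyant particles
    (``rho_eff < rho_medium``), exactly zero at neutral buoyancy.
    """
    d_h = _require_positive(d_h, "hydrodynamic diameter")
    _require_positive(rho_eff, "effective density")
    out = (
        GRAVITY
        * (np.asarray(rho_eff, dtype=float) - medium.density)
        * d_h**2
        / (18.0 * medium.viscosity)
    )
    return out if np.ndim(out) else float(out)


def is_buoyant(rho_eff, rho_medium) -> bool | np.ndarray:
    """True where the effective density is strictly below the medium density.

    Buoyant particles float to the free surface instead of sedimenting; neutral
    density (equal values) is treated as non-buoyant with zero drift.
    """
    _require_positive(rho_eff, "effective density")
    _require_positive(rho_medium, "medium density")
    out = np.asarray(rho_eff, dtype=float) < np.asarray(rho_medium, dtype=float)
    return out if out.ndim else bool(out)
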