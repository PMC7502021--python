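"""Effective-dose outputs and closed-form validation oracles.

The effective (delivered, target-cell) dose is the fraction of administered
particles that has reached cells — on the well bottom or on the colonized wall
band — within the exposure time, as opposed to the nominal medium
concentration.  This module turns raw simulation output into that dose-time
series, converts it to the conventional mass-per-area metric, and provides the
two analytic limits (pure settling, free diffusion) the engine is validated
against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import WellGeometry, wall_band_area
from .simulator import FATE_BOTTOM, FATE_SURFACE, FATE_SUSPENDED, FATE_WALL, SimResult

__all__ = [
    "DoseSeries",
    "dose_series",
    "dose_to_concentration",
    "settling_only_fraction",
    "msd_check",
]


@dataclass(frozen=True)
class DoseSeries:
    """Number-fraction dose over time.

    All arrays share the snapshot time axis [h]; at every time the four
    fractions sum to one, and the absorbed fractions (bottom, wall, surface)
    are non-decreasing.
    """

    times: np.ndarray
    fraction_bottom: np.ndarray
    fraction_wall: np.ndarray
    fraction_surface: np.ndarray
    fraction_suspended: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "fraction_bottom": self.fraction_bottom,
                "fraction_wall": self.fraction_wall,
                "fraction_surface": self.fraction_surface,
                "fraction_suspended": self.fraction_suspended,
            }
        )


def dose_series(result: SimResult) -> DoseSeries:
    """Per-snapshot fate fractions: fate counts divided by particle count."""
    counts = result.fate_counts()
    n = result.n_particles
    return DoseSeries(
        times=result.times,
        fraction_bottom=counts[:, FATE_BOTTOM] / n,
        fraction_wall=counts[:, FATE_WALL] / n,
        fraction_surface=counts[:, FATE_SURFACE] / n,
        fraction_suspended=counts[:, FATE_SUSPENDED] / n,
    )


def dose_to_concentration(
    series: DoseSeries, administered: float, geom: WellGeometry
) -> pd.DataFrame:
    """Convert number fractions to deposited mass per area [ug/cm^2].

    ``administered`` is the nominal medium concentration [ug/mL].  The total
    administered mass is ``administered * medium volume``; the bottom dose
    divides the bottom fraction's share of it by the bottom area, the wall
    dose divides the wall fraction's share by the lateral band area (the band
    is treated as uniformly populated).  Linear in ``administered``; the wall
    dose is zero (not undefined) when there is no wall band.
    """
    if administered < 0:
        raise ValueError(f"administered concentration must be >= 0, got {administered}")
    mass_ug = administered * geom.volume_ml
    band_area = wall_band_area(geom)
    wall = (
        series.fraction_wall * mass_ug / band_area
        if band_area > 0
        else np.zeros_like(series.fraction_wall)
    )
    return pd.DataFrame(
        {
            "time_h": series.times,
            "bottom_dose_ug_cm2": series.fraction_bottom * mass_ug / geom.bottom_area,
            "wall_dose_ug_cm2": wall,
        }
    )


def settling_only_fraction(v: float, h: float, t):
    """Deposited fraction for pure settling from a uniform column.

    With diffusion switched off, a particle starting at height ``z`` reaches
    the bottom exactly at ``z / v``; for a uniform initial distribution over
    ``(0, h)`` the deposited fraction at time ``t`` is ``min(1, v t / h)``.
    SI units (m, m/s, s).
    """
    if v < 0:
        raise ValueError(f"settling velocity must be >= 0 in this oracle, got {v}")
    if not h > 0:
        raise ValueError(f"column height must be positive, got {h}")
    t = np.asarray(t, dtype=float)
    out = np.minimum(1.0, v * t / h)
    return out if out.ndim else float(out)


def msd_check(result: SimResult, expected_D: float) -> pd.DataFrame:
    """Per-axis mean-squared-displacement rate from a boundary-free run.

    For drift-free Brownian motion each axis obeys ``MSD(t) = 2 D t``; this
    estimates ``MSD/t`` per axis over the full run, with the standard error of
    the mean, for comparison with ``2 * expected_D``.  Expects a run made with
    ``boundaries=False`` and zero drift.
    """
    disp = (result.positions[-1] - result.positions[0]) * 1e-2  # cm -> m
    t = (result.times[-1] - result.times[0]) * 3600.0
    if not t > 0:
        raise ValueError("run must span a positive time interval")
    sq = disp**2
    ratio = sq.mean(axis=0) / t
    se = sq.std(axis=0, ddof=1) / np.sqrt(sq.shape[0]) / t
    return pd.DataFrame(
        {
            "axis": ["x", "y", "z"],
            "msd_rate": ratio,
            "se": se,
            "expected": 2.0 * expected_D,
        }
    )
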