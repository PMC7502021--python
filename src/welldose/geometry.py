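"""Cell-culture well geometry.

The well is modelled as an upright right circular cylinder: the dominant
multiwell-plate geometry.  The liquid column runs from ``z = 0`` (well bottom)
to ``z = medium_height`` (free surface); ``x, y`` are measured from the
cylinder axis.  Differentiated cell models (Caco-2, HepaRG) colonize a band of
the lateral wall from the bottom up to ``wall_band_height``; undifferentiated
models use a band height of 0.

User-facing lengths are in cm (matching how plate dimensions are reported);
SI accessors (``radius_m`` etc.) feed the stochastic engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["WellGeometry", "make_geometry", "wall_band_area"]


@dataclass(frozen=True)
class WellGeometry:
    """Cylindrical well holding the medium column.

    Parameters
    ----------
    bottom_area : float
        Dish bottom area [cm^2].
    medium_height : float
        Medium filling level (liquid column height) [cm].
    wall_band_height : float
        Height of cell growth up the lateral wall [cm]; 0 for
        undifferentiated cell models.
    """

    bottom_area: float
    medium_height: float
    wall_band_height: float = 0.0

    def __post_init__(self) -> None:
        if not self.bottom_area > 0:
            raise ValueError(f"dish bottom area must be positive, got {self.bottom_area}")
        if not self.medium_height > 0:
            raise ValueError(
                f"medium filling level must be positive, got {self.medium_height}"
            )
        if self.wall_band_height < 0:
            raise ValueError(
                f"wall cell-band height must be >= 0, got {self.wall_band_height}"
            )
        if self.wall_band_height > self.medium_height:
            raise ValueError(
                "wall cell-band height "
                f"({self.wall_band_height} cm) exceeds the medium filling level "
                f"({self.medium_height} cm)"
            )

    @property
    def radius(self) -> float:
        """Well radius [cm], derived from the bottom area."""
        return math.sqrt(self.bottom_area / math.pi)

    @property
    def volume_ml(self) -> float:
        """Medium volume [mL] (1 mL = 1 cm^3)."""
        return self.bottom_area * self.medium_height

    # --- SI accessors for the engine ---
    @property
    def radius_m(self) -> float:
        return self.radius * 1e-2

    @property
    def height_m(self) -> float:
        return self.medium_height * 1e-2

    @property
    def wall_band_m(self) -> float:
        return self.wall_band_height * 1e-2


def make_geometry(
    bottom_area: float,
    medium_height: float | None = None,
    medium_volume: float | None = None,
    wall_band_height: float = 0.0,
) -> WellGeometry:
    """Build a `WellGeometry` from Table-style plate parameters.

    Exactly one of ``medium_height`` [cm] or ``medium_volume`` [mL] must be
    given; the filling level can be measured directly or computed from the
    dispensed volume as ``height = volume / bottom_area``.

    Raises
    ------
    ValueError
        If both or neither of height/volume are given, or if the wall band
        exceeds the resulting filling level.
    """
    if (medium_height is None) == (medium_volume is None):
        raise ValueError(
            "exactly one of medium_height [cm] or medium_volume [mL] must be given"
        )
    if medium_height is None:
        if not medium_volume > 0:
            raise ValueError(f"medium volume must be positive, got {medium_volume}")
        if not bottom_area > 0:
            raise ValueError(f"dish bottom area must be positive, got {bottom_area}")
        medium_height = medium_volume / bottom_area
    return WellGeometry(
        bottom_area=bottom_area,
        medium_height=medium_height,
        wall_band_height=wall_band_height,
    )


def wall_band_area(geom: WellGeometry) -> float:
    """Lateral area of the wall cell band [cm^2]: ``2 pi r h_band``.

    In small-footprint formats (e.g. a 96-well plate with a differentiated
    Caco-2 band of ~0.54 cm) this exceeds the bottom area, so the wall cell
    population can outnumber the bottom one.
    """
    return 2.0 * math.pi * geom.radius * geom.wall_band_height
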