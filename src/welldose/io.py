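"""Result serialization and static plots.

Tabular outputs are plain CSV with a header (spreadsheet-friendly), summaries
are JSON.  Snapshot positions are stored in cm to 6 significant digits with
the fate as a string.  Plots are static PNG files.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dosimetry import DoseSeries, dose_series
from .geometry import wall_band_area
from .simulator import FATE_NAMES, SimResult

__all__ = [
    "write_dose_series",
    "read_dose_series",
    "write_snapshots",
    "read_snapshots",
    "write_summary",
    "plot_dose_series",
    "plot_snapshot",
]


def write_dose_series(series: DoseSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_dose_series(path: str | Path) -> DoseSeries:
    df = pd.read_csv(path)
    return DoseSeries(
        times=df["time_h"].to_numpy(),
        fraction_bottom=df["fraction_bottom"].to_numpy(),
        fraction_wall=df["fraction_wall"].to_numpy(),
        fraction_surface=df["fraction_surface"].to_numpy(),
        fraction_suspended=df["fraction_suspended"].to_numpy(),
    )


def snapshots_frame(result: SimResult) -> pd.DataFrame:
    """Long-format snapshot table: one row per (snapshot, particle)."""
    n_snap, n, _ = result.positions.shape
    fate_names = np.array(FATE_NAMES)
    return pd.DataFrame(
        {
            "time_h": np.repeat(result.times, n),
            "particle": np.tile(np.arange(n), n_snap),
            "x_cm": result.positions[:, :, 0].ravel(),
            "y_cm": result.positions[:, :, 1].ravel(),
            "z_cm": result.positions[:, :, 2].ravel(),
            "fate": fate_names[result.fates.ravel()],
        }
    )


def write_snapshots(result: SimResult, path: str | Path) -> None:
    snapshots_frame(result).to_csv(path, index=False, float_format="%.6g")


def read_snapshots(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_summary(result: SimResult, path: str | Path, **extra) -> dict:
    """Terminal dose summary as JSON; returns the written dict."""
    from . import __version__

    series = dose_series(result)
    geom = result.geometry
    summary = {
        "n_particles": result.n_particles,
        "simulation_time_h": float(result.times[-1]),
        "n_snapshots": len(result.times),
        "seed": result.controls.seed,
        "geometry": {
            "bottom_area_cm2": geom.bottom_area,
            "radius_cm": geom.radius,
            "medium_height_cm": geom.medium_height,
            "wall_band_height_cm": geom.wall_band_height,
            "wall_band_area_cm2": wall_band_area(geom),
        },
        "terminal_fractions": {
            "bottom": float(series.fraction_bottom[-1]),
            "wall": float(series.fraction_wall[-1]),
            "surface": float(series.fraction_surface[-1]),
            "suspended": float(series.fraction_suspended[-1]),
        },
        "versions": {"welldose": __version__, "numpy": np.__version__},
    }
    summary.update(extra)
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
    return summary


def plot_dose_series(series: DoseSeries, path: str | Path) -> None:
    """Deposited/suspended fraction versus time as a static PNG."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(series.times, series.fraction_bottom, label="bottom")
    if np.any(series.fraction_wall > 0):
        ax.plot(series.times, series.fraction_wall, label="wall band")
    if np.any(series.fraction_surface > 0):
        ax.plot(series.times, series.fraction_surface, label="surface")
    ax.plot(series.times, series.fraction_suspended, label="suspended", ls="--")
    ax.set_xlabel("time [h]")
    ax.set_ylabel("fraction of administered particles")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_snapshot(
    snapshots: pd.DataFrame, time_h: float, path: str | Path
) -> float:
    """Side-view scatter (r, z) of the snapshot nearest ``time_h``.

    Returns the snapshot time actually plotted.
    """
    times = np.sort(snapshots["time_h"].unique())
    t = float(times[np.argmin(np.abs(times - time_h))])
    snap = snapshots[snapshots["time_h"] == t]
    fig, ax = plt.subplots(figsize=(5, 5))
    for fate in FATE_NAMES:
        sel = snap[snap["fate"] == fate]
        if len(sel) == 0:
            continue
        r = np.hypot(sel["x_cm"], sel["y_cm"])
        ax.scatter(r, sel["z_cm"], s=4, alpha=0.5, label=fate)
    ax.set_xlabel("radial distance [cm]")
    ax.set_ylabel("height above bottom [cm]")
    ax.set_title(f"t = {t:g} h")
    ax.legend(frameon=False, markerscale=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return t
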