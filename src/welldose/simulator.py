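"""3D stochastic sedimentation–diffusion engine.

Every suspended particle performs Euler–Maruyama Brownian dynamics in the
liquid cylinder: per time step each coordinate gains a Gaussian increment of
variance ``2 D_i dt`` and the vertical coordinate additionally drifts by
``-v_i dt`` (``v_i`` signed, positive = downward sedimentation, negative =
flotation).  Boundary rules, applied after every step:

* ``z <= 0`` — absorbed at the bottom (fate ``bottom``), frozen at ``z = 0``;
* radial distance ``>= R`` with ``z`` inside the wall cell band — absorbed at
  the lateral wall (fate ``wall``), projected onto the wall;
* radial distance ``>= R`` above the band — specular reflection back inside;
* ``z >= h`` — absorbed at the free surface (fate ``surface``) for buoyant
  particles (``v_i < 0``), specular reflection otherwise.

A step violating both the bottom and the lateral boundary resolves bottom
first.  Absorbed particles never move again; their absorption time is
recorded.  Boundary detection is end-of-step with projection (no
Brownian-bridge crossing correction), a small first-order absorption bias that
is negligible at the default step size.

One seeded generator drives initialization and stepping in fixed iteration
order, so a run is bit-reproducible from its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import WellGeometry
from .physics import MediumSpec
from .population import ParticleEnsemble, ParticleSpec, sample_ensemble

__all__ = [
    "FATE_SUSPENDED",
    "FATE_BOTTOM",
    "FATE_WALL",
    "FATE_SURFACE",
    "FATE_NAMES",
    "SimControls",
    "SimResult",
    "initial_positions",
    "step",
    "apply_boundaries",
    "default_time_step",
    "simulate_ensemble",
    "run",
]

logger = logging.getLogger(__name__)

FATE_SUSPENDED = 0
FATE_BOTTOM = 1
FATE_WALL = 2
FATE_SURFACE = 3
FATE_NAMES = ("suspended", "bottom", "wall", "surface")


@dataclass(frozen=True)
class SimControls:
    """Simulation controls.

    Parameters
    ----------
    total_time : float
        Simulated incubation time [h].
    n_particles : int
        Number of tracked particles (10,000 is a good accuracy/cost
        compromise).
    snapshot_fraction : float
        Interval between recorded snapshots [h]; 0.25 samples every 15 min.
    time_step : float or None
        Integrator step [s]; ``None`` selects it from the ensemble (see
        `default_time_step`).
    seed : int
        Seed of the single pseudo-random stream.
    max_snapshot_bytes : int
        Abort before running if storing all snapshots would exceed this cap.
    """

    total_time: float
    n_particles: int = 10_000
    snapshot_fraction: float = 0.25
    time_step: float | None = None
    seed: int = 0
    max_snapshot_bytes: int = 512 * 1024 * 1024

    def __post_init__(self) -> None:
        if not self.total_time > 0:
            raise ValueError(f"simulation time must be positive, got {self.total_time}")
        if self.n_particles < 1:
            raise ValueError(f"need at least one particle, got {self.n_particles}")
        if not 0 < self.snapshot_fraction <= self.total_time:
            raise ValueError(
                "snapshot fraction must lie in (0, total_time], got "
                f"{self.snapshot_fraction}"
            )
        if self.time_step is not None and not (
            0 < self.time_step <= self.snapshot_fraction * 3600.0
        ):
            raise ValueError(
                "time step must be positive and at most the snapshot interval, "
                f"got {self.time_step} s"
            )

    def snapshot_times(self) -> np.ndarray:
        """Snapshot times [h], including t = 0 and t = total_time."""
        k = int(math.floor(self.total_time / self.snapshot_fraction + 1e-9))
        times = self.snapshot_fraction * np.arange(k + 1, dtype=float)
        if self.total_time - times[-1] > 1e-9 * max(1.0, self.total_time):
            times = np.append(times, self.total_time)
        return times


@dataclass
class SimResult:
    """Full output of a run: snapshot trajectories plus per-particle fates.

    ``positions`` is (n_snapshots, n_particles, 3) in cm, ``fates`` the fate
    code of each particle at each snapshot, ``fate_time`` the absorption time
    [h] (NaN while suspended at the end of the run).
    """

    times: np.ndarray
    positions: np.ndarray
    fates: np.ndarray
    fate_time: np.ndarray
    geometry: WellGeometry
    controls: SimControls
    ensemble: ParticleEnsemble = field(repr=False, default=None)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def fate_counts(self) -> np.ndarray:
        """Counts per fate, shape (n_snapshots, 4), order `FATE_NAMES`."""
        counts = np.empty((len(self.times), 4), dtype=np.int64)
        for code in range(4):
            counts[:, code] = (self.fates == code).sum(axis=1)
        return counts


def initial_positions(
    geom: WellGeometry, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Uniform positions in the liquid cylinder (well-mixed suspension), in m.

    Radial placement uses ``r = R sqrt(u)`` so the disc is sampled uniformly;
    ``z`` is uniform over (0, medium height).
    """
    if n < 1:
        raise ValueError(f"need at least one particle, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = geom.radius_m * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * np.pi
    z = rng.uniform(0.0, geom.height_m, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def step(
    positions: np.ndarray,
    diffusion: np.ndarray,
    velocity: np.ndarray,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Euler–Maruyama step for the given particles (positions in m).

    Each coordinate receives ``Normal(0, 1) * sqrt(2 D dt)``; z additionally
    drifts down by ``v dt`` (signed).  Returns the displaced positions.
    """
    if not dt > 0:
        raise ValueError(f"time step must be positive, got {dt}")
    sigma = np.sqrt(2.0 * np.asarray(diffusion) * dt)
    out = positions + rng.standard_normal(positions.shape) * sigma[:, None]
    out[:, 2] -= np.asarray(velocity) * dt
    return out


def apply_boundaries(
    positions: np.ndarray,
    fates: np.ndarray,
    fate_time: np.ndarray,
    ids: np.ndarray,
    velocity: np.ndarray,
    geom: WellGeometry,
    time_h: float,
    bottom_mode: str = "absorb",
    top_mode: str = "auto",
) -> None:
    """Resolve boundary crossings for the just-moved particles ``ids`` in place.

    ``bottom_mode``/``top_mode`` are test-harness knobs (``"absorb"``,
    ``"reflect"``, top also ``"auto"`` = absorb only buoyant particles); the
    physical configuration is the default.
    """
    R = geom.radius_m
    h = geom.height_m
    band = geom.wall_band_m
    p = positions[ids]
    z = p[:, 2]
    new_fate = np.zeros(len(ids), dtype=fates.dtype)

    # bottom first: bottom-area cells take precedence over the wall band
    low = z <= 0.0
    if bottom_mode == "absorb":
        z[low] = 0.0
        new_fate[low] = FATE_BOTTOM
    elif bottom_mode == "reflect":
        z[low] = -z[low]
        low[:] = False
    else:  # pragma: no cover - guarded by tests
        raise ValueError(f"unknown bottom_mode {bottom_mode!r}")

    # lateral wall: absorb inside the cell band, reflect above it
    r = np.hypot(p[:, 0], p[:, 1])
    out = (r >= R) & ~low
    hit_wall = out & (z <= band)
    if np.any(hit_wall):
        scale = R / r[hit_wall]
        p[hit_wall, 0] *= scale
        p[hit_wall, 1] *= scale
        new_fate[hit_wall] = FATE_WALL
    refl = out & ~hit_wall
    if np.any(refl):
        scale = np.maximum(2.0 * R - r[refl], 1e-12 * R) / r[refl]
        p[refl, 0] *= scale
        p[refl, 1] *= scale

    # free surface: absorb buoyant particles, reflect the rest
    high = (z >= h) & ~low & ~hit_wall
    if top_mode == "auto":
        absorb_top = high & (np.asarray(velocity)[ids] < 0.0)
    elif top_mode == "absorb":
        absorb_top = high
    elif top_mode == "reflect":
        absorb_top = np.zeros_like(high)
    else:  # pragma: no cover - guarded by tests
        raise ValueError(f"unknown top_mode {top_mode!r}")
    z[absorb_top] = h
    new_fate[absorb_top] = FATE_SURFACE
    refl_top = high & ~absorb_top
    z[refl_top] = np.clip(2.0 * h - z[refl_top], 0.0, h)

    p[:, 2] = z
    positions[ids] = p
    absorbed = new_fate != FATE_SUSPENDED
    if np.any(absorbed):
        fates[ids[absorbed]] = new_fate[absorbed]
        fate_time[ids[absorbed]] = time_h


def default_time_step(
    ensemble: ParticleEnsemble, geom: WellGeometry, snapshot_interval_s: float
) -> float:
    """Step size [s] keeping every particle's typical move small.

    Chosen so that ``max_i(sqrt(2 D_i dt) + |v_i| dt) <= h / 200`` (one step
    covers at most 0.5% of the column height), capped at the snapshot
    interval.
    """
    L = geom.height_m / 200.0
    sq = np.sqrt(2.0 * ensemble.diffusion)
    av = np.abs(ensemble.velocity)
    dt = np.full(ensemble.n, np.inf)
    drift = av > 0
    # solve |v| dt + sqrt(2D) sqrt(dt) - L = 0 for sqrt(dt)
    s = (-sq[drift] + np.sqrt(sq[drift] ** 2 + 4.0 * av[drift] * L)) / (
        2.0 * av[drift]
    )
    dt[drift] = s**2
    pure = ~drift & (sq > 0)
    dt[pure] = (L / sq[pure]) ** 2
    return float(min(dt.min(), snapshot_interval_s))


def simulate_ensemble(
    ensemble: ParticleEnsemble,
    geom: WellGeometry,
    controls: SimControls,
    rng: np.random.Generator | None = None,
    zero_diffusion: bool = False,
    boundaries: bool = True,
    bottom_mode: str = "absorb",
    top_mode: str = "auto",
) -> SimResult:
    """Advance a sampled ensemble through the well and record snapshots.

    ``zero_diffusion`` (drift-only oracle mode) and ``boundaries=False``
    (free-space diffusion) exist for validation against closed-form limits;
    they are not physical user modes.
    """
    n = ensemble.n
    if n != controls.n_particles:
        raise ValueError(
            f"ensemble size {n} does not match controls.n_particles "
            f"{controls.n_particles}"
        )
    times = controls.snapshot_times()
    n_snap = len(times)
    need = n_snap * n * (3 * 8 + 1) + n * 8
    if need > controls.max_snapshot_bytes:
        raise MemoryError(
            f"storing {n_snap} snapshots of {n} particles needs ~{need / 1e6:.0f} MB, "
            f"above the configured cap of {controls.max_snapshot_bytes / 1e6:.0f} MB; "
            "increase the snapshot fraction or the cap"
        )
    rng = rng if rng is not None else np.random.default_rng(controls.seed)
    D = np.zeros(n) if zero_diffusion else ensemble.diffusion
    v = ensemble.velocity

    pos = initial_positions(geom, n, rng)
    fates = np.zeros(n, dtype=np.int8)
    fate_time = np.full(n, np.nan)
    positions = np.empty((n_snap, n, 3))
    fates_out = np.empty((n_snap, n), dtype=np.int8)
    positions[0] = pos * 1e2  # m -> cm
    fates_out[0] = fates

    snap_s = controls.snapshot_fraction * 3600.0
    base_dt = (
        controls.time_step
        if controls.time_step is not None
        else default_time_step(ensemble, geom, snap_s)
    )
    if zero_diffusion and not np.isfinite(base_dt):
        base_dt = snap_s
    logger.info(
        "simulating %d particles for %g h (%d snapshots, dt ~ %.3g s)",
        n, controls.total_time, n_snap, base_dt,
    )

    for k in range(1, n_snap):
        interval_s = (times[k] - times[k - 1]) * 3600.0
        n_steps = max(1, int(math.ceil(interval_s / base_dt - 1e-12)))
        dt = interval_s / n_steps
        for j in range(n_steps):
            ids = np.nonzero(fates == FATE_SUSPENDED)[0]
            if ids.size == 0:
                break
            pos[ids] = step(pos[ids], D[ids], v[ids], dt, rng)
            if boundaries:
                t_h = times[k - 1] + (j + 1) * dt / 3600.0
                apply_boundaries(
                    pos, fates, fate_time, ids, v, geom, t_h,
                    bottom_mode=bottom_mode, top_mode=top_mode,
                )
        positions[k] = pos * 1e2
        fates_out[k] = fates
        logger.debug(
            "t = %6.2f h: %d suspended", times[k], int((fates == 0).sum())
        )

    return SimResult(
        times=times,
        positions=positions,
        fates=fates_out,
        fate_time=fate_time,
        geometry=geom,
        controls=controls,
        ensemble=ensemble,
    )


def run(
    spec: ParticleSpec,
    medium: MediumSpec,
    geom: WellGeometry,
    controls: SimControls,
    **engine_flags,
) -> SimResult:
    """Sample the particle ensemble and simulate it: the one-call entry point.

    Ensemble sampling and particle tracking share the single stream seeded by
    ``controls.seed``, so identical inputs give bit-identical results.
    """
    rng = np.random.default_rng(controls.seed)
    ensemble = sample_ensemble(spec, medium, controls.n_particles, rng)
    return simulate_ensemble(ensemble, geom, controls, rng=rng, **engine_flags)
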