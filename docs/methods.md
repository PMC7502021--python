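# Methods

## Model

`welldose` tracks `n` independent spherical particles through the liquid
column of a cell-culture well, modelled as an upright right circular cylinder
of radius `R = sqrt(A/π)` (from the dish bottom area `A`) and height `h` (the
medium filling level, given directly or as volume/area). Rectangular dishes
must be approximated by an equal-area cylinder; this is a documented
limitation, not a supported geometry.

Each particle `i` carries a hydrodynamic diameter `d_i`, a diffusion
coefficient `D_i` and a signed settling velocity `v_i` (positive downward),
fixed for the whole run:

* `D = k_B T / (3π η d)` (Stokes–Einstein). When the input is a diffusion
  coefficient (NTA), this conversion is skipped and the measured `D` is used
  directly; a diameter is then recovered through the inverse relation at the
  characterization conditions, solely for the settling term.
* Measurements refer to the characterization temperature/viscosity; the
  engine rescales to incubation conditions via
  `D_inc = D_char (T_inc/T_char)(η_char/η_inc)`, i.e. Stokes–Einstein with an
  invariant hydrodynamic diameter. No transformation of the diameter itself
  between fluids is attempted — measuring in the incubation medium is the
  user's responsibility.
* `v = g (ρ_eff − ρ_medium) d² / (18 η)` (Stokes settling) with the
  *effective agglomerate density*, a single scalar for the whole ensemble
  (centrifugation methods yield an average, not a per-size density). Using
  the raw material density would badly overestimate sedimentation. A negative
  `v` (effective density below the medium) makes the particle float; neutral
  density gives exactly `v = 0` and pure diffusion, by convention not treated
  as an error.

Particle populations are weighted empirical distributions: the support points
of the measured distribution (or a single average value) are resampled with
replacement. No parametric form is fitted. Input distributions are assumed
number-weighted; DLS intensity-weighted exports should be converted before
input — the package applies no conversion.

## Stochastic integration

Euler–Maruyama with a fixed step `Δt`: each coordinate receives an
independent `N(0,1)·sqrt(2 D_i Δt)` increment and `z` drifts by `−v_i Δt`.
The initial condition is a uniform i.i.d. sample over the liquid cylinder
(a freshly administered, well-mixed suspension): `z ~ U(0, h)`, radially
`r = R·sqrt(u)`.

Boundary rules, applied after every step (end-of-step detection with
projection onto the violated boundary):

* `z ≤ 0`: absorbed at the bottom, frozen at `z = 0` (fate `bottom`);
* radial distance `≥ R` with `z` inside the wall cell band: absorbed,
  projected onto the wall (fate `wall`); above the band: specular reflection
  `r → 2R − r`;
* `z ≥ h`: absorbed (fate `surface`) if the particle is buoyant
  (`v_i < 0`, decided per particle so mixed ensembles behave correctly),
  otherwise specular reflection `z → 2h − z`.

A step violating both the bottom and the lateral boundary resolves bottom
first (bottom cells take precedence); the tie-break is arbitrary and affects
a vanishing fraction of events at the default step. End-of-step detection
without a Brownian-bridge crossing correction slightly under-detects
absorptions within a step; this first-order bias shrinks with `Δt` and the
self-convergence test (halving `Δt` moves the 24 h bottom fraction by less
than 3 binomial standard errors at n = 10,000) bounds it below the Monte
Carlo noise at the default step.

**Step size.** Unless overridden, `Δt` is the largest value with
`max_i( sqrt(2 D_i Δt) + |v_i| Δt ) ≤ h/200` — the typical per-step move of
the fastest particle stays below 0.5% of the column height — capped at the
snapshot interval. For 100 nm particles in a 0.625 cm column this gives
`Δt ≈ 79 s`, about 11 steps per 15-min snapshot.

**Randomness.** One `numpy` PCG64 generator, seeded from the run seed, drives
ensemble resampling, initial placement and stepping in fixed iteration order;
identical configurations therefore reproduce results bit for bit, and the
dose-series CSV byte for byte.

**Degenerate inputs.** A single support point is a valid "average mode"
distribution (all particles identical). A wall band of 0 produces no wall
absorptions (undifferentiated models). Snapshot storage is pre-sized and the
run aborts with a clear error if it would exceed a configurable memory cap
(default 512 MB) instead of exhausting memory mid-run.

## Parameters

| parameter | unit | default | notes |
|---|---|---|---|
| hydrodynamic diameter / diffusion coefficient | nm / nm²s⁻¹ | — | average or whole distribution |
| effective density | g/cm³ | — | agglomerate density, one value per ensemble |
| characterization temperature / viscosity | °C / mPa·s | — | conditions of the size measurement |
| medium density / viscosity / temperature | g/cm³ / mPa·s / °C | — | incubation conditions |
| dish bottom area | cm² | — | cylinder radius derived from it |
| filling level **or** volume | cm / mL | — | `h = V/A` when volume is given |
| wall growth height | cm | 0 | ~0.54 cm for differentiated Caco-2, ~0.28 cm for HepaRG |
| particles simulated | — | 10,000 | accuracy/cost compromise; binomial error ~1/√n |
| simulation time | h | — | match the incubation time |
| snapshot fraction | h | 0.25 | 0.25 = record every 15 min |
| time step | s | auto | see step-size rule; expose only for convergence studies |
| seed | — | 0 | full-run reproducibility |

Internally everything is SI (m, s, kg, K, Pa·s); the user-facing units above
are converted exactly once at the configuration boundary, which avoids
mixed-unit formula bugs.

## Dose outputs

The dose–time series reports the four fate fractions (bottom, wall, surface,
suspended) at every snapshot; they sum to one and the absorbed fractions are
non-decreasing by construction. `dose_to_concentration` converts to the
conventional mass-per-area metric: with administered concentration `c`
[µg/mL] and medium volume `V`, the bottom dose is
`f_bottom · c · V / A_bottom` and the wall dose `f_wall · c · V / (2π R h_band)`,
treating the band as uniformly populated (sub-band position is not resolved).
Per-particle-number or surface-area doses are linear rescalings left to the
user. Absorbed particles are frozen and kept in all snapshots with a fate
column, rather than removed, so any snapshot can be re-plotted with or
without deposited particles.

## Synthetic data

`generate_fixture_distribution` emulates a DLS/NTA size export as a lognormal
sample (geometric median, geometric standard deviation) written in the
single-column CSV dialect the reader accepts. Defaults used throughout the
tests and the reproduction script — median 100 nm, GSD 1.5, effective density
1.3 g/cm³, water-like medium at 37 °C (1.0 g/cm³, 0.74 mPa·s), characterized
at 25 °C / 0.89 mPa·s, 96-well-like geometry (0.32 cm², 0.2 mL, Caco-2 band
0.54 cm) — describe a typical agglomerating metal-oxide suspension in a
differentiated barrier-model experiment. The generator does not emulate
multimodal populations, intensity weighting, measurement noise floors,
time-dependent agglomeration or dissolution; passing tests therefore
demonstrate the transport and bookkeeping are correct under the stated
physics, not that those effects are negligible for any real particle.

## Validation strategy

The model prints no reference dataset to compare against, so validation is by
closed-form limits, each exercised in the test suite and the reproduction
script:

* the diameter↔diffusion maps and the condition correction are exact
  algebraic inverses (round-trip error ≤ 1e-12 relative over the full
  parameter grid);
* with boundaries disabled and zero drift, the per-axis MSD rate matches the
  Brownian law `2D` within 3 standard errors (the Gaussian increments make
  the integrator exact for free diffusion at any step);
* with diffusion forced to zero (a hidden oracle mode, not a user setting),
  the deposition curve equals `min(1, v t / h)` up to the empirical-CDF
  fluctuation of the uniform initial sample (≤ 2/√n);
* flotation mirrors sedimentation: flipping the sign of the density
  difference and mirroring the absorbing plane to the top reproduces the
  deposition curve within binomial error;
* conservation (fates partition the ensemble) and monotonicity of absorbed
  counts hold exactly at every snapshot.

Problem sizes in the routine checks (10,000 particles, 24 h simulated,
15-min snapshots) follow the recommended defaults and keep the whole suite
in the tens of seconds on one core.

## Limitations

Spherical particles with time-invariant size and density (no agglomeration
kinetics, dissolution or ion release); no slip correction, hindered settling,
particle–particle interaction or convection; a flat free surface (no
meniscus) and constant column height (no evaporation); no transwell inserts.
The wall region above the cell band reflects — whether a bare upper wall
should instead adsorb particles is particle-specific and out of scope. The
browser-style interactive 3D visualization of the original tool is replaced
by static plots of the same snapshot data.
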