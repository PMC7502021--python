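import numpy as np
import pytest

from welldose import (
    ParticleEnsemble,
    SimControls,
    initial_positions,
    run,
    simulate_ensemble,
)
from welldose.simulator import (
    FATE_BOTTOM,
    FATE_SUSPENDED,
    FATE_SURFACE,
    FATE_WALL,
    apply_boundaries,
    default_time_step,
    step,
)


def monodisperse(n, D, v):
    return ParticleEnsemble(
        diameter=np.full(n, 1e-7),
        diffusion=np.full(n, D),
        velocity=np.full(n, v),
    )


class TestInitialPositions:
    def test_uniform_moments(self, geom_96_flat):
        pos = initial_positions(geom_96_flat, 10_000, seed=0)
        h, R = geom_96_flat.height_m, geom_96_flat.radius_m
        z = pos[:, 2]
        se_z = h / np.sqrt(12 * len(z))
        assert abs(z.mean() - h / 2) < 3 * se_z
        r2 = pos[:, 0] ** 2 + pos[:, 1] ** 2
        se_r2 = r2.std(ddof=1) / np.sqrt(len(r2))
        assert abs(r2.mean() - R**2 / 2) < 3 * se_r2

    def test_support_inside_domain(self, geom_96_flat):
        pos = initial_positions(geom_96_flat, 5000, seed=1)
        r = np.hypot(pos[:, 0], pos[:, 1])
        assert np.all(r < geom_96_flat.radius_m)
        assert np.all((pos[:, 2] > 0) & (pos[:, 2] < geom_96_flat.height_m))


class TestStep:
    def test_drift_only_limit_is_deterministic(self):
        rng = np.random.default_rng(0)
        pos = np.zeros((5, 3))
        out = step(pos, np.zeros(5), np.full(5, 2e-7), dt=100.0, rng=rng)
        np.testing.assert_allclose(out[:, 2], -2e-5)
        np.testing.assert_allclose(out[:, :2], 0.0)

    def test_buoyant_drift_raises_z(self):
        rng = np.random.default_rng(0)
        pos = np.zeros((5000, 3))
        out = step(pos, np.full(5000, 1e-12), np.full(5000, -2e-7), dt=100.0, rng=rng)
        se = out[:, 2].std(ddof=1) / np.sqrt(5000)
        assert abs(out[:, 2].mean() - 2e-5) < 3 * se

    def test_displacement_variance_matches_diffusion(self):
        rng = np.random.default_rng(3)
        D, dt, n = 5e-12, 60.0, 20_000
        out = step(np.zeros((n, 3)), np.full(n, D), np.zeros(n), dt, rng)
        for ax in range(3):
            var = out[:, ax].var(ddof=1)
            se = var * np.sqrt(2 / (n - 1))
            assert abs(var - 2 * D * dt) < 3 * se


class TestBoundaries:
    def boundary_case(self, geom, pos, v, **kw):
        positions = np.array(pos, dtype=float)
        n = len(positions)
        fates = np.zeros(n, dtype=np.int8)
        fate_time = np.full(n, np.nan)
        apply_boundaries(
            positions, fates, fate_time, np.arange(n), np.asarray(v, float),
            geom, time_h=1.0, **kw,
        )
        return positions, fates, fate_time

    def test_bottom_absorption_clamps_to_zero(self, geom_96_flat):
        pos, fates, ft = self.boundary_case(
            geom_96_flat, [[0.0, 0.0, -1e-5]], [1e-7]
        )
        assert fates[0] == FATE_BOTTOM
        assert pos[0, 2] == 0.0
        assert ft[0] == 1.0

    def test_wall_absorption_inside_band(self, geom_96_caco2):
        R = geom_96_caco2.radius_m
        pos, fates, _ = self.boundary_case(
            geom_96_caco2, [[R * 1.01, 0.0, 0.002]], [1e-7]
        )
        assert fates[0] == FATE_WALL
        assert np.hypot(pos[0, 0], pos[0, 1]) == pytest.approx(R)

    def test_lateral_reflection_above_band(self, geom_96_caco2):
        R = geom_96_caco2.radius_m
        z_above = geom_96_caco2.wall_band_m * 1.05
        pos, fates, _ = self.boundary_case(
            geom_96_caco2, [[R * 1.01, 0.0, z_above]], [1e-7]
        )
        assert fates[0] == FATE_SUSPENDED
        assert np.hypot(pos[0, 0], pos[0, 1]) == pytest.approx(0.99 * R)

    def test_no_wall_absorption_without_band(self, geom_96_flat):
        R = geom_96_flat.radius_m
        pos, fates, _ = self.boundary_case(
            geom_96_flat, [[R * 1.01, 0.0, 0.0001]], [1e-7]
        )
        assert fates[0] == FATE_SUSPENDED  # reflected, never absorbed

    def test_top_reflects_sedimenting_particle(self, geom_96_flat):
        h = geom_96_flat.height_m
        pos, fates, _ = self.boundary_case(
            geom_96_flat, [[0.0, 0.0, h * 1.01]], [1e-7]
        )
        assert fates[0] == FATE_SUSPENDED
        assert pos[0, 2] == pytest.approx(0.99 * h)

    def test_top_absorbs_buoyant_particle(self, geom_96_flat):
        h = geom_96_flat.height_m
        pos, fates, _ = self.boundary_case(
            geom_96_flat, [[0.0, 0.0, h * 1.01]], [-1e-7]
        )
        assert fates[0] == FATE_SURFACE
        assert pos[0, 2] == h

    def test_bottom_takes_precedence_over_wall(self, geom_96_caco2):
        R = geom_96_caco2.radius_m
        _, fates, _ = self.boundary_case(
            geom_96_caco2, [[R * 1.01, 0.0, -1e-6]], [1e-7]
        )
        assert fates[0] == FATE_BOTTOM

    def test_harness_modes_flip_boundaries(self, geom_96_flat):
        h = geom_96_flat.height_m
        pos, fates, _ = self.boundary_case(
            geom_96_flat, [[0.0, 0.0, -1e-5], [0.0, 0.0, h * 1.01]], [1e-7, 1e-7],
            bottom_mode="reflect", top_mode="absorb",
        )
        assert fates[0] == FATE_SUSPENDED
        assert pos[0, 2] == pytest.approx(1e-5)
        assert fates[1] == FATE_SURFACE


class TestControls:
    def test_snapshot_times_include_endpoints(self):
        ctl = SimControls(total_time=24.0, snapshot_fraction=0.25)
        times = ctl.snapshot_times()
        assert len(times) == 97
        assert times[0] == 0.0 and times[-1] == 24.0

    def test_partial_final_interval_appended(self):
        times = SimControls(total_time=1.1, snapshot_fraction=0.25).snapshot_times()
        assert times[-1] == pytest.approx(1.1)
        assert len(times) == 6

    @pytest.mark.parametrize(
        "kw",
        [
            {"total_time": 0.0},
            {"total_time": 1.0, "snapshot_fraction": 2.0},
            {"total_time": 1.0, "n_particles": 0},
            {"total_time": 1.0, "time_step": -1.0},
            {"total_time": 1.0, "time_step": 7200.0},
        ],
    )
    def test_invalid_controls_rejected(self, kw):
        with pytest.raises(ValueError):
            SimControls(**kw)

    def test_default_time_step_limits_displacement(self, geom_96_flat):
        ens = monodisperse(10, 6.6e-12, 2e-7)
        dt = default_time_step(ens, geom_96_flat, 900.0)
        L = geom_96_flat.height_m / 200
        assert np.sqrt(2 * 6.6e-12 * dt) + 2e-7 * dt <= L * (1 + 1e-9)


class TestRun:
    def test_same_seed_bit_identical(self, spec_100nm, medium, geom_96_caco2):
        ctl = SimControls(total_time=1.0, n_particles=300, seed=42)
        a = run(spec_100nm, medium, geom_96_caco2, ctl)
        b = run(spec_100nm, medium, geom_96_caco2, ctl)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.fates, b.fates)

    def test_all_suspended_at_time_zero(self, spec_100nm, medium, geom_96_caco2):
        ctl = SimControls(total_time=0.5, n_particles=200, seed=0)
        res = run(spec_100nm, medium, geom_96_caco2, ctl)
        assert np.all(res.fates[0] == FATE_SUSPENDED)

    def test_conservation_and_monotonicity(self, spec_100nm, medium, geom_96_caco2):
        ctl = SimControls(total_time=4.0, n_particles=1000, seed=9)
        res = run(spec_100nm, medium, geom_96_caco2, ctl)
        counts = res.fate_counts()
        assert np.all(counts.sum(axis=1) == 1000)
        for code in (FATE_BOTTOM, FATE_WALL, FATE_SURFACE):
            assert np.all(np.diff(counts[:, code]) >= 0)

    def test_no_wall_fates_without_band(self, spec_100nm, medium, geom_96_flat):
        ctl = SimControls(total_time=4.0, n_particles=500, seed=2)
        res = run(spec_100nm, medium, geom_96_flat, ctl)
        assert np.all(res.fates != FATE_WALL)

    def test_absorbed_particles_stay_frozen(self, spec_100nm, medium, geom_96_caco2):
        ctl = SimControls(total_time=4.0, n_particles=500, seed=5)
        res = run(spec_100nm, medium, geom_96_caco2, ctl)
        absorbed_at = np.argmax(res.fates != FATE_SUSPENDED, axis=0)
        for p in np.nonzero(absorbed_at > 0)[0][:50]:
            k = absorbed_at[p]
            later = res.positions[k:, p, :]
            assert np.all(later == later[0])

    def test_snapshot_memory_cap(self, spec_100nm, medium, geom_96_flat):
        ctl = SimControls(
            total_time=24.0, n_particles=10_000, seed=0, max_snapshot_bytes=1000
        )
        with pytest.raises(MemoryError, match="snapshot"):
            run(spec_100nm, medium, geom_96_flat, ctl)

    def test_ensemble_size_must_match_controls(self, geom_96_flat):
        ctl = SimControls(total_time=1.0, n_particles=10)
        with pytest.raises(ValueError, match="does not match"):
            simulate_ensemble(monodisperse(5, 1e-12, 0.0), geom_96_flat, ctl)
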