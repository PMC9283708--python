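"""Growth-dynamics checks: death/birth statistics, Euler-Maruyama motion
against closed forms and an adaptive Runge-Kutta oracle, admissibility,
and seed determinism."""

import numpy as np
import pytest

from tumornet import (
    CellConfiguration,
    SimulationParams,
    birth_sweep,
    death_sweep,
    is_admissible,
    move_sweep,
    run_simulation,
    run_surviving_replicates,
)
from tumornet.dynamics import ExtinctionCapError
from tumornet import fixture_hexagonal
from oracles import separation_ode_solution


def grid_config(n_side, spacing):
    xs, ys = np.meshgrid(np.arange(n_side), np.arange(n_side))
    pos = np.column_stack([xs.ravel(), ys.ravel()]) * spacing
    return CellConfiguration(0.0, pos.astype(float), np.arange(n_side**2))


class TestDeathSweep:
    def test_zero_rate_is_identity(self, rng):
        config = grid_config(5, 2.0)
        params = SimulationParams(delta=0.0, death_rate=0.0)
        out = death_sweep(config, params, rng)
        assert np.array_equal(out.ids, config.ids)
        assert np.array_equal(out.positions, config.positions)

    def test_certain_death_empties_population(self, rng):
        config = grid_config(4, 2.0)
        params = SimulationParams(delta=0.0, death_rate=1.0, dt=1.0, birth_rate=1.0)
        assert death_sweep(config, params, rng).n_cells == 0

    def test_survival_fraction_matches_binomial_law(self, rng):
        n = 100_000
        config = CellConfiguration(0.0, rng.random((n, 2)) * 2000, np.arange(n))
        params = SimulationParams(delta=0.0, death_rate=0.1, dt=1e-3)
        out = death_sweep(config, params, rng)
        p = 1e-4
        se = np.sqrt(p * (1 - p) / n)
        assert out.n_cells / n == pytest.approx(1 - p, abs=3 * se)


class FakeRng:
    """Deterministic stand-in: first uniform block triggers proliferation,
    subsequent scalars give the requested angles."""

    def __init__(self, angles):
        self.angles = list(angles)

    def random(self, n=None):
        if n is not None:
            return np.zeros(n)  # every cell proliferates (u < p)
        return self.angles.pop(0) / (2 * np.pi)


class TestBirthSweep:
    def test_daughter_at_unit_distance_at_drawn_angle(self):
        config = CellConfiguration(0.0, np.zeros((1, 2)), np.array([0]))
        params = SimulationParams(delta=0.0, birth_rate=1.0, dt=1.0)
        out = birth_sweep(config, params, FakeRng([0.0]))
        assert out.n_cells == 2
        assert out.positions[1] == pytest.approx([1.0, 0.0])

    def test_zero_rate_no_births(self, rng):
        config = grid_config(3, 2.0)
        params = SimulationParams(delta=0.0, birth_rate=0.0)
        assert birth_sweep(config, params, rng).n_cells == config.n_cells

    def test_kissing_shell_always_rejects_birth(self, rng):
        # every daughter position of the central mother is within
        # 2*sin(15 deg) ~ 0.518 < 0.8 of some ring cell
        config = fixture_hexagonal(1)
        params = SimulationParams(delta=0.0, birth_rate=1.0, dt=1.0, max_retries=100)

        class CenterOnly:
            """Only the central cell (id 0, at the origin) proliferates."""

            def __init__(self, inner):
                self.inner = inner

            def random(self, n=None):
                if n is not None:
                    u = np.ones(n)
                    u[0] = 0.0
                    return u
                return self.inner.random()

        out = birth_sweep(config, params, CenterOnly(rng))
        assert out.n_cells == 7

    def test_daughters_are_at_least_floor_from_everyone(self, rng):
        config = grid_config(4, 1.2)
        params = SimulationParams(delta=0.0, birth_rate=1.0, dt=0.5)
        out = birth_sweep(config, params, rng)
        out.validate(params.overlap_floor)

    def test_birth_count_binomial_in_sparse_gas(self, rng):
        config = grid_config(100, 10.0)  # 10^4 mothers, no crowding
        p = 0.01
        params = SimulationParams(delta=0.0, birth_rate=10.0, dt=1e-3)
        out = birth_sweep(config, params, rng)
        births = out.n_cells - config.n_cells
        n = config.n_cells
        assert births == pytest.approx(n * p, abs=3 * np.sqrt(n * p * (1 - p)))


class TestIsAdmissible:
    def test_empty_system_accepts_anything(self):
        assert is_admissible(np.empty((0, 2)), (5.0, 5.0))

    @pytest.mark.parametrize(
        "dist,expected", [(0.85, True), (0.80, True), (0.75, False)]
    )
    def test_floor_is_inclusive(self, dist, expected):
        pos = np.array([[0.0, 0.0]])
        assert is_admissible(pos, (dist, 0.0)) is expected


class TestMoveSweep:
    def test_single_cell_msd_matches_free_diffusion(self, rng):
        # 10^4 one-step displacements: <|dr|^2> = 4 D dt in 2-D
        params = SimulationParams(delta=0.0, dt=1e-3)
        disps = []
        for _ in range(10_000):
            config = CellConfiguration(0.0, np.zeros((1, 2)), np.array([0]))
            out = move_sweep(config, params, rng)
            disps.append(np.sum(out.positions[0] ** 2))
        disps = np.array(disps)
        expected = 4 * params.diffusion * params.dt
        se = disps.std(ddof=1) / np.sqrt(len(disps))
        assert disps.mean() == pytest.approx(expected, abs=3 * se)

    def test_two_cell_separation_matches_rk_oracle(self):
        # noise-free pair collapse: Euler path vs adaptive Runge-Kutta
        delta, sigma, r0 = 1.0, 1.5, 3.5
        params = SimulationParams(delta=delta, sigma=sigma, diffusion=0.0, dt=1e-3)
        config = CellConfiguration(
            0.0, np.array([[-r0 / 2, 0.0], [r0 / 2, 0.0]]), np.arange(2)
        )
        rng = np.random.default_rng(0)
        n_steps = 5000
        seps = [r0]
        for _ in range(n_steps):
            config = move_sweep(config, params, rng)
            seps.append(float(np.hypot(*(config.positions[1] - config.positions[0]))))
        t = np.arange(n_steps + 1) * params.dt
        oracle = separation_ode_solution(delta, sigma, r0, t)
        assert oracle[-1] > 1.0  # trajectory stays in the tabulated regime
        assert np.abs(np.array(seps) - oracle).max() < 1e-3

    def test_admissibility_preserved_under_crowding(self, rng):
        config = fixture_hexagonal(3)  # dense 37-cell packing
        params = SimulationParams(delta=2.0, dt=1e-3)
        for _ in range(200):
            config = move_sweep(config, params, rng)
            config.validate(params.overlap_floor)

    def test_time_advances_by_dt(self, rng):
        config = CellConfiguration(1.0, np.zeros((1, 2)), np.array([0]))
        params = SimulationParams(delta=0.0, dt=0.25)
        assert move_sweep(config, params, rng).time == pytest.approx(1.25)


class TestRunSimulation:
    def test_lone_immortal_cell_diffuses_freely(self):
        # no birth, no death, no attraction: MSD(t) ~ 4 D t across replicates
        t_final, n_reps = 0.5, 200
        sq = []
        for seed in range(n_reps):
            params = SimulationParams(
                delta=0.0, birth_rate=0.0, death_rate=0.0, n_steps=500, seed=seed
            )
            rec = run_simulation(params)
            assert rec.final.n_cells == 1
            sq.append(np.sum(rec.final.positions[0] ** 2))
        sq = np.array(sq)
        se = sq.std(ddof=1) / np.sqrt(n_reps)
        assert sq.mean() == pytest.approx(4 * t_final, abs=3 * se)

    def test_default_parameters_run_and_record(self):
        params = SimulationParams(delta=1.5, n_steps=600, seed=5, snapshot_every=200)
        rec = run_simulation(params)
        assert rec.extinct == (rec.final.n_cells == 0)
        assert rec.population_counts[0] == 1
        assert len(rec.population_times) == len(rec.population_counts)
        if not rec.extinct:
            assert rec.snapshots and rec.snapshots[-1].time == pytest.approx(rec.final.time)
            rec.final.validate(params.overlap_floor)

    def test_same_seed_bitwise_identical(self):
        params = SimulationParams(delta=1.2, n_steps=400, seed=77)
        a = run_simulation(params)
        b = run_simulation(params)
        assert np.array_equal(a.final.positions, b.final.positions)
        assert np.array_equal(a.final.ids, b.final.ids)
        assert np.array_equal(a.population_counts, b.population_counts)

    def test_invalid_params_rejected_before_stepping(self):
        with pytest.raises(ValueError):
            SimulationParams(delta=1.0, dt=2.0, death_rate=1.0)  # gamma*dt > 1


class TestSurvivingReplicates:
    def test_immortal_population_needs_no_extras(self):
        params = SimulationParams(delta=0.5, death_rate=0.0, n_steps=50, seed=3)
        recs = run_surviving_replicates(params, 3)
        assert len(recs) == 3
        seeds = [r.params.seed for r in recs]
        assert seeds == [3, 4, 5]

    def test_certain_extinction_hits_safety_cap(self):
        params = SimulationParams(
            delta=0.5, death_rate=1.0, dt=1.0, birth_rate=1.0, n_steps=10, seed=0
        )
        with pytest.raises(ExtinctionCapError):
            run_surviving_replicates(params, 2)

    def test_default_smoke_collects_distinct_survivors(self):
        params = SimulationParams(delta=1.5, n_steps=300, seed=11)
        recs = run_surviving_replicates(params, 5)
        assert len(recs) == 5
        assert all(not r.extinct for r in recs)
        assert len({r.params.seed for r in recs}) == 5
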