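"""Movement, demographic update, and full-run behavior of the engine."""

import numpy as np
import pytest

import fishscape.engine as eng
from fishscape.demography import make_vital_rates
from fishscape.engine import (
    AgentState,
    GridLevels,
    SimConfig,
    annual_demographic_update,
    enumerate_scenarios,
    initialize_population,
    movement_step,
    realized_suitability,
    run_scenario_grid,
    run_simulation,
)
from fishscape.fixtures import make_fixture_world
from fishscape.landscape import make_gradient_landscape
from fishscape.niche import NicheModel, draw_preferences

STRONG = NicheModel.from_mode("strong")


def empty_state():
    return AgentState(
        np.array([], dtype=np.int64), np.array([]), np.array([], dtype=np.int64)
    )


class TestRealizedSuitability:
    @pytest.mark.parametrize(
        "h,z,n,k,expected",
        [
            (0.5, 0.5, 0, 40, 1.0),  # perfect match, no crowding
            (0.3, 0.5, 20, 40, 0.3),  # 1 - 0.2 - 0.5
            (0.7, 0.7, 40, 40, 0.0),  # density term saturates at capacity
        ],
    )
    def test_formula(self, h, z, n, k, expected):
        assert realized_suitability(h, z, n, k) == pytest.approx(expected)

    def test_may_be_negative(self):
        assert realized_suitability(0.0, 1.0, 10, 5) < 0

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            realized_suitability(0.5, 0.5, 1, 0)


class TestInitialization:
    def test_hundred_fish_per_age_class(self, rng):
        cfg = SimConfig()
        grid = make_gradient_landscape(cfg.carrying_capacity)
        state = initialize_population(cfg, STRONG, grid, rng)
        assert len(state) == 900
        assert np.all(np.bincount(state.ages)[1:] == 100)

    def test_preferences_respect_age_niches(self, rng):
        cfg = SimConfig()
        grid = make_gradient_landscape(cfg.carrying_capacity)
        state = initialize_population(cfg, STRONG, grid, rng)
        lo = STRONG.interval_lo[state.ages - 1]
        hi = STRONG.interval_hi[state.ages - 1]
        assert np.all((state.preference >= lo) & (state.preference <= hi))

    def test_seeded_initialization_repeats(self):
        cfg = SimConfig()
        grid = make_gradient_landscape(cfg.carrying_capacity)
        a = initialize_population(cfg, STRONG, grid, np.random.default_rng(5))
        b = initialize_population(cfg, STRONG, grid, np.random.default_rng(5))
        assert np.array_equal(a.cell, b.cell) and np.array_equal(a.preference, b.preference)


class TestMovement:
    def test_strict_improvement_forces_move(self, rng):
        grid, state, _ = make_fixture_world([[0.0, 1.0]], [(1, 1.0, (0, 0))])
        new = movement_step(state, grid, rng)
        assert new.cell[0] == 1  # only neighbor, strictly better

    def test_equal_suitability_keeps_fish_in_place(self, rng):
        # two identical cells, one fish each: candidate R equals current R
        grid, state, _ = make_fixture_world(
            [[0.5, 0.5]], [(1, 0.5, (0, 0)), (1, 0.5, (0, 1))], carrying_capacity=10
        )
        for _ in range(20):
            state = movement_step(state, grid, rng)
        assert np.array_equal(np.sort(state.cell), [0, 1])

    def test_movement_conserves_population_and_traits(self, rng):
        cfg = SimConfig()
        grid = make_gradient_landscape(cfg.carrying_capacity)
        state = initialize_population(cfg, STRONG, grid, rng)
        before = state
        for _ in range(10):
            after = movement_step(state, grid, rng)
            assert len(after) == len(before)
            assert np.array_equal(after.ages, before.ages)
            assert np.array_equal(after.preference, before.preference)
            assert after.occupancy(grid.n_cells).sum() == len(before)
            # synchronous single-step moves: at most one cell in Chebyshev distance
            dr = np.abs(after.cell // grid.width - state.cell // grid.width)
            dc = np.abs(after.cell % grid.width - state.cell % grid.width)
            assert np.all(np.maximum(dr, dc) <= 1)
            state = after

    def test_empty_state_is_a_noop(self, rng):
        grid = make_gradient_landscape(40)
        assert len(movement_step(empty_state(), grid, rng)) == 0


class TestAnnualUpdate:
    def test_newborn_count_matches_binomial_expectation(self):
        # E[recruits] = sum_i R_i N_i, checked by Monte-Carlo at 400 reps
        vr = make_vital_rates(0.0)
        ages = np.repeat(np.arange(1, 10), 100)
        z = draw_preferences(STRONG, ages, np.random.default_rng(0))
        cells = np.zeros(len(ages), dtype=np.int64)
        expected = float(np.sum(vr.reproduction * 100))
        counts = []
        master = np.random.default_rng(42)
        for _ in range(400):
            state = AgentState(ages, z, cells)
            new = annual_demographic_update(state, vr, STRONG, master)
            counts.append(int(np.sum(new.ages == 1)))
        counts = np.asarray(counts)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_newborns_inherit_mother_cells(self, rng):
        grid, state, vr = make_fixture_world(
            [[0.2, 0.8]], [(1, 0.3, (0, 0))] * 50, reproduction=1.0, natural_mortality=1.0
        )
        new = annual_demographic_update(state, vr, STRONG, rng)
        assert np.all(new.ages == 1)  # parents all died, newborns survive
        assert np.all(new.cell == 0)
        assert len(new) == 50

    def test_age_nine_never_survives(self, rng):
        _, state, vr = make_fixture_world(
            [[0.5, 0.5]], [(9, 0.5, (0, 0))] * 200, reproduction=0.01
        )
        new = annual_demographic_update(state, vr, STRONG, rng)
        assert np.all(new.ages == 1)  # only Bernoulli(0.01) newborns remain
        assert len(new) < 20

    def test_degenerate_rates_only_increment_ages(self, rng):
        _, state, vr = make_fixture_world(
            [[0.5, 0.5]], [(a, 0.5, (0, 0)) for a in (1, 3, 8, 9)]
        )
        new = annual_demographic_update(state, vr, STRONG, rng)
        assert sorted(new.ages) == [2, 4, 9]  # age 9 dies even at M=0

    def test_total_mortality_empties_population(self, rng):
        _, state, vr = make_fixture_world(
            [[0.5, 0.5]], [(a, 0.5, (0, 0)) for a in range(1, 10)], natural_mortality=1.0
        )
        assert len(annual_demographic_update(state, vr, STRONG, rng)) == 0

    def test_aged_fish_redraw_preference_from_new_niche(self, rng):
        _, state, vr = make_fixture_world([[0.5, 0.5]], [(1, 0.1, (0, 0))] * 100)
        new = annual_demographic_update(state, vr, STRONG, rng)
        lo, hi = STRONG.interval_lo[1], STRONG.interval_hi[1]
        assert np.all((new.preference >= lo) & (new.preference <= hi))


class TestRunSimulation:
    def test_fifteen_annual_records(self):
        out = run_simulation(SimConfig(seed=9))
        assert out.abundance.shape == (15, 121, 9)
        assert np.all(out.abundance >= 0)
        assert out.extinct_year is None

    def test_identical_seed_gives_bit_identical_output(self):
        a = run_simulation(SimConfig(landscape="fragmented", seed=4, replicate=2))
        b = run_simulation(SimConfig(landscape="fragmented", seed=4, replicate=2))
        assert np.array_equal(a.abundance, b.abundance)

    def test_replicates_differ(self):
        a = run_simulation(SimConfig(seed=4, replicate=0))
        b = run_simulation(SimConfig(seed=4, replicate=1))
        assert not np.array_equal(a.abundance, b.abundance)

    def test_extinction_records_zeros_and_flag(self, monkeypatch):
        monkeypatch.setattr(
            eng, "annual_demographic_update", lambda s, vr, m, r: empty_state()
        )
        out = run_simulation(SimConfig(years=5, steps_per_year=2, seed=1))
        assert out.extinct_year == 2
        assert out.abundance[0].sum() == 900
        assert out.abundance[1:].sum() == 0

    def test_unconstrained_fish_reach_preferred_column(self):
        # huge K: by the 40th step nearly all fish sit at a nearest-|H-Z| cell
        from fishscape.landscape import HABITAT_LEVELS, neighbor_table

        cfg = SimConfig(carrying_capacity=1e6, seed=3)
        rng = eng.simulation_rng(cfg)
        grid = eng.build_landscape(cfg, rng)
        state = initialize_population(cfg, STRONG, grid, rng)
        nbr = neighbor_table(grid.height, grid.width)
        for _ in range(cfg.steps_per_year):
            state = movement_step(state, grid, rng, nbr)
        h = grid.habitat_flat[state.cell]
        nearest = HABITAT_LEVELS[
            np.argmin(np.abs(HABITAT_LEVELS[None, :] - state.preference[:, None]), axis=1)
        ]
        assert np.mean(np.isclose(h, nearest)) >= 0.95

    def test_population_quasi_stationary_after_transient(self):
        # stochastic window mean tracks the deterministic Leslie projection
        from fishscape.demography import build_leslie

        a = build_leslie(make_vital_rates(0.0))
        n = np.full(9, 100.0)
        det = []
        for _ in range(15):
            det.append(n.sum())
            n = a @ n
        det_window = np.mean(det[4:15])
        pops = []
        for rep in range(10):
            out = run_simulation(SimConfig(seed=11, replicate=rep))
            pops.append(out.abundance[4:15].sum(axis=(1, 2)).mean())
        assert np.mean(pops) == pytest.approx(det_window, rel=0.15)

    def test_fishing_truncates_old_ages(self):
        def window_age_means(f):
            reps = [
                run_simulation(SimConfig(fishing_mortality=f, seed=21, replicate=r))
                for r in range(3)
            ]
            return np.mean([o.abundance[4:15].sum(axis=1).mean(axis=0) for o in reps], axis=0)

        unfished = window_age_means(0.0)
        fished = window_age_means(0.5)
        assert np.all(np.diff(unfished) < 0)  # right-skewed age structure
        assert np.all(fished[4:] < unfished[4:])  # ages 5-9 depressed by fishing

    def test_strong_preference_segregates_age_classes(self):
        # mean pairwise overlap of age-specific cell distributions at high K
        def mean_overlap(mode):
            out = run_simulation(
                SimConfig(preference=mode, carrying_capacity=160, seed=31)
            )
            rec = out.abundance[14].astype(float)  # (cells, ages)
            totals = rec.sum(axis=0)
            p = rec[:, totals > 0] / totals[totals > 0]
            k = p.shape[1]
            overlaps = [
                np.minimum(p[:, i], p[:, j]).sum()
                for i in range(k)
                for j in range(i + 1, k)
            ]
            return np.mean(overlaps)

        assert mean_overlap("strong") < mean_overlap("weak")


class TestScenarioGrid:
    def test_full_factorial_has_144_scenarios(self):
        assert len(enumerate_scenarios()) == 144

    def test_reduced_factorial_counts(self):
        levels = GridLevels(
            fishing_mortalities=(0.0,), landscapes=("gradient",), carrying_capacities=(40,)
        )
        df = run_scenario_grid(levels, replicates=3, master_seed=1, years=6)
        assert len(df) == 2 * 1 * 1 * 1 * 3  # preferences x F x landscape x K x reps
        assert set(df["preference"]) == {"strong", "weak"}

    def test_grid_replicate_matches_standalone_run(self):
        # stream splitting: replicate 2 of a grid equals the standalone run
        levels = GridLevels(
            preferences=("strong",),
            fishing_mortalities=(0.2,),
            landscapes=("fragmented",),
            carrying_capacities=(40,),
        )
        df = run_scenario_grid(levels, replicates=3, master_seed=7)
        cfg = SimConfig(
            preference="strong",
            fishing_mortality=0.2,
            landscape="fragmented",
            carrying_capacity=40,
            seed=7,
            replicate=2,
        )
        from fishscape.summaries import summarize_replicate

        stand_alone = summarize_replicate(run_simulation(cfg))
        row = df[df["replicate"] == 2].iloc[0]
        assert row["mean_cv"] == pytest.approx(stand_alone.mean_cv)
        assert row["mean_shannon"] == pytest.approx(stand_alone.mean_shannon)

    def test_invalid_replicates_rejected(self):
        with pytest.raises(ValueError):
            run_scenario_grid(replicates=0)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimConfig(preference="medium")
    with pytest.raises(ValueError):
        SimConfig(carrying_capacity=-1)
    with pytest.raises(ValueError):
        SimConfig(landscape="island")
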