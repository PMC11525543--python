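"""Arena initialization, the cycle pipeline, and its conservation laws."""

import numpy as np
import pytest

from holoflux.arena import (CellAgent, SimulationConfig, init_arena,
                            lysis_release, mass_balance_report, run_simulation,
                            step)
from holoflux.environment import build_seawater_medium
from holoflux.symbiont_models import MOLAR_MASS


def small_config(**overrides):
    base = dict(grid_count=100, rows=10, cols=10, cycles=5, rng_seed=7)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="module")
def models(autotroph, heterotroph):
    return [autotroph, heterotroph]


class TestInit:
    def test_default_agent_count_and_apportionment(self, models, seawater):
        config = SimulationConfig()
        arena = init_arena(models, seawater, config,
                           np.random.default_rng(0))
        assert arena.occupied.size == 1600
        assert (arena.occupied >= 0).sum() == 1520  # round(0.95 * 1600)
        assert arena.count("autotroph") == 1451  # largest-remainder on 94.6/4.5
        assert arena.count("heterotroph") == 69

    def test_zero_occupancy_runs_empty(self, models, seawater):
        config = small_config(initial_occupancy=0.0)
        trajectory, arena = run_simulation(models, seawater, config)
        assert (trajectory.populations["count"] == 0).all()

    def test_occupancy_above_one_rejected(self, models, seawater):
        with pytest.raises(ValueError):
            init_arena(models, seawater, small_config(initial_occupancy=1.2),
                       np.random.default_rng(0))

    def test_grid_geometry_must_be_consistent(self):
        with pytest.raises(ValueError, match="rows"):
            small_config(rows=7).validate()

    def test_fields_charged_with_medium_amounts(self, models, seawater):
        config = small_config()
        arena = init_arena(models, seawater, config, np.random.default_rng(0))
        expected = seawater.concentrations["nh4_e"] * config.grid_volume_L
        assert np.allclose(arena.fields["nh4_e"], expected)


class TestStep:
    def test_single_autotroph_grows_and_draws_down_ammonium(self, models,
                                                            seawater):
        config = small_config(
            initial_occupancy=0.01,  # one agent
            initial_abundances={"autotroph": 1.0, "heterotroph": 0.0})
        rng = np.random.default_rng(3)
        arena = init_arena(models, seawater, config, rng)
        (pos,) = [tuple(rc) for rc in np.argwhere(arena.occupied == 0)]
        nh4_before = arena.fields["nh4_e"][pos]
        biomass_before = arena.biomass[pos]
        config.removal_fraction = 0.0
        config.lysis_schedule = [(0, 10 ** 9, 0.0)]
        step(arena, models, config, rng)
        assert arena.biomass[pos] > biomass_before
        # diffusion spreads the dip; total field must have decreased
        assert arena.fields["nh4_e"].sum() < nh4_before * 100

    def test_removal_fraction_one_empties_the_arena(self, models, seawater):
        config = small_config(removal_fraction=1.0)
        rng = np.random.default_rng(0)
        arena = init_arena(models, seawater, config, rng)
        step(arena, models, config, rng)
        assert (arena.occupied >= 0).sum() == 0

    def test_certain_lysis_deposits_b12_locally(self, models, seawater):
        config = small_config(
            initial_occupancy=0.01, growth_enabled=False,
            removal_fraction=0.0,
            initial_abundances={"autotroph": 1.0, "heterotroph": 0.0},
            lysis_schedule=[(0, 10 ** 9, 1.0)])
        rng = np.random.default_rng(1)
        arena = init_arena(models, seawater, config, rng)
        assert arena.fields["b12_e"].sum() == 0.0
        step(arena, models, config, rng)
        assert (arena.occupied >= 0).sum() == 0
        assert arena.fields["b12_e"].sum() > 0
        assert arena.fields["orgmat_e"].sum() > 0

    def test_occupancy_never_exceeds_grid_count(self, models, seawater):
        config = small_config(cycles=8, initial_occupancy=1.0)
        trajectory, _ = run_simulation(models, seawater, config)
        totals = trajectory.populations.groupby("cycle")["count"].sum()
        assert (totals <= config.grid_count).all()


class TestLysisRelease:
    COMPOSITION = {"orgmat_e": 0.9999, "b12_e": 1e-4}

    def test_direct_arithmetic(self):
        agent = CellAgent("autotroph", 1.0, (0, 0))
        out = lysis_release(agent, self.COMPOSITION, 1.0, MOLAR_MASS_E)
        assert out["b12_e"] == pytest.approx(1e-4 * 1000 / 1355.4)
        released_mass = sum(v * MOLAR_MASS_E[k] / 1000 for k, v in out.items())
        assert released_mass == pytest.approx(1.0)

    def test_zero_efficiency_releases_nothing(self):
        agent = CellAgent("autotroph", 1.0, (0, 0))
        out = lysis_release(agent, self.COMPOSITION, 0.0, MOLAR_MASS_E)
        assert all(v == 0.0 for v in out.values())

    def test_release_is_linear_in_biomass(self):
        one = lysis_release(CellAgent("a", 1.0, (0, 0)), self.COMPOSITION,
                            1.0, MOLAR_MASS_E)
        two = lysis_release(CellAgent("a", 2.0, (0, 0)), self.COMPOSITION,
                            1.0, MOLAR_MASS_E)
        for met in one:
            assert two[met] == pytest.approx(2 * one[met])

    def test_missing_molar_mass_is_an_error(self):
        agent = CellAgent("a", 1.0, (0, 0))
        with pytest.raises(ValueError, match="molar mass"):
            lysis_release(agent, {"mystery_e": 1.0}, 1.0, MOLAR_MASS_E)

    def test_composition_must_sum_to_one(self):
        agent = CellAgent("a", 1.0, (0, 0))
        with pytest.raises(ValueError, match="sum"):
            lysis_release(agent, {"orgmat_e": 0.5}, 1.0, MOLAR_MASS_E)


MOLAR_MASS_E = {f"{k}_e": v for k, v in MOLAR_MASS.items()}


class TestDeterminismAndConservation:
    def test_identical_seed_gives_identical_trajectory(self, models, seawater):
        t1, _ = run_simulation(models, seawater, small_config(cycles=6))
        t2, _ = run_simulation(models, seawater, small_config(cycles=6))
        assert t1.populations.equals(t2.populations)
        assert t1.exchange_fluxes.equals(t2.exchange_fluxes)
        assert t1.medium_totals.equals(t2.medium_totals)

    def test_different_seed_changes_the_run(self, models, seawater):
        t1, _ = run_simulation(models, seawater, small_config(cycles=6))
        t2, _ = run_simulation(models, seawater,
                               small_config(cycles=6, rng_seed=8))
        assert not t1.populations.equals(t2.populations)

    def test_no_lysis_no_b12_heterotroph_never_grows(self, models, seawater):
        config = small_config(cycles=10,
                              lysis_schedule=[(0, 10 ** 9, 0.0)])
        trajectory, _ = run_simulation(models, seawater, config)
        counts = trajectory.counts_wide()["heterotroph"]
        assert (counts.diff().dropna() <= 0).all()

    def test_mass_balance_closes_in_closed_arena(self, models, seawater):
        config = small_config(cycles=5, lysis_release_efficiency=1.0)
        report = mass_balance_report(models, seawater, config)
        total_biomass_scale = 100 * config.unit_biomass_gdw
        assert (report.biomass_error_gdw < 1e-9 * total_biomass_scale).all()
        assert (report.pool_error_mmol < 1e-12).all()
        assert (report.released_mass_gdw == report.lysed_biomass_gdw).all()
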