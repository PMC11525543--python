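"""LP flux balance analysis against independent oracles and its invariants."""

import math

import numpy as np
import pytest

from holoflux.fba import (ZERO_TOL, growth_feasible, minimal_requirement,
                          solve_fba)
from holoflux.netcore import build_stoichiometric_matrix
from holoflux.synthetic_data import enumerate_fba_optimum, generate_toy_network

from conftest import make_chain_model


class TestChainOracle:
    def test_unit_yield_chain_growth_equals_uptake(self, chain_model):
        sol = solve_fba(chain_model, {"A_e": 10.0})
        assert sol.status == "optimal"
        assert sol.growth_rate == pytest.approx(10.0, abs=1e-8)
        # export-positive convention: uptake appears as negative exchange flux
        assert sol.fluxes["EX_A"] == pytest.approx(-10.0, abs=1e-8)

    @pytest.mark.parametrize("yield_coef,demand,expected",
                             [(1.0, 1.0, 10.0), (2.0, 1.0, 20.0),
                              (0.5, 1.0, 5.0), (1.0, 2.0, 5.0)])
    def test_yields_scale_linearly(self, yield_coef, demand, expected):
        model = make_chain_model(yield_coef=yield_coef, demand=demand)
        assert solve_fba(model, {"A_e": 10.0}).growth_rate == pytest.approx(
            expected, abs=1e-8)

    @pytest.mark.parametrize("k", [0.0, 0.5, 3.0])
    def test_uptake_scaling_scales_growth(self, chain_model, k):
        base = solve_fba(chain_model, {"A_e": 4.0}).growth_rate
        scaled = solve_fba(chain_model, {"A_e": 4.0 * k}).growth_rate
        assert scaled == pytest.approx(k * base, abs=1e-8)

    def test_absent_metabolite_means_zero_uptake(self, chain_model):
        assert solve_fba(chain_model, {}).growth_rate == 0.0


class TestPackagedModels:
    def test_autotroph_starves_without_any_uptake(self, autotroph):
        sol = solve_fba(autotroph, {})
        assert sol.growth_rate == 0.0

    def test_heterotroph_needs_b12(self, heterotroph, seawater_uptake,
                                   seawater_uptake_with_b12):
        assert solve_fba(heterotroph, seawater_uptake).growth_rate == 0.0
        assert solve_fba(heterotroph, seawater_uptake_with_b12).growth_rate > 0.01

    def test_steady_state_closure(self, autotroph, heterotroph,
                                  seawater_uptake_with_b12):
        for model in (autotroph, heterotroph):
            sol = solve_fba(model, seawater_uptake_with_b12)
            S = build_stoichiometric_matrix(model)
            v = np.array([sol.fluxes[r] for r in S.columns])
            assert np.abs(S.to_numpy() @ v).max() <= 1e-6

    def test_determinism(self, heterotroph, seawater_uptake_with_b12):
        a = solve_fba(heterotroph, seawater_uptake_with_b12)
        b = solve_fba(heterotroph, seawater_uptake_with_b12)
        assert a.fluxes == b.fluxes

    def test_unbounded_diagnostic_names_cycle(self, chain_model):
        loop = chain_model.copy()
        # a free generator: B -> 2 B makes biomass unbounded
        from holoflux.netcore import Reaction
        loop.reactions.append(Reaction(
            "LOOP", stoichiometry={"B": 1.0}, lower_bound=0.0,
            upper_bound=math.inf, kind="internal", evidence="synthetic"))
        loop.reactions_by_id["BIOMASS"].upper_bound = math.inf
        sol = solve_fba(loop, {"A_e": 1.0})
        assert sol.status == "unbounded"
        assert "LOOP" in sol.diagnostic


class TestEnumerationOracle:
    @pytest.mark.parametrize("seed", range(120))
    def test_lp_matches_vertex_enumeration(self, seed):
        model, uptake, optimum = generate_toy_network(seed)
        sol = solve_fba(model, uptake, parsimonious=False)
        assert sol.growth_rate == pytest.approx(optimum, abs=1e-6)

    def test_parsimonious_solution_keeps_the_optimum(self):
        for seed in range(25):
            model, uptake, optimum = generate_toy_network(seed)
            sol = solve_fba(model, uptake, parsimonious=True)
            assert sol.growth_rate == pytest.approx(optimum, abs=1e-6)

    def test_monotone_in_uptake_bound(self):
        for seed in range(20):
            model, uptake, _ = generate_toy_network(seed)
            lo = solve_fba(model, {"A_e": uptake["A_e"]}, parsimonious=False)
            hi = solve_fba(model, {"A_e": uptake["A_e"] * 2},
                           parsimonious=False)
            assert hi.growth_rate >= lo.growth_rate - 1e-9


class TestMinimalRequirement:
    def test_linear_chain_threshold_equals_floor(self, chain_model):
        thr = minimal_requirement(chain_model, {}, "A_e", growth_floor=5.0)
        assert thr == pytest.approx(5.0, rel=1e-3)

    def test_auxotrophy_cannot_be_rescued_by_carbon(self, heterotroph,
                                                    seawater_uptake):
        bounds = {k: v for k, v in seawater_uptake.items() if k != "taur_e"}
        assert minimal_requirement(heterotroph, bounds, "taur_e",
                                   growth_floor=1e-3) == math.inf

    def test_threshold_monotone_in_growth_floor(self, autotroph,
                                                seawater_uptake):
        others = {k: v for k, v in seawater_uptake.items() if k != "nh4_e"}
        thresholds = [minimal_requirement(autotroph, others, "nh4_e", floor)
                      for floor in (1e-6, 0.01, 0.05)]
        assert thresholds[0] > 0
        assert thresholds == sorted(thresholds)

    def test_rejects_nonpositive_floor(self, chain_model):
        with pytest.raises(ValueError):
            minimal_requirement(chain_model, {}, "A_e", growth_floor=0.0)


class TestGrowthFeasible:
    def test_autotroph_aerobe_needs_oxygen(self, autotroph, seawater_uptake):
        assert growth_feasible(autotroph, seawater_uptake)
        anoxic = {k: v for k, v in seawater_uptake.items() if k != "o2_e"}
        assert not growth_feasible(autotroph, anoxic)

    def test_heterotroph_on_taurine_and_b12_alone(self, heterotroph,
                                                  seawater_uptake):
        inorganics = {k: seawater_uptake[k]
                      for k in ("o2_e", "nh4_e", "co2_e", "so4_e")}
        assert growth_feasible(heterotroph,
                               {**inorganics, "taur_e": 10.0, "b12_e": 1.0})


class TestCobraCrossCheck:
    def test_growth_agrees_with_cobrapy(self, autotroph, seawater_uptake,
                                        tmp_path):
        """Independent solver route: SBML export -> cobrapy/GLPK optimum."""
        cobra = pytest.importorskip("cobra")
        from holoflux.netcore import export_sbml

        path = tmp_path / "auto.xml"
        export_sbml(autotroph, path)
        cm = cobra.io.read_sbml_model(str(path))
        for rx in cm.reactions:
            if rx.id.startswith("EX_"):
                met = rx.id[3:] + "_e"
                rx.lower_bound = -seawater_uptake.get(met, 0.0)
        expected = solve_fba(autotroph, seawater_uptake).growth_rate
        assert cm.slim_optimize() == pytest.approx(expected, rel=1e-6)
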