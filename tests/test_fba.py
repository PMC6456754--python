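import numpy as np
import pytest

from methyloflux.fba import (ConfigurationError, MaintenanceConfig,
                             OrderConstraint, RatioConstraint, ScenarioConfig,
                             atpm_grid, ratio_sensitivity_scan,
                             robustness_scan, run_scenario_ladder, solve_fba)

from conftest import (TOY_BUILDERS, random_toy_model, toy_atp_waste,
                      toy_branch, toy_chain, toy_maintenance, toy_parallel)
from oracles import brute_force_fba, model_lp_data


class TestSolveFBA:
    def test_toy_chain_growth(self):
        sol = solve_fba(toy_chain())
        assert sol.optimal
        assert sol.growth_rate == pytest.approx(1.0, abs=1e-9)

    def test_ratio_constraint_halves_growth(self):
        # half the uptake forced through the dead-end branch
        sc = ScenarioConfig(ratio_constraints=[
            RatioConstraint("WASTE", "UPT", 0.5)])
        sol = solve_fba(toy_branch(), sc)
        assert sol.growth_rate == pytest.approx(0.5, abs=1e-9)

    def test_mass_balance_residual(self, core_model):
        m = core_model
        sol = solve_fba(m)
        c, A_eq, b_eq, lb, ub = model_lp_data(m)
        v = np.array([sol.fluxes[r.id] for r in m.reactions])
        assert np.abs(A_eq @ v - b_eq).max() < 1e-6

    def test_fluxes_within_bounds(self):
        m = toy_atp_waste()
        sol = solve_fba(m)
        for r in m.reactions:
            assert r.lower_bound - 1e-9 <= sol.fluxes[r.id] \
                <= r.upper_bound + 1e-9

    def test_infeasible_status_empty_fluxes(self):
        m = toy_chain()
        sc = ScenarioConfig(fixed_fluxes={"UPT": 0.0, "BIO": 1.0})
        sol = solve_fba(m, sc)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}
        assert np.isnan(sol.growth_rate)

    def test_unknown_reaction_id_raises(self):
        with pytest.raises(ConfigurationError):
            solve_fba(toy_chain(),
                      ScenarioConfig(fixed_fluxes={"NOPE": 1.0}))

    def test_order_constraint_enforced(self):
        m = toy_parallel()
        sc = ScenarioConfig(
            order_constraints=[OrderConstraint("R1", "R2")],
            fixed_fluxes={"R2": 4.0})
        sol = solve_fba(m, sc)
        assert sol.optimal
        assert sol.fluxes["R1"] >= sol.fluxes["R2"] - 1e-9

    def test_deterministic_objective(self):
        vals = {solve_fba(toy_atp_waste()).growth_rate for _ in range(5)}
        assert len({round(v, 12) for v in vals}) == 1

    def test_min_total_flux_canonicalizes_degenerate_optimum(self):
        m = toy_parallel()
        sol = solve_fba(m, minimize_total_flux=True)
        assert sol.growth_rate == pytest.approx(1.0, abs=1e-9)
        # total |flux| of the canonical solution is minimal: uptake 10,
        # 10 through one/both routes, biomass 1
        total = sum(abs(v) for v in sol.fluxes.values())
        assert total == pytest.approx(21.0, abs=1e-6)

    def test_gam_override_scales_with_growth(self):
        m = toy_maintenance()
        mu0 = solve_fba(m, ScenarioConfig(
            maintenance=MaintenanceConfig(gam=0.0, ngam=0.0))).growth_rate
        # GAM g consumes g ATP (hence g extra A) per unit growth:
        # mu = 10 / (10 + g)
        for g in (5.0, 10.0):
            mu = solve_fba(m, ScenarioConfig(
                maintenance=MaintenanceConfig(gam=g, ngam=0.0))).growth_rate
            assert mu == pytest.approx(10.0 / (10.0 + g), abs=1e-9)
        assert mu0 == pytest.approx(1.0, abs=1e-9)


class TestOracleEquivalence:
    @pytest.mark.parametrize("builder", TOY_BUILDERS,
                             ids=lambda b: b.__name__)
    def test_toys_match_vertex_enumeration(self, builder):
        m = builder()
        expected = brute_force_fba(m)
        sol = solve_fba(m)
        assert expected is not None
        assert sol.growth_rate == pytest.approx(expected, abs=1e-9)

    def test_toy_with_ratio_constraint_matches_oracle(self):
        m = toy_branch()
        expected = brute_force_fba(m, ratio_constraints=[("WASTE", "UPT",
                                                          0.5)])
        sol = solve_fba(m, ScenarioConfig(ratio_constraints=[
            RatioConstraint("WASTE", "UPT", 0.5)]))
        assert sol.growth_rate == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_toys_match_oracle(self, seed):
        m = random_toy_model(np.random.default_rng(seed))
        expected = brute_force_fba(m)
        sol = solve_fba(m)
        if expected is None:
            assert not sol.optimal
        else:
            assert sol.growth_rate == pytest.approx(expected, abs=1e-9)


class TestLadder:
    def test_tightening_uptake_scales_growth(self):
        m = toy_chain()
        scenarios = [ScenarioConfig(name=f"u{u}", fixed_fluxes={"UPT": u})
                     for u in (10, 5, 2)]
        rows = run_scenario_ladder(m, scenarios)
        assert [round(r["growth_rate"], 9) for r in rows] == [1.0, 0.5, 0.2]

    def test_repeated_scenario_idempotent(self):
        m = toy_chain()
        sc = ScenarioConfig(fixed_fluxes={"UPT": 5})
        rows = run_scenario_ladder(m, [sc, sc])
        assert rows[0]["growth_rate"] == pytest.approx(
            rows[1]["growth_rate"], abs=1e-12)

    def test_infeasible_row_reported_ladder_continues(self):
        m = toy_chain()
        scenarios = [
            ScenarioConfig(name="ok", fixed_fluxes={"UPT": 5}),
            ScenarioConfig(name="bad", fixed_fluxes={"UPT": 0, "BIO": 1}),
            ScenarioConfig(name="ok2", fixed_fluxes={"UPT": 2}),
        ]
        rows = run_scenario_ladder(m, scenarios)
        assert [r["status"] for r in rows] == ["optimal", "infeasible",
                                               "optimal"]

    @pytest.mark.parametrize("seed", range(30))
    def test_added_constraint_never_raises_growth(self, seed):
        rng = np.random.default_rng(1000 + seed)
        m = random_toy_model(rng)
        base = solve_fba(m)
        if not base.optimal:
            pytest.skip("random base infeasible")
        rids = [r.id for r in m.reactions]
        kind = rng.integers(0, 2)
        if kind == 0:
            rid = rids[rng.integers(len(rids))]
            cap = float(rng.uniform(0, max(base.fluxes[rid], 0.1)))
            sc = ScenarioConfig(fixed_fluxes={rid: cap})
        else:
            a, b = rng.choice(len(rids), size=2, replace=False)
            sc = ScenarioConfig(ratio_constraints=[
                RatioConstraint(rids[a], rids[b],
                                float(rng.uniform(0.2, 5.0)))])
        constrained = solve_fba(m, sc)
        if constrained.optimal:
            assert constrained.growth_rate <= base.growth_rate + 1e-7

    def test_core_ladder_monotone(self, core_model):
        from methyloflux.pipeline import default_ladder
        rows = run_scenario_ladder(core_model, default_ladder(core_model))
        mus = [r["growth_rate"] for r in rows]
        assert all(s == "optimal" for s in (r["status"] for r in rows))
        assert all(mus[i + 1] <= mus[i] + 1e-7 for i in range(len(mus) - 1))


class TestRobustness:
    def test_scan_uptake_linear_then_stops_at_bound(self):
        m = toy_chain()
        curve = robustness_scan(m, None, "UPT", step=1.0, max_value=10.0)
        assert curve.grid == pytest.approx(list(range(11)))
        assert curve.growth == pytest.approx(
            [0.1 * g for g in curve.grid], abs=1e-9)
        assert curve.max_feasible == pytest.approx(10.0, abs=1e-9)

    def test_scan_stops_at_infeasibility_and_refines(self):
        m = toy_chain()
        # BIO capped at 0.55 => UPT beyond 5.5 infeasible
        m.get_reaction("BIO").upper_bound = 0.55
        curve = robustness_scan(m, None, "UPT", step=1.0, max_value=10.0)
        assert curve.growth[-1] is None
        assert curve.max_feasible == pytest.approx(5.5, abs=0.1)

    def test_absent_reaction_raises(self):
        with pytest.raises(ConfigurationError):
            robustness_scan(toy_chain(), None, "NOPE", step=1.0)

    def test_bad_step_raises(self):
        with pytest.raises(ValueError):
            robustness_scan(toy_chain(), None, "UPT", step=0.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_curve_concave_piecewise_linear(self, seed):
        m = random_toy_model(np.random.default_rng(2000 + seed))
        base = solve_fba(m)
        if not base.optimal or base.fluxes["UPT"] < 0.5:
            pytest.skip("degenerate random model")
        hi = base.fluxes["UPT"]
        curve = robustness_scan(m, None, "UPT", step=hi / 8, max_value=hi,
                                refine=False)
        mus = [g for g in curve.growth if g is not None]
        diffs = np.diff(mus)
        assert (np.diff(diffs) <= 1e-6).all(), "not concave"
        # midpoint re-solve lies on/above the chord (concavity oracle)
        for i in range(len(curve.grid) - 2):
            if curve.growth[i] is None or curve.growth[i + 1] is None:
                continue
            mid = 0.5 * (curve.grid[i] + curve.grid[i + 1])
            sol = solve_fba(m, ScenarioConfig(fixed_fluxes={"UPT": mid}))
            chord = 0.5 * (curve.growth[i] + curve.growth[i + 1])
            assert sol.growth_rate >= chord - 1e-6

    def test_argmax_interval(self):
        m = toy_chain()
        curve = robustness_scan(m, None, "UPT", step=2.0, max_value=10.0)
        lo, hi = curve.argmax_interval()
        assert (lo, hi) == (10.0, 10.0)


class TestRatioScan:
    def test_symmetric_branches_invariant(self):
        m = toy_parallel()
        results = ratio_sensitivity_scan(m, None, "R1", "R2",
                                         [0.1, 0.5, 1, 2, 10])
        mus = [mu for _, mu in results]
        assert mus == pytest.approx([1.0] * 5, abs=1e-9)

    def test_atp_wasting_branch_decreasing(self):
        # mu(r) = 5(1+r)/(1+2r) for r = v_R2/v_R1 (hand LP)
        m = toy_atp_waste()
        results = ratio_sensitivity_scan(m, None, "R2", "R1", [0.5, 1, 4])
        for (r, mu) in results:
            assert mu == pytest.approx(5 * (1 + r) / (1 + 2 * r), abs=1e-9)
        mus = [mu for _, mu in results]
        assert mus[0] > mus[1] > mus[2]

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            ratio_sensitivity_scan(toy_parallel(), None, "R1", "R2", [0.0])


class TestAtpmGrid:
    def test_origin_dominates(self):
        m = toy_maintenance()
        grid = atpm_grid(m, None, [0, 5, 10], [0, 2, 4])
        assert np.nanmax(grid) == pytest.approx(grid[0, 0], abs=1e-9)

    def test_ngam_linear_decline(self):
        # mu(ngam) = 1 - 0.1*ngam until zero (hand LP)
        m = toy_maintenance()
        ngams = [0.0, 2.0, 5.0, 10.0]
        grid = atpm_grid(m, None, [0.0], ngams)
        assert grid[0] == pytest.approx([1 - 0.1 * g for g in ngams],
                                        abs=1e-9)

    def test_monotone_in_each_axis(self, core_model):
        sc = ScenarioConfig(methanol_uptake=19.3)
        grid = atpm_grid(core_model, sc, [0, 30, 60], [0, 5, 10])
        assert (np.diff(grid, axis=0) <= 1e-7).all()
        assert (np.diff(grid, axis=1) <= 1e-7).all()

    def test_negative_grid_rejected(self):
        with pytest.raises(ValueError):
            atpm_grid(toy_maintenance(), None, [-1.0], [0.0])
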