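"""Michaelis-Menten uptake, the g_r heuristic, daily LP and the growth loop."""

import math
from dataclasses import replace

import pytest
from hypothesis import given, strategies as st

from dielfba.growth import (
    DayInfeasibleError,
    GrowthDomainError,
    GrowthParams,
    PerturbationEvent,
    PlantState,
    advance_state,
    day_lp,
    leaf_growth_proportion,
    max_nitrate_uptake,
    projected_leaf_area,
    run_growth,
    run_sensitivity_scan,
    solve_day,
)
from lp_oracle import oracle_solve

P = GrowthParams()


class TestMichaelisMenten:
    def test_half_saturation(self):
        assert max_nitrate_uptake(P.k_m, 1.0, P) == pytest.approx(0.5 * P.v_max)
        assert max_nitrate_uptake(P.k_m, 1.0, P) == pytest.approx(0.00168)

    def test_zero_nitrate_means_zero_uptake(self):
        assert max_nitrate_uptake(0.0, 3.0, P) == 0.0

    def test_printed_parameters_hand_case(self):
        # V_max=0.00336, K_M=0.4 mmol, S=1.2 mmol, R_B=2 g:
        # 0.00336 * 0.75 * 2 = 0.00504 mol/day
        assert max_nitrate_uptake(0.0012, 2.0, P) == pytest.approx(0.00504)

    def test_negative_inputs_rejected(self):
        with pytest.raises(GrowthDomainError):
            max_nitrate_uptake(-1e-3, 1.0, P)
        with pytest.raises(GrowthDomainError):
            max_nitrate_uptake(1e-3, 0.0, P)

    @given(st.floats(1e-9, 1.0), st.floats(1e-9, 1.0))
    def test_monotone_in_nitrate_and_never_negative(self, s_lo, delta):
        lo = max_nitrate_uptake(s_lo, 1.0, P)
        hi = max_nitrate_uptake(s_lo + delta, 1.0, P)
        assert 0.0 <= lo <= hi <= P.v_max


class TestProjectedLeafArea:
    def test_zero_leaf_zero_area(self):
        assert projected_leaf_area(0.0, 0.03) == 0.0

    def test_identity_slope(self):
        assert projected_leaf_area(0.5, 1.0) == 0.5

    @given(st.floats(1e-9, 1e3))
    def test_linearity(self, leaf):
        assert projected_leaf_area(2 * leaf, 0.03) == pytest.approx(
            2 * projected_leaf_area(leaf, 0.03))

    def test_negative_rejected(self):
        with pytest.raises(GrowthDomainError):
            projected_leaf_area(-1.0, 0.03)


class TestLeafGrowthProportion:
    def test_unit_photon_nitrate_ratio_clamps_to_root(self):
        # PN_r = 1 -> ln 1 = 0 -> everything to the root (lower clamp)
        pla = 0.01
        sigma = pla * P.p_max_daily
        g, pn = leaf_growth_proportion(pla, sigma, 1e-4, 1.0, 1.0, P)
        assert pn == pytest.approx(1.0)
        assert g == P.g_min

    def test_balanced_point_is_one_half(self):
        # ln(PN_r)=1, ln(P_max/S)=1 and L/R=1 -> 1/(1+1)
        s = P.p_max_daily / math.e
        pla = 0.01
        sigma = pla * P.p_max_daily / math.e
        g, _ = leaf_growth_proportion(pla, sigma, s, 2.0, 2.0, P)
        assert g == pytest.approx(0.5, rel=1e-12)

    def test_decreasing_in_leaf_root_ratio(self):
        pla, s = 0.01, 1e-4
        sigma = pla * P.p_max_daily / 50.0  # PN_r = 50 > 1
        gs = [leaf_growth_proportion(pla, sigma, s, lr, 1.0, P)[0]
              for lr in (0.2, 1.0, 5.0, 25.8)]
        assert all(a > b for a, b in zip(gs, gs[1:]))

    def test_low_nitrate_day6_partitions_to_root(self):
        # reference initial conditions, low-nitrate scenario
        state = P.initial_state()
        sigma = max_nitrate_uptake(state.nitrate, state.root_biomass, P)
        g, _ = leaf_growth_proportion(state.pla, sigma, state.nitrate,
                                      state.leaf_biomass, state.root_biomass, P)
        assert g < 0.5

    def test_domain_error_outside_validity(self):
        # soil nitrate above the photon dose makes the denominator negative
        with pytest.raises(GrowthDomainError):
            leaf_growth_proportion(0.01, 1e-5, P.p_max_daily * 10, 0.1, 10.0, P)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(GrowthDomainError):
            leaf_growth_proportion(0.0, 1e-5, 1e-3, 1.0, 1.0, P)

    @given(st.floats(1e-6, 1e3), st.floats(1e-9, 1e-2), st.floats(1e-4, 1e2),
           st.floats(1e-4, 1e2))
    def test_clamped_to_open_unit_interval(self, pla, s, leaf, root):
        sigma = 1e-5
        try:
            g, _ = leaf_growth_proportion(pla, sigma, s, leaf, root, P)
        except GrowthDomainError:
            return
        assert P.g_min <= g <= 1.0 - P.g_min


class TestSolveDay:
    def test_no_photons_no_growth(self, toy_model):
        # photon cap zero and zero maintenance: nothing can be synthesized
        params = replace(P, atp_maint=0.0, nadph_maint=0.0)
        state = params.initial_state()
        with day_lp(toy_model, state, params, irradiance=1e-30,
                    g_r=0.5) as (m, info):
            assert m.slim_optimize() == pytest.approx(0.0, abs=1e-12)

    def test_partition_constraint_echo(self, traj_nlow):
        for rec in traj_nlow.records:
            sol = rec.solution
            z = sol.total_growth
            if z < 1e-12:
                continue
            assert (1 - sol.g_r) * sol.leaf_growth == pytest.approx(
                sol.g_r * sol.root_growth, rel=1e-6, abs=1e-9 * z)

    def test_uptake_within_kinetic_cap(self, traj_nlow):
        for rec in traj_nlow.records:
            sol = rec.solution
            assert sol.nitrate_uptake <= sol.sigma_n_max * (1 + 1e-6) + 1e-12

    def test_sigma_values_nonnegative(self, traj_nlow):
        for rec in traj_nlow.records:
            s = rec.solution
            assert min(s.sigma_n_day, s.sigma_n_night, s.sigma_photon,
                       s.sigma_leaf_day, s.sigma_leaf_night,
                       s.sigma_root_day, s.sigma_root_night) >= -1e-12

    def test_day_optimum_matches_independent_lp(self, toy_model):
        """The daily optimum agrees with a from-scratch scipy assembly of
        the same constraints (photon cap, maintenance, nitrate cap row,
        partition row)."""
        from dielfba.builder import maintenance_values
        state = PlantState(10, 0.002, 0.001, 0.0012, P.m_slope)
        sol = solve_day(toy_model, state, P)
        kr = toy_model.key_reactions
        maint = maintenance_values(P.atp_maint, P.nadph_maint,
                                   state.leaf_biomass, state.root_biomass)
        # oracle works on the LP scale: mmol (metabolites) / mg (biomass)
        overrides = {kr["photon_uptake"]:
                     (0.0, P.p_max_daily * state.pla * 1000.0)}
        for sfx, vals in maint.items():
            overrides[kr[f"atpase_{sfx.lower()}"]] = (vals["atp"], vals["atp"])
            overrides[kr[f"nadph_oxidase_{sfx.lower()}"]] = \
                (vals["nadph"], vals["nadph"])
        cap = min(sol.sigma_n_max, state.nitrate) * 1000.0
        extra_ub = [({kr["nitrate_uptake_day"]: 1.0,
                      kr["nitrate_uptake_night"]: 1.0}, cap)]
        extra_eq = [({kr["biomass_leaf_day"]: 1 - sol.g_r,
                      kr["biomass_leaf_night"]: 1 - sol.g_r,
                      kr["biomass_root_day"]: -sol.g_r,
                      kr["biomass_root_night"]: -sol.g_r}, 0.0)]
        status, obj, _, _ = oracle_solve(
            toy_model.network, extra_eq=extra_eq, extra_ub=extra_ub,
            bound_overrides=overrides)
        assert status == "optimal"
        assert sol.total_growth * 1000.0 == pytest.approx(obj, rel=1e-6)


class TestAdvanceState:
    def test_zero_growth_only_advances_the_day(self, toy_model):
        state = PlantState(10, 0.01, 0.01, 0.0012, P.m_slope)
        from dielfba.growth import DaySolution
        from dielfba.network import FluxSolution
        sol = DaySolution(0.5, 1.0, 1e-5, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                          FluxSolution({}, 0.0, "optimal"))
        new, raw, floored = advance_state(state, sol, P)
        assert new.day == 11
        assert new.leaf_biomass == state.leaf_biomass
        assert new.nitrate == state.nitrate and not floored

    def test_overdraft_floors_with_warning(self, caplog):
        state = PlantState(10, 0.01, 0.01, 1e-5, P.m_slope)
        from dielfba.growth import DaySolution
        from dielfba.network import FluxSolution
        sol = DaySolution(0.5, 1.0, 1e-3, 3e-5, 2e-5, 0.0, 0.0, 0.0, 0.0, 0.0,
                          FluxSolution({}, 0.0, "optimal"))
        import logging
        with caplog.at_level(logging.WARNING, logger="dielfba.growth"):
            new, raw, floored = advance_state(state, sol, P)
        assert floored and new.nitrate == P.nitrate_floor
        assert raw == pytest.approx(-4e-5)
        assert any("floor" in r.message for r in caplog.records)


class TestRunGrowth:
    def test_loop_extent_and_day_labels(self, traj_nlow):
        assert [r.day for r in traj_nlow.records] == list(range(7, 37))
        df = traj_nlow.to_dataframe()
        assert len(df) == 31 and df["day"].iloc[0] == 6

    def test_initial_split_follows_lr_ratio(self, traj_nlow):
        init = traj_nlow.initial_state
        assert init.leaf_biomass / init.root_biomass == pytest.approx(25.8)
        assert init.total_biomass == pytest.approx(P.initial_total_biomass)

    def test_biomass_is_nondecreasing(self, traj_nlow, traj_nhigh):
        for traj in (traj_nlow, traj_nhigh):
            df = traj.to_dataframe().iloc[1:]
            assert (df["L_B_end"] >= df["L_B"] - 1e-12).all()
            assert (df["R_B_end"] >= df["R_B"] - 1e-12).all()

    def test_nitrate_bookkeeping_closes(self, traj_nlow):
        """Initial nitrate minus total uptake plus explicit floor top-ups
        equals final nitrate, to 1e-9 mol."""
        topups = sum(r.state_end.nitrate - r.nitrate_end_raw
                     for r in traj_nlow.records if r.floored)
        lhs = traj_nlow.initial_state.nitrate \
            - traj_nlow.total_nitrate_uptake() + topups
        assert lhs == pytest.approx(traj_nlow.final_state.nitrate, abs=1e-9)

    def test_nitrate_nonincreasing_between_perturbations(self, traj_nlow):
        df = traj_nlow.to_dataframe().iloc[1:]
        assert (df["S_end"] <= df["S"] + 1e-12).all()

    def test_state_chain_is_consistent(self, traj_nlow):
        prev = traj_nlow.initial_state
        for rec in traj_nlow.records:
            assert rec.state_start.leaf_biomass == pytest.approx(
                prev.leaf_biomass)
            assert rec.state_end.leaf_biomass == pytest.approx(
                rec.state_start.leaf_biomass + rec.solution.leaf_growth)
            prev = rec.state_end

    def test_determinism(self, toy_model, traj_nlow, scenarios):
        again = run_growth(toy_model, scenarios["n_low"].params)
        assert again.metadata == traj_nlow.metadata
        for a, b in zip(again.records, traj_nlow.records):
            assert a.solution.total_growth == pytest.approx(
                b.solution.total_growth, rel=1e-9, abs=1e-15)
            # identical up to LP tolerance: the solver warm-starts from
            # whatever basis the previous run left behind
            assert a.solution.g_r == pytest.approx(b.solution.g_r, rel=1e-9)

    def test_herbivory_overwrites_leaf_biomass(self, toy_model, scenarios):
        sc = scenarios["herbivory_n_low"]
        traj = run_growth(toy_model, sc.params, sc.perturbations)
        df = traj.to_dataframe()
        assert df.loc[df.day == 21, "L_B"].iloc[0] == 0.001

    def test_shading_persists_after_its_day(self, toy_model, scenarios):
        sc = scenarios["shade_n_low"]
        traj = run_growth(toy_model, sc.params, sc.perturbations)
        for rec in traj.records:
            expected = 100e-6 if rec.day >= 21 else P.p_max_irradiance
            assert rec.irradiance == expected

    def test_perturbation_day_must_be_in_range(self, toy_model):
        with pytest.raises(ValueError):
            run_growth(toy_model, P,
                       [PerturbationEvent(40, "set_nitrate", 0.1)])

    def test_unknown_perturbation_kind_rejected(self):
        with pytest.raises(ValueError):
            PerturbationEvent(21, "set_wind_speed", 1.0)


class TestSensitivityScan:
    def test_empty_scan_returns_baseline(self, toy_model):
        short = replace(P, end_day=9)
        runs, table = run_sensitivity_scan(toy_model, short,
                                           "initial_nitrate", [])
        assert len(runs) == 1
        assert table.shape[1] == 1

    def test_phloem_ratio_rows_follow_the_scan(self, toy_model):
        short = replace(P, end_day=9)
        runs, table = run_sensitivity_scan(toy_model, short,
                                           "phloem_light_dark", [2.0, 4.0])
        for value, traj in runs:
            sol = traj.records[-1].solution.flux_vector.fluxes
            day = sol["Suc_Leaf_to_CP_Day"]
            night = sol["Suc_Leaf_to_CP_Night"]
            assert day == pytest.approx(value * night, rel=1e-6, abs=1e-12)

    def test_sign_pattern_stable_under_moderate_scan(self, toy_model):
        short = replace(P, end_day=12)
        _, table = run_sensitivity_scan(toy_model, short,
                                        "rubisco_c_to_o", [2.5, 3.0, 3.5])
        cols = list(table.columns)
        for col in cols[1:]:
            assert (table[col] == table[cols[0]]).all()

    def test_unknown_parameter_rejected(self, toy_model):
        with pytest.raises(ValueError):
            run_sensitivity_scan(toy_model, P, "gravity", [9.8])

    def test_lower_nitrate_lower_final_biomass(self, toy_model, traj_nlow):
        params = replace(P, initial_nitrate=0.0003)
        lower = run_growth(toy_model, params)
        assert lower.final_state.total_biomass \
            < traj_nlow.final_state.total_biomass
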