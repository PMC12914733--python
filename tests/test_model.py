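import numpy as np
import pytest

from cd4sim import layout as L
from cd4sim.agefun import (AGE, AgeModulationSet, blood_volume,
                           default_modulations, effective_parameters)
from cd4sim.model import (StateVector, StructuralError, ValidationError,
                          flow_audit, full_rhs, seed_state,
                          simulate_trajectory, solve_steady_state,
                          steady_state_direct)


def eff_at(params, mod, age, c_rte=0.0):
    return effective_parameters(age, c_rte, params, mod)


class TestFullRhs:
    def test_zero_state_has_zero_derivative(self, params, mod_static):
        d = full_rhs(np.zeros(24), eff_at(params, mod_static, 10.0))
        assert np.all(d == 0.0)

    def test_isolated_effector_in_gut_decays_at_printed_rate(
            self, params, mod_static):
        y = np.zeros(24)
        y[L.I_EFF_GIT] = 1.0
        d = full_rhs(y, eff_at(params, mod_static, 5.0))
        assert d[L.I_EFF_GIT] == pytest.approx(-0.87)
        d[L.I_EFF_GIT] = 0.0
        assert np.all(d == 0.0)

    def test_dimension_mismatch_is_structural_error(self, params, mod_static):
        with pytest.raises(StructuralError):
            full_rhs(np.zeros(23), eff_at(params, mod_static, 1.0))

    def test_negative_rate_is_validation_error(self, params, mod_static):
        eff = eff_at(params, mod_static, 1.0)
        eff.values["muN4"] = -1.0
        with pytest.raises(ValidationError):
            full_rhs(np.zeros(24), eff)


class TestFlowAudit:
    def test_sums_match_rhs_on_random_states(self, params, mod_fb, rng):
        eff = eff_at(params, mod_fb, 30.0, c_rte=50.0)
        for _ in range(300):
            y = rng.uniform(0, 1e9, 24)
            d = full_rhs(y, eff)
            s = flow_audit(y, eff).sums()
            assert np.allclose(s, d, rtol=1e-12, atol=1e-3)

    def test_naive_blood_to_lymphoid_flux_at_printed_rate(
            self, params, mod_static, rng):
        y = rng.uniform(0, 1e8, 24)
        fb = flow_audit(y, eff_at(params, mod_static, 0.0))
        # the BL->LT migration contribution appears inside N-LT inflow
        n_bl = y[L.I_N_BL]
        inflow = fb.per_state[("N", "LT")]["migration_in"]
        assert inflow == pytest.approx(40.0 * n_bl, rel=1e-12)

    def test_migration_pairing_balance(self, params, mod_fb, rng):
        """Migration leaving any state re-enters elsewhere, except the
        peripheral-tissue sinks (omega*bl_tis) and thymic egress."""
        y = rng.uniform(0, 1e9, 24)
        eff = eff_at(params, mod_fb, 40.0, c_rte=30.0)
        fb = flow_audit(y, eff)
        total_out = -sum(v["migration_out"] for v in fb.per_state.values())
        total_in = sum(v["migration_in"] for v in fb.per_state.values())
        sinks = (eff.omegaN4bl_tis * y[L.I_N_BL]
                 + eff.omegaA4bl_tis * y[L.I_A_BL]
                 + eff.omegaCM4bl_tis * y[L.I_CM_BL]
                 + eff.omegaEM4bl_tis * y[L.I_EM_BL]
                 + eff.omegaEFF4bl_tis * y[L.I_EFF_BL])
        assert total_out - total_in == pytest.approx(sinks, rel=1e-10)

    def test_effector_production_balance(self, params, mod_static, rng):
        y = rng.uniform(0, 1e9, 24)
        eff = eff_at(params, mod_static, 0.0)
        fb = flow_audit(y, eff)
        em_total = sum(y[i] for i in L.LAYOUT.states_of("EM"))
        expected = (eff.phiEM4 * em_total
                    + (1.0 - eff.f4) * eff.phiA4 * y[L.I_A_LT])
        produced = sum(fb.per_state[(s, c)]["differentiation_in"]
                       for (s, c) in fb.per_state if s == "EFF")
        assert produced == pytest.approx(expected, rel=1e-12)


class TestTrajectory:
    def test_single_state_decay_matches_closed_form(self, params, mod_static):
        y0 = np.zeros(24)
        y0[L.I_EFF_GIT] = 1000.0
        t = np.linspace(0, 5.0, 40)
        traj = simulate_trajectory(y0, params, mod_static, t,
                                   freeze_age=10.0, rtol=1e-10, atol=1e-8)
        expected = 1000.0 * np.exp(-0.87 * t)
        rel = np.abs(traj.states[:, L.I_EFF_GIT] - expected) / expected
        assert rel.max() < 1e-6

    def test_zero_initial_state_stays_zero(self, params, mod_fb):
        t = np.linspace(0, 365.0, 10)
        traj = simulate_trajectory(np.zeros(24), params, mod_fb, t)
        assert np.all(traj.states == 0.0)

    def test_repeat_run_is_bitwise_identical(self, params, mod_fb,
                                             newborn_ss):
        t = np.linspace(0, 400.0, 20)
        a = simulate_trajectory(newborn_ss, params, mod_fb, t)
        b = simulate_trajectory(newborn_ss, params, mod_fb, t)
        assert np.array_equal(a.states, b.states)

    def test_rejects_bad_grid_and_negative_initial(self, params, mod_fb):
        with pytest.raises(ValidationError):
            simulate_trajectory(np.zeros(24), params, mod_fb,
                                np.array([1.0, 0.5]))
        y = np.zeros(24)
        y[0] = -5.0
        with pytest.raises(ValidationError):
            simulate_trajectory(y, params, mod_fb, np.array([0.0, 1.0]))

    def test_nonnegative_under_random_rate_perturbations(self, params,
                                                         mod_fb, rng):
        t = np.linspace(0, 2 * 365.25, 15)
        base = params.to_dict()
        for _ in range(15):
            perturbed = {k: v * rng.uniform(0.5, 1.5)
                         for k, v in base.items()
                         if k not in ("f4", "thy_fSP4")}
            p = params.replace(**perturbed)
            traj = simulate_trajectory(seed_state(), p, mod_fb, t)
            assert traj.states.min() >= 0.0

    def test_tidy_frame_schema(self, params, mod_static, newborn_ss):
        t = np.linspace(0, 10.0, 3)
        df = simulate_trajectory(newborn_ss, params, mod_static, t).to_frame()
        assert list(df.columns) == ["time_days", "age_years",
                                    "subpopulation", "compartment", "count"]
        assert len(df) == 3 * 24


class TestSteadyState:
    def test_zero_fixed_point_without_source_or_proliferation(self, params,
                                                              mod_static):
        p = params.replace(thy_lamDN=0.0, thy_lamDP=0.0, thy_lamSP=0.0)
        y = steady_state_direct(p, mod_static, 10.0)
        assert np.all(y == 0.0)

    def test_fixed_point_residual_below_tolerance(self, params, mod_fb):
        sv = solve_steady_state(params, mod_fb, 5.0, t_equilibrate=2e5)
        assert isinstance(sv, StateVector)
        bv = blood_volume(5.0, mod_fb.body)
        eff = eff_at(params, mod_fb, 5.0,
                     c_rte=sv.counts[L.I_RTE_BL] / (bv * 1e6))
        r = full_rhs(sv.counts, eff)
        assert np.max(np.abs(r) / np.maximum(sv.counts, 1.0)) < 1e-8

    def test_direct_solver_agrees_with_integration_path(self, params,
                                                        mod_fb):
        yd = steady_state_direct(params, mod_fb, 20.0)
        sv = solve_steady_state(params, mod_fb, 20.0, t_equilibrate=2e5)
        assert np.allclose(sv.counts, yd, rtol=1e-4)

    def test_monotone_response_to_thymic_output(self, params, mod_age):
        """Scaling thymic egress up (feedbacks off) cannot decrease any
        steady-state peripheral count."""
        y1 = steady_state_direct(params, mod_age, 10.0)
        y2 = steady_state_direct(params.replace(thy_epsSP4=0.2),
                                 mod_age, 10.0)
        per = list(L.PERIPHERAL)
        assert np.all(y2[per] >= y1[per] * (1 - 1e-9))

    def test_linear_subsystem_matches_matrix_solution(self, params,
                                                      mod_static):
        """With lamA4 = 0 the peripheral block is linear; its fixed point
        must equal the solution of an independently assembled system."""
        p = params.replace(lamA4=0.0)
        age = 20.0
        y = steady_state_direct(p, mod_static, age)
        egress = p.thy_epsSP4 * y[L.I_SP4]
        x = _independent_linear_steady_state(p, egress)
        model = y[list(L.PERIPHERAL)]
        assert np.allclose(model, x, rtol=1e-8)


def _independent_linear_steady_state(p, egress):
    """Hand-assembled 20-state peripheral balance (lamA4 = 0), written
    equation by equation as an oracle independent of the model RHS."""
    ix = {lab: i for i, lab in enumerate(
        [l for l in L.STATE_LABELS if l[1] != "THY"])}
    A = np.zeros((20, 20))
    b = np.zeros(20)

    def add(row, col, v):
        A[ix[row], ix[col]] += v

    b[ix[("RTE", "BL")]] = egress
    add(("RTE", "BL"), ("RTE", "BL"), -(p.omegaRTE4bl_lt + p.muRTE4))
    add(("RTE", "LT"), ("RTE", "BL"), p.omegaRTE4bl_lt)
    add(("RTE", "LT"), ("RTE", "LT"), -(p.phiRTE4 + p.muRTE4))
    add(("N", "LT"), ("RTE", "LT"), p.phiRTE4)
    add(("N", "LT"), ("N", "LT"),
        p.lamN4 - p.muN4 - p.phiN4 - p.omegaN4lt_bl)
    add(("N", "LT"), ("N", "BL"), p.omegaN4bl_lt)
    add(("N", "BL"), ("N", "LT"), p.omegaN4lt_bl)
    add(("N", "BL"), ("N", "BL"),
        p.lamN4 - p.muN4 - p.omegaN4bl_lt - p.omegaN4bl_git
        - p.omegaN4bl_lung - p.omegaN4bl_tis)
    add(("N", "BL"), ("N", "GIT"), p.omegaN4git_bl)
    add(("N", "BL"), ("N", "LUNG"), p.omegaN4lung_bl)
    add(("N", "GIT"), ("N", "BL"), p.omegaN4bl_git)
    add(("N", "GIT"), ("N", "GIT"), -(p.muN4 + p.omegaN4git_bl))
    add(("N", "LUNG"), ("N", "BL"), p.omegaN4bl_lung)
    add(("N", "LUNG"), ("N", "LUNG"), -(p.muN4 + p.omegaN4lung_bl))
    add(("A", "LT"), ("N", "LT"), p.phiN4)
    add(("A", "LT"), ("A", "LT"), -(p.muA4 + p.phiA4 + p.omegaA4lt_bl))
    add(("A", "LT"), ("A", "BL"), p.omegaA4bl_lt)
    add(("A", "BL"), ("A", "LT"), p.omegaA4lt_bl)
    add(("A", "BL"), ("A", "BL"),
        -(p.muA4 + p.omegaA4bl_lt + p.omegaA4bl_tis))
    # central-memory
    add(("CM", "LT"), ("A", "LT"), p.f4 * p.phiA4)
    net_cm = p.lamCM4 - p.muCM4 - p.phiCM4
    add(("CM", "LT"), ("CM", "LT"), net_cm - p.omegaCM4lt_bl)
    add(("CM", "LT"), ("CM", "BL"), p.omegaCM4bl_lt)
    add(("CM", "BL"), ("CM", "LT"), p.omegaCM4lt_bl)
    add(("CM", "BL"), ("CM", "BL"),
        net_cm - p.omegaCM4bl_lt - p.omegaCM4bl_git - p.omegaCM4bl_lung
        - p.omegaCM4bl_tis)
    add(("CM", "BL"), ("CM", "GIT"), p.omegaCM4git_bl)
    add(("CM", "BL"), ("CM", "LUNG"), p.omegaCM4lung_bl)
    add(("CM", "GIT"), ("CM", "BL"), p.omegaCM4bl_git)
    add(("CM", "GIT"), ("CM", "GIT"), net_cm - p.omegaCM4git_bl)
    add(("CM", "LUNG"), ("CM", "BL"), p.omegaCM4bl_lung)
    add(("CM", "LUNG"), ("CM", "LUNG"), net_cm - p.omegaCM4lung_bl)
    # effector-memory
    net_em = p.lamEM4 - p.muEM4 - p.phiEM4
    for comp in ("BL", "LT", "GIT", "LUNG"):
        add(("EM", comp), ("CM", comp), p.phiCM4)
    add(("EM", "LT"), ("EM", "LT"), net_em - p.omegaEM4lt_bl)
    add(("EM", "BL"), ("EM", "LT"), p.omegaEM4lt_bl)
    add(("EM", "BL"), ("EM", "BL"),
        net_em - p.omegaEM4bl_git - p.omegaEM4bl_lung - p.omegaEM4bl_tis)
    add(("EM", "BL"), ("EM", "GIT"), p.omegaEM4git_bl)
    add(("EM", "BL"), ("EM", "LUNG"), p.omegaEM4lung_bl)
    add(("EM", "GIT"), ("EM", "BL"), p.omegaEM4bl_git)
    add(("EM", "GIT"), ("EM", "GIT"), net_em - p.omegaEM4git_bl)
    add(("EM", "LUNG"), ("EM", "BL"), p.omegaEM4bl_lung)
    add(("EM", "LUNG"), ("EM", "LUNG"), net_em - p.omegaEM4lung_bl)
    # effector
    add(("EFF", "LT"), ("A", "LT"), (1.0 - p.f4) * p.phiA4)
    for comp in ("BL", "LT", "GIT", "LUNG"):
        add(("EFF", comp), ("EM", comp), p.phiEM4)
        add(("EFF", comp), ("EFF", comp), -p.muEFF4)
    add(("EFF", "LT"), ("EFF", "LT"), -p.omegaEFF4lt_bl)
    add(("EFF", "BL"), ("EFF", "LT"), p.omegaEFF4lt_bl)
    add(("EFF", "BL"), ("EFF", "BL"),
        -(p.omegaEFF4bl_git + p.omegaEFF4bl_lung + p.omegaEFF4bl_tis))
    add(("EFF", "GIT"), ("EFF", "BL"), p.omegaEFF4bl_git)
    add(("EFF", "LUNG"), ("EFF", "BL"), p.omegaEFF4bl_lung)
    return np.linalg.solve(A, -b)
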