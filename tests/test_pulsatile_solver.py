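import dataclasses

import numpy as np
import pytest
from scipy import optimize

from octffr import (PressureWaveforms, SolverSettings, compute_simffr,
                    parameter_sweep, simulate, solve_epicardial,
                    systolic_diastolic_means)
from octffr.errors import ConfigError, InvalidParameterError
from octffr.network_builder import MicrovascularBed, NetworkModel

from conftest import make_case


def steady_state_oracle(net, pa, p_ra):
    """Independent steady solution: shooting on inlet flow and venous pressure
    with an explicit marching pass down the chain (no matrix reduction)."""
    k = net.k_visc_segments
    n = k.size
    m = net.conv_segment
    gl = net.leak_g[:-1] / net.split_fraction
    g_pdv = (net.leak_g[-1] + net.g_bed) / net.split_fraction
    g_vout = net.g_total / (1 - net.split_fraction)

    def march(q0, pv):
        p, q, leak_sum = pa, q0, 0.0
        for i in range(1, n + 1):
            p -= k[i - 1] * q + (net.k_conv * q * abs(q) if i == m else 0.0)
            if i < n:
                lk = gl[i - 1] * (p - pv)
                leak_sum += lk
                q -= lk
        return p, q, leak_sum

    def resid(x):
        q0, pv = x
        p_n, q_n, leak_sum = march(q0, pv)
        return [q_n - g_pdv * (p_n - pv),
                leak_sum + g_pdv * (p_n - pv) - g_vout * max(pv - p_ra, 0.0)]

    sol = optimize.root(resid, [2.0, 10.0], tol=1e-13)
    assert sol.success
    p_n, _, _ = march(*sol.x)
    return p_n, sol.x[0]  # Pd, inlet flow


def simple_bed():
    return MicrovascularBed(r_micro=46.2, r_micro_prox=34.65,
                            r_micro_dist=11.55, c_micro=4.5e-3, c_dist=1.1e-3)


class TestSolveEpicardial:
    def test_linear_chain_is_ohmic(self):
        net = NetworkModel(position=np.linspace(0, 50, 251),
                           k_visc_segments=np.full(250, 0.02), k_conv=0.0,
                           conv_segment=125, leak_g=np.zeros(250),
                           bed=simple_bed(), g_total=1 / 46.2, g_bed=1 / 46.2)
        sol = solve_epicardial(100.0, (60.0, 10.0), net)
        assert sol.q_segments[0] == pytest.approx((100 - 60) / 5.0, rel=1e-9)
        assert np.ptp(sol.q_segments) < 1e-10  # no leaks: uniform flow

    def test_quadratic_element_closed_form_root(self):
        net = NetworkModel(position=np.array([0.0, 50.0]),
                           k_visc_segments=np.array([1e-12]), k_conv=2.0,
                           conv_segment=1, leak_g=np.array([0.0]),
                           bed=simple_bed(), g_total=1 / 46.2, g_bed=1 / 46.2)
        sol = solve_epicardial(100.0, (50.0, 10.0), net)
        assert sol.q_segments[0] == pytest.approx(np.sqrt(50.0 / 2.0), rel=1e-6)

    def test_interior_conservation_with_leaks(self, moderate_lad_case):
        net = moderate_lad_case.build()
        sol = solve_epicardial(95.0, (70.0, 12.0), net)
        inflow = sol.q_segments[:-1]
        outflow = sol.q_segments[1:] + sol.q_leaks
        np.testing.assert_allclose(inflow, outflow, atol=1e-10)


class TestSimulate:
    def test_steady_inlet_matches_independent_oracle(self, constant_inlet):
        rng = np.random.default_rng(42)
        for i in range(3):
            a_prox = float(rng.uniform(7, 14))
            case = make_case(depth=float(rng.uniform(0.2, 0.85)),
                             a_prox=a_prox, a_dist=a_prox * 0.55,
                             width=float(rng.uniform(2, 6)), seed=i)
            net = case.build()
            res = simulate(net, constant_inlet,
                           SolverSettings(convergence_tol=1e-8, max_cycles=300))
            pd_o, q_o = steady_state_oracle(net, 100.0, net.p_ra)
            assert res.mean_pd == pytest.approx(pd_o, rel=1e-3)
            assert res.mean_q == pytest.approx(q_o, rel=1e-3)

    def test_simffr_decreases_with_severity(self, wf_hyperemia, settings):
        mild = simulate(make_case(depth=0.3).build(), wf_hyperemia, settings)
        severe = simulate(make_case(depth=0.85).build(), wf_hyperemia, settings)
        assert severe.sim_ffr < mild.sim_ffr

    def test_flow_balance_residual_bounded(self, wf_hyperemia, settings,
                                           moderate_lad_case):
        res = simulate(moderate_lad_case.build(), wf_hyperemia, settings)
        assert res.max_flow_residual < 1e-8

    def test_capacitive_storage_closes_mass_balance(self, wf_hyperemia,
                                                    settings, moderate_lad_case):
        # q_in = C_d dPd/dt + C_v d(Pv - 0.5 Plv)/dt + venous outflow,
        # with backward differences matching the implicit scheme
        net = moderate_lad_case.build()
        res = simulate(net, wf_hyperemia, settings)
        dt = settings.dt
        dpd = np.diff(res.pd) / dt
        dplv = np.diff(res.plv) / dt
        dpv = np.diff(res.pv) / dt
        g_vout = net.g_total / (1 - net.split_fraction)
        p_out = np.maximum(net.p_ra, net.bed.im_coupling * res.plv[1:])
        q_out_ra = g_vout * np.maximum(res.pv[1:] - p_out, 0.0)
        lhs = res.q_inlet[1:]
        rhs = (net.bed.c_dist * dpd
               + net.bed.c_micro * (dpv - net.bed.im_coupling * dplv)
               + q_out_ra)
        np.testing.assert_allclose(lhs, rhs, atol=1e-7)

    def test_mean_pd_below_mean_pa(self, wf_hyperemia, settings):
        res = simulate(make_case(depth=0.5).build(), wf_hyperemia, settings)
        assert res.mean_pd < res.mean_pa

    def test_zero_disease_limit(self, wf_hyperemia, settings):
        case = make_case(depth=0.0, a_prox=25.0, a_dist=25.0, roi=30.0)
        res = simulate(case.build(), wf_hyperemia, settings)
        assert res.sim_ffr >= 0.99

    def test_diastolic_flow_dominates_with_lv_coupling(self, wf_hyperemia,
                                                       settings):
        res = simulate(make_case(depth=0.5).build(), wf_hyperemia, settings)
        q_sys, q_dia = systolic_diastolic_means(res)
        assert q_dia > q_sys

    def test_time_step_convergence(self, wf_hyperemia, moderate_lad_case):
        net = moderate_lad_case.build()
        f1 = simulate(net, wf_hyperemia, SolverSettings(dt=1e-3)).sim_ffr
        f2 = simulate(net, wf_hyperemia, SolverSettings(dt=5e-4)).sim_ffr
        assert abs(f1 - f2) < 1e-4

    def test_result_is_periodic_and_consistent(self, wf_hyperemia, settings,
                                               moderate_lad_case):
        res = simulate(moderate_lad_case.build(), wf_hyperemia, settings)
        assert res.sim_ffr == pytest.approx(res.mean_pd / res.mean_pa, rel=1e-12)
        assert 0 < res.sim_ffr <= 1.05
        assert res.cycles_to_converge <= settings.max_cycles


class TestComputeSimFfr:
    def test_ratio_of_cycle_means(self, wf_hyperemia, settings,
                                  moderate_lad_case):
        res = simulate(moderate_lad_case.build(), wf_hyperemia, settings)
        assert compute_simffr(res) == res.sim_ffr

    def test_table_arithmetic(self, wf_hyperemia, settings, moderate_lad_case):
        res = simulate(moderate_lad_case.build(), wf_hyperemia, settings)
        res = dataclasses.replace(res, mean_pd=66.0, mean_pa=83.0)
        assert compute_simffr(res) == pytest.approx(0.795, abs=5e-4)

    def test_non_positive_mean_pa_rejected(self, wf_hyperemia, settings,
                                           moderate_lad_case):
        res = simulate(moderate_lad_case.build(), wf_hyperemia, settings)
        res = dataclasses.replace(res, mean_pa=0.0)
        with pytest.raises(InvalidParameterError):
            compute_simffr(res)


class TestParameterSweep:
    def test_stronger_lumen_correction_cannot_raise_ffr(self, wf_hyperemia,
                                                        settings):
        case = make_case(depth=0.75)
        table = parameter_sweep(case, wf_hyperemia, settings, "k_lumencorr",
                                [0.0, -0.075, -0.15])
        assert np.all(np.diff(table["sim_ffr"].to_numpy()) <= 0)

    def test_single_value_matches_direct_simulation(self, wf_hyperemia,
                                                    settings):
        case = make_case(depth=0.6)
        table = parameter_sweep(case, wf_hyperemia, settings, "p_ra", [2.0])
        direct = simulate(case.build(), wf_hyperemia, settings)
        assert table.loc[0, "sim_ffr"] == pytest.approx(direct.sim_ffr,
                                                        rel=1e-12)

    def test_empty_value_list_gives_empty_table(self, wf_hyperemia, settings):
        table = parameter_sweep(make_case(), wf_hyperemia, settings,
                                "k_lumencorr", [])
        assert table.empty

    def test_unknown_parameter_rejected(self, wf_hyperemia, settings):
        with pytest.raises(ConfigError, match="unknown sweep parameter"):
            parameter_sweep(make_case(), wf_hyperemia, settings,
                            "not_a_knob", [1.0])
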