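"""Fast daily model: toxicity, flux terms, full-day integration."""

import numpy as np
import pytest

import t2dsim as t
from t2dsim.daily import (DailyTrace, calibrate_toxicity, fasting_inputs,
                          glucagon_rhs, glucagon_steady, glucose_rhs, gut_rhs,
                          insulin_rhs, simulate_day, summarize_trace)


class TestToxicity:
    def test_anchor_exactness(self):
        tox = calibrate_toxicity()
        assert tox(5.5) == pytest.approx(1.0, abs=1e-9)
        assert tox(30.0) == pytest.approx(3.5, abs=1e-9)

    def test_matches_two_dimensional_root_solve(self):
        # independent oracle: solve both anchor residuals numerically
        from scipy.optimize import fsolve

        def residuals(x):
            h, K = x
            f = lambda g: 4.0 * g**h / (K**h + g**h)
            return [f(5.5) - 1.0, f(30.0) - 3.5]

        h, K = fsolve(residuals, [2.0, 10.0], xtol=1e-12)
        tox = calibrate_toxicity()
        assert tox.h == pytest.approx(h, rel=1e-8)
        assert tox.K == pytest.approx(K, rel=1e-8)
        assert tox.h == pytest.approx(1.7946, abs=1e-4)
        assert tox.K == pytest.approx(10.144, abs=1e-3)

    def test_zero_monotone_saturating(self):
        tox = calibrate_toxicity()
        assert tox(0.0) == 0.0
        gg = np.linspace(0.0, 100.0, 1000)
        assert np.all(np.diff(tox(gg)) > 0)
        assert np.all(tox(gg) < 4.0)
        assert tox(1e9) == pytest.approx(4.0, rel=1e-6)

    def test_inconsistent_anchors_rejected(self):
        with pytest.raises(ValueError):
            calibrate_toxicity(((5.5, 3.5), (30.0, 1.0)))
        with pytest.raises(ValueError):
            calibrate_toxicity(((5.5, 1.0), (30.0, 4.5)))


class TestFluxTerms:
    def test_gut_conservation_fraction(self, params):
        # total appearance in plasma after one meal is f_GJ * M
        dS, dJ, ra = gut_rhs(417.0, 0.0, params.k_JS0, params)
        assert dS == pytest.approx(-params.k_JS0 * 417.0)
        # half-life of the stomach content
        assert np.log(2) / params.k_JS0 == pytest.approx(29.5, abs=0.1)

    def test_gut_empty_state(self, params):
        assert gut_rhs(0.0, 0.0, params.k_JS0, params) == (0.0, 0.0, 0.0)

    def test_glucagon_fasting_steady_state(self, params):
        # secretion/elimination balance at 4.2 mM reproduces the tabulated
        # fasting glucagon of 15 pM
        L_star = glucagon_steady(4.2, params)
        assert L_star == pytest.approx(15.0, rel=0.005)
        assert glucagon_rhs(L_star, 4.2, params) == pytest.approx(0.0, abs=1e-12)

    def test_glucagon_hyperglycemic_floor(self, params):
        # fully suppressed secretion: kLGmax * fLGmin / kXL
        assert glucagon_steady(1e6, params) == pytest.approx(2.56 * 0.15 / 0.04)

    def test_glucagon_secretion_monotone_in_glycemia(self, params):
        gg = np.linspace(0.0, 30.0, 50)
        sec = [glucagon_rhs(0.0, g, params) for g in gg]
        assert all(a > b for a, b in zip(sec, sec[1:]))

    def test_insulin_incretin_amplification(self, params):
        # at J = J_G50 the effective glycemia multiplier is 1 + f_IJ/2
        from t2dsim.slow import psi_igluc

        G = 5.0
        got = insulin_rhs(0.0, G, params.J_G50, 1000.0, params)
        expected = psi_igluc(1000.0, G * (1 + params.f_IJ / 2), params) / (
            params.V_I * params.W
        )
        assert got == pytest.approx(expected)

    def test_insulin_reductions(self, params):
        from t2dsim.slow import psi_igluc

        # no intestinal glucose: plain fasting secretion drive
        assert insulin_rhs(0.0, 5.0, 0.0, 1000.0, params) == pytest.approx(
            psi_igluc(1000.0, 5.0, params) / (params.V_I * params.W)
        )
        # no beta-cells: pure exponential decay
        assert insulin_rhs(100.0, 5.0, 0.0, 0.0, params) == pytest.approx(
            -params.k_XI_start * 100.0
        )

    def test_glucose_rhs_hand_arithmetic(self, params):
        # I = L = ra = ur = 0 at G = 1: only insulin-independent uptake,
        # unsuppressed hepatic output and brain oxidation remain
        got = glucose_rhs(1.0, 0.0, 0.0, 0.0, 0.0, params)
        expected = -0.001 * 1.0 + (0.75 - 70 * 0.0059 * (1.0 / 1.5)) / (0.19 * 70)
        assert got == pytest.approx(expected)

    def test_uptake_half_saturation(self, params):
        # at I = I_KXGI50 the insulin-dependent uptake is half of max
        base = glucose_rhs(5.0, 0.0, 10.0, 0.0, 0.0, params)
        half = glucose_rhs(5.0, params.I_KXGI50, 10.0, 0.0, 0.0, params)
        full_uptake = params.k_XGI0max * 5.0
        hgo_lost = (
            params.k_GI_max
            * (1 - np.exp(-params.lam_GI0 * (params.I_KXGI50 / 6.0) * 5.0))
            / (params.V_G * params.W)
        )
        assert base - half == pytest.approx(full_uptake / 2 + hgo_lost)

    def test_hgo_fully_suppressed_at_clamp_levels(self, params):
        # high-insulinization clamp conditions: hepatic output negligible
        exponent = params.lam_GI0 * (420.0 / params.insulin_pM_per_uIU) * 5.0
        assert np.exp(-exponent) < 0.01


class TestSimulateDay:
    def test_three_meal_jumps(self, params, baseline_day):
        trace, _ = baseline_day
        jumps = np.diff(trace.S)
        big = np.where(jumps > 50)[0]
        assert len(big) == 3
        # jump sizes recover the meal masses (minus within-minute emptying)
        sizes = jumps[big]
        for size, mass in zip(sizes, (417.0, 280.0, 280.0)):
            assert size == pytest.approx(mass, rel=0.05)
        times = trace.tau[big + 1]
        assert np.allclose(times, [420.0, 720.0, 1080.0], atol=1.0)

    def test_trace_nonnegative(self, baseline_day):
        trace, _ = baseline_day
        for arr in (trace.S, trace.J, trace.G, trace.I, trace.L, trace.ra, trace.ur):
            assert np.all(arr >= 0.0)

    def test_coupling_sample(self, params, baseline_day):
        # G_f24 is exactly the traced glycemia 1440 min after the start
        trace, summary = baseline_day
        idx = np.argmin(np.abs(trace.tau - (trace.tau[0] + 1440.0)))
        assert summary.G_f24 == pytest.approx(trace.G[idx], abs=1e-9)

    def test_meal_free_day_stays_at_equilibrium(self, params, grid, baseline_state,
                                                equilibrium_glycemia):
        # start exactly at the fasted fixed point with no meals: the whole
        # day stays constant to solver tolerance
        inputs = fasting_inputs(
            baseline_state.B, equilibrium_glycemia, baseline_state.controls,
            params, meals=[], grid=grid,
        )
        trace, summary = simulate_day(inputs, params, grid=grid)
        assert np.max(np.abs(trace.G - equilibrium_glycemia)) < 1e-3
        assert summary.G_f24 == pytest.approx(equilibrium_glycemia, abs=1e-3)

    def test_constant_normoglycemia_scores_unit_toxicity(self, params):
        # a synthetic constant 5.5 mM day has mean toxicity exactly 1
        tau = np.arange(360.0, 1801.0)
        n = tau.size
        const = DailyTrace(
            tau=tau, S=np.zeros(n), J=np.zeros(n), G=np.full(n, 5.5),
            I=np.full(n, 20.0), L=np.full(n, 15.0), ra=np.zeros(n),
            ur=np.zeros(n), C_end=np.zeros(3),
        )
        summary = summarize_trace(const, params)
        assert summary.G_eta == pytest.approx(1.0, abs=1e-9)
        assert summary.G_B == pytest.approx(5.5)

    def test_glucose_bookkeeping_closes(self, params, baseline_day):
        # absorbed = change in plasma content + uptake + brain + urinary
        #            - hepatic/glucagon production, using the quadrature
        #            states carried by the integrator
        trace, _ = baseline_day
        c = trace.cumulative
        dG_content = (trace.G[-1] - trace.G[0]) * params.V_G * params.W
        residual = (
            c["absorbed"] + c["production"]
            - c["uptake"] - c["brain"] - c["urinary"] - dG_content
        )
        assert abs(residual) / c["absorbed"] < 1e-4

    def test_slower_emptying_delays_glycemic_peak(self, params, grid, baseline_state):
        def peak_time(k_js_scale):
            controls = dict(baseline_state.controls)
            controls["k_JS"] = controls["k_JS"] * k_js_scale
            inputs = fasting_inputs(
                baseline_state.B, baseline_state.G_f, controls, params,
                meals=[(420.0, 417.0)], grid=grid,
            )
            trace, _ = simulate_day(inputs, params, grid=grid)
            return trace.tau[np.argmax(trace.G)]

        assert peak_time(0.5) > peak_time(1.0)

    def test_solver_failure_reports_context(self, params, grid, baseline_state):
        inputs = fasting_inputs(
            baseline_state.B, baseline_state.G_f, baseline_state.controls,
            params, grid=grid,
        )
        inputs.meals = [(1000.0, -5.0)]
        with pytest.raises(ValueError):
            simulate_day(inputs, params, grid=grid)

    def test_summary_statistics_consistent(self, baseline_day):
        _, summary = baseline_day
        assert summary.G_min <= summary.G_B <= summary.G_max
        assert summary.I_min <= summary.I_mean <= summary.I_max
        assert summary.G_sd > 0 and summary.I_sd > 0
        assert summary.urinary_mmol > 0
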