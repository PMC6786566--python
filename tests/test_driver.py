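"""Life-course driver: stepping, scenarios, endpoints, fixture, comparison."""

import numpy as np
import pandas as pd
import pytest

import t2dsim as t
from t2dsim.driver import compare, extract_endpoints, generate_fixture, step
from t2dsim.params import builtin_treatment
from t2dsim.slow import SlowState


class TestStep:
    def test_carrying_capacity_preserved(self, params, grid):
        state = SlowState(t=0.0, B=params.B_max, eta=0.04, G_f=4.2, A=5.0)
        new, _ = step(state, builtin_treatment("none"), params, grid=grid)
        assert new.B == pytest.approx(params.B_max, rel=1e-12)

    def test_glycemia_fixed_point_preserved(self, params, grid, baseline_state,
                                            equilibrium_glycemia):
        # at the fasted fixed point with no meals the day returns G_f24 = G_f,
        # so the slow glycemia does not move
        import t2dsim.daily as daily

        inputs = daily.fasting_inputs(
            baseline_state.B, equilibrium_glycemia, baseline_state.controls,
            params, meals=[], grid=grid,
        )
        _, summary = daily.simulate_day(inputs, params, grid=grid)
        dG = params.k_GG * (summary.G_f24 - equilibrium_glycemia)
        assert abs(dG) < 1e-3

    def test_reserve_floor_and_mass_clipping(self, params, grid):
        state = SlowState(t=500.0, B=10.0, eta=1e-9, G_f=15.0, A=8.0)
        new, _ = step(state, builtin_treatment("none"), params, grid=grid)
        assert new.eta >= 0.0
        assert 0.0 <= new.B <= params.B_max

    def test_step_halving_first_order_consistency(self, params, grid, base_course):
        # Richardson check on a smooth stretch: the distance to a fine
        # reference halves when the step halves
        start = base_course.state_at(540.0)
        spec = builtin_treatment("none")

        def advance(dt, months=2.0):
            s = SlowState(t=start.t, B=start.B, eta=start.eta, G_f=start.G_f, A=start.A)
            for _ in range(int(round(months / dt))):
                s, _ = step(s, spec, params, grid=grid, dt=dt)
            return np.array([s.B, s.eta, s.G_f, s.A])

        ref = advance(0.25)
        e1 = np.linalg.norm(advance(1.0) - ref)
        e2 = np.linalg.norm(advance(0.5) - ref)
        assert 1.2 < e1 / e2 < 3.5


class TestScenarios:
    def test_determinism(self, params):
        config = t.ScenarioConfig(treatment="none", horizon=3.0)
        df1 = t.run_scenario(config, params=params).to_frame()
        df2 = t.run_scenario(config, params=params).to_frame()
        pd.testing.assert_frame_equal(df1, df2)

    def test_early_plateau_is_approximately_stationary(self, base_course):
        # before the age-18 perturbations start, the untreated subject sits
        # near a healthy steady state: bounded drift of G_f and B
        df = base_course.to_frame()
        early = df[(df.t_mo >= 24) & (df.t_mo <= 216)]
        assert early.Gf_mM.max() - early.Gf_mM.min() < 0.5
        assert early.B_Mc.max() / early.B_Mc.min() < 1.15
        # control values equal their baselines on the plateau
        c = base_course.state_at(216.0).controls
        assert c["k_XGI"] == base_course.params.k_XGI0max
        assert c["lam_GI"] == base_course.params.lam_GI0

    def test_headline_dynamics(self, base_course):
        # glycemia non-decreasing through the study window; beta-cell mass
        # peaks before enrollment and declines thereafter
        df = base_course.to_frame()
        window = df[(df.t_mo >= 600) & (df.t_mo <= 660)]
        assert np.all(np.diff(window.Gf_mM) >= -1e-9)
        assert df.t_mo[df.B_Mc.idxmax()] < 600
        late = df[df.t_mo >= 600]
        assert np.all(np.diff(late.B_Mc) < 0)

    def test_arms_identical_before_treatment_start(self, params):
        # with an early t_thx the four arms share the pre-treatment segment
        frames = {}
        for arm in ("none", "placebo", "lifestyle", "metformin"):
            config = t.ScenarioConfig(treatment=arm, horizon=30.0, t_thx=24.0)
            frames[arm] = t.run_scenario(config, params=params).to_frame()
        pre = lambda df: df[df.t_mo <= 24.0].reset_index(drop=True)
        for arm in ("placebo", "lifestyle", "metformin"):
            pd.testing.assert_frame_equal(pre(frames["none"]), pre(frames[arm]))
        # and diverge afterwards
        post = {a: f[f.t_mo == 30.0].Gf_mM.iloc[0] for a, f in frames.items()}
        assert post["lifestyle"] != post["none"]

    def test_lifestyle_lowers_two_hour_glycemia_vs_placebo(self, arm_branches):
        # the peripheral-sensitivity effect acts on post-load glycemia
        g2h = {a: c.ogtt[612.0].G[120] for a, c in arm_branches.items()}
        assert g2h["lifestyle"] < g2h["placebo"] < g2h["none"]

    def test_metformin_contrast_concentrated_on_fasting(self, arm_branches):
        # metformin and placebo share the peripheral effect; the extra
        # hepatic effect shows in fasting more than in 2-h glycemia
        # hepatic effect shows in fasting glycemia; the post-load excursion
        # (2-h minus fasting), which the peripheral channel governs, barely moves
        met = arm_branches["metformin"]
        pla = arm_branches["placebo"]
        d_gf = pla.state_at(612.0).G_f - met.state_at(612.0).G_f
        exc_pla = pla.ogtt[612.0].G[120] - pla.ogtt[612.0].G[0]
        exc_met = met.ogtt[612.0].G[120] - met.ogtt[612.0].G[0]
        assert d_gf > 0
        assert d_gf > abs(exc_pla - exc_met)

    def test_recorded_ogtt_starts_at_slow_glycemia(self, base_course):
        for tt, ogtt in base_course.ogtt.items():
            assert ogtt.G[0] == pytest.approx(base_course.state_at(tt).G_f, abs=1e-9)


class TestEndpoints:
    def test_extraction_at_enrollment(self, base_course):
        series = extract_endpoints(base_course, [600.0, 612.0])
        row = series.frame.iloc[0]
        assert row.visit_mo == 600.0
        assert row.Gf_mM == pytest.approx(base_course.state_at(600.0).G_f)
        assert row.G30_mM == base_course.ogtt[600.0].G[30]
        assert row.I30_pM == base_course.ogtt[600.0].I[30]

    def test_missing_ogtt_raises(self, base_course):
        with pytest.raises(KeyError):
            extract_endpoints(base_course, [601.0])

    def test_empty_visit_list(self, base_course):
        assert len(extract_endpoints(base_course, []).frame) == 0


class TestFixtureAndCompare:
    def test_zero_noise_equals_model(self, base_course):
        series = extract_endpoints(base_course, [600.0, 612.0])
        df = generate_fixture(0, endpoints=series, noise_sd={})
        pd.testing.assert_frame_equal(df, series.frame)

    def test_seed_reproducibility(self, base_course):
        series = extract_endpoints(base_course, [600.0, 612.0])
        sd = {"Gf_mM": 0.2}
        df1 = generate_fixture(7, endpoints=series, noise_sd=sd)
        df2 = generate_fixture(7, endpoints=series, noise_sd=sd)
        pd.testing.assert_frame_equal(df1, df2)
        df3 = generate_fixture(8, endpoints=series, noise_sd=sd)
        assert not df1.Gf_mM.equals(df3.Gf_mM)

    def test_noise_rms_matches_sd(self, base_course):
        # replicate the two-visit series to many rows for a Monte-Carlo check
        series = extract_endpoints(base_course, [600.0, 612.0])
        big = t.EndpointSeries(
            arm=series.arm,
            frame=pd.concat([series.frame] * 200, ignore_index=True),
        )
        df = generate_fixture(3, endpoints=big, noise_sd={"Gf_mM": 0.2})
        rms = np.sqrt(np.mean((df.Gf_mM - big.frame.Gf_mM) ** 2))
        assert rms == pytest.approx(0.2, rel=0.15)

    def test_compare_zero_and_uniform_shift(self, base_course):
        series = extract_endpoints(base_course, [600.0, 612.0])
        report = compare(series, series.frame)
        for col, stats in report["endpoints"].items():
            assert stats["rms"] == pytest.approx(0.0, abs=1e-12)
        shifted = series.frame.copy()
        shifted["Gf_mM"] += 0.5
        report = compare(series, shifted)
        assert report["endpoints"]["Gf_mM"]["rms"] == pytest.approx(0.5)
        assert report["endpoints"]["G2h_mM"]["rms"] == 0.0

    def test_compare_rejects_malformed_csv(self, base_course):
        series = extract_endpoints(base_course, [600.0, 612.0])
        bad = series.frame.drop(columns=["I30_pM"])
        with pytest.raises(ValueError, match="I30_pM"):
            compare(series, bad)

    def test_fixture_csv_dialect(self, base_course, tmp_path):
        series = extract_endpoints(base_course, [600.0, 612.0])
        path = tmp_path / "observed.csv"
        generate_fixture(0, endpoints=series, path=path)
        from t2dsim.driver import ENDPOINT_COLUMNS

        df = pd.read_csv(path)
        assert list(df.columns) == ENDPOINT_COLUMNS
        header = path.read_text().splitlines()[0]
        assert header == "visit_mo,arm,Gf_mM,G30_mM,G2h_mM,If_pM,I30_pM"
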