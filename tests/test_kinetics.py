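"""Change-point detection, dwell fits, survival analysis and statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ecfret as ef
from ecfret.kinetics import (
    compare_decay_rates, detect_transitions, first_dissociation_time,
    first_event_analysis, fit_ec50, fit_exponential_dwells, harvest_dwells,
    welch_anova_tukey,
)


class TestDetectTransitions:
    def test_noiseless_single_step_located_exactly(self):
        x = np.concatenate([np.full(200, 0.60), np.full(250, 0.08)])
        res = detect_transitions(x)
        assert res.n_transitions == 1
        assert res.change_points[0] == 200
        assert res.states[0] == "associated" and res.states[-1] == "dissociated"

    def test_pure_noise_rarely_produces_change_points(self):
        rng = np.random.default_rng(0)
        fp = sum(detect_transitions(0.6 + rng.normal(0, 0.06, 450)).n_transitions > 0
                 for _ in range(300))
        assert fp / 300 < 0.01

    def test_three_transition_trace_recovered_within_two_frames(self, cf_true):
        sc = ef.KineticScenario(frac_responsive=1, frac_inactive=0,
                                frac_donor_only=0, frac_acceptor_only=0)
        g0, g1 = sc.green_window
        found = 0
        trials = 0
        rng = np.random.default_rng(12)
        while trials < 20:
            tr, truth = ef.simulate_trace(sc, seed=rng, pre_equilibrated=True)
            ts = truth.transitions_in(g0, g1) - g0
            # well-separated transitions only (>= 2 s dwells on both sides)
            bounds = np.concatenate([[0.0], ts, [g1 - g0]])
            if len(ts) != 3 or np.min(np.diff(bounds)) < 2.0:
                continue
            trials += 1
            proc = ef.process_trace(tr, cf_true)
            det = detect_transitions(proc.E_raw).change_points * 0.2
            if len(det) == 3 and np.max(np.abs(det - ts)) <= 0.4 + 1e-9:
                found += 1
        assert found >= 18

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_transitions(np.ones(4), min_dwell=3)

    def test_deterministic_for_fixed_input(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([np.full(200, 0.6), np.full(250, 0.08)])
        x += rng.normal(0, 0.05, 450)
        r1 = detect_transitions(x)
        r2 = detect_transitions(x)
        assert np.array_equal(r1.change_points, r2.change_points)


class TestHarvestDwells:
    @staticmethod
    def _result(levels, lengths):
        x = np.concatenate([np.full(l, v) for v, l in zip(levels, lengths)])
        return detect_transitions(x)

    def test_two_transitions_give_one_complete_dwell(self):
        res = self._result([0.6, 0.08, 0.6], [100, 150, 200])
        dwells = harvest_dwells([res], frame_time=0.2)
        t, _ = dwells.complete("dissociated")
        assert t.size == 1
        assert t[0] == pytest.approx(150 * 0.2)
        assert set(dwells.censoring) == {"first", "complete", "last"}

    def test_static_trace_contributes_zero_complete_dwells(self):
        res = self._result([0.6], [450])
        dwells = harvest_dwells([res], frame_time=0.2)
        assert (dwells.censoring == "complete").sum() == 0

    def test_single_transition_trace_contributes_zero_complete_dwells(self):
        res = self._result([0.6, 0.08], [200, 250])
        dwells = harvest_dwells([res], frame_time=0.2)
        assert (dwells.censoring == "complete").sum() == 0


class TestExponentialFits:
    def test_mle_recovers_mean_of_large_exponential_sample(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(8.0, 10_000)
        fit = fit_exponential_dwells(t, min_dwell_s=0.0)
        assert fit.tau == pytest.approx(8.0, abs=0.25)

    def test_degenerate_equal_dwells_flagged_non_exponential(self):
        fit = fit_exponential_dwells(np.full(50, 5.0), min_dwell_s=0.0)
        assert "non-exponential" in fit.flags

    def test_truncated_mle_beats_naive_mean_under_window_censoring(self):
        # tau = 20 s inside a 90 s window: the naive mean underestimates,
        # the truncated likelihood recovers the true mean within 10 %
        rng = np.random.default_rng(3)
        raw = rng.exponential(20.0, 40_000)
        starts = rng.uniform(0, 60.0, raw.size)
        keep = raw < 90.0 - starts
        t, s = raw[keep], starts[keep]
        naive = fit_exponential_dwells(t, method="naive")
        trunc = fit_exponential_dwells(t, min_dwell_s=0.0, window_s=90.0,
                                       starts=s)
        assert naive.tau < 0.9 * 20.0
        assert trunc.tau == pytest.approx(20.0, rel=0.1)

    def test_small_samples_refused(self):
        with pytest.raises(ValueError, match="at least"):
            fit_exponential_dwells(np.ones(5))

    def test_histogram_lsq_agrees_on_clean_data(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(8.0, 20_000)
        fit = fit_exponential_dwells(t, method="lsq")
        assert fit.tau == pytest.approx(8.0, rel=0.1)
        assert np.isfinite(fit.amplitude)


class TestFirstEvent:
    def test_synchronized_events_make_a_step_curve(self):
        curve = first_event_analysis([5.0] * 20, window=90.0)
        assert curve.survival[0] == 1.0
        assert curve.evaluate(np.array([4.9]))[0] == 1.0
        assert curve.evaluate(np.array([5.1]))[0] == 0.0

    def test_exponential_events_recover_seven_second_half_life(self):
        rng = np.random.default_rng(5)
        events = rng.exponential(7.0 / np.log(2), 200)
        obs = [t if t < 90.0 else None for t in events]
        curve = first_event_analysis(obs, window=90.0)
        assert curve.half_life == pytest.approx(7.0, abs=1.0)

    def test_survival_curve_is_monotone_from_one(self):
        rng = np.random.default_rng(6)
        obs = list(rng.exponential(10.0, 50)) + [None] * 10
        curve = first_event_analysis(obs, window=40.0)
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 0)

    def test_delayed_arrival_keeps_curve_flat_during_dead_time(self):
        rng = np.random.default_rng(7)
        obs = list(10.0 + rng.exponential(8.0, 150))
        curve = first_event_analysis(obs, window=200.0)
        assert curve.evaluate(np.array([9.9]))[0] == 1.0
        assert curve.evaluate(np.array([40.0]))[0] < 0.2

    def test_no_events_yields_curve_without_fit(self):
        curve = first_event_analysis([None] * 10, window=90.0)
        assert np.isnan(curve.half_life) and curve.n_censored == 10

    def test_first_dissociation_time_reads_the_state_path(self):
        x = np.concatenate([np.full(100, 0.60), np.full(350, 0.08)])
        res = detect_transitions(x)
        t = first_dissociation_time(res, frame_time=0.2)
        assert t == pytest.approx(20.0)
        x_up = np.concatenate([np.full(100, 0.08), np.full(350, 0.60)])
        assert first_dissociation_time(detect_transitions(x_up), 0.2) is None


class TestCompareRates:
    def test_identical_fits_are_not_distinguished(self):
        t, p = compare_decay_rates((0.1, 0.01, 50), (0.1, 0.01, 50))
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_clearly_different_rates_detected(self):
        _, p = compare_decay_rates((0.1, 0.01, 50), (0.3, 0.01, 50))
        assert p < 1e-4

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(500):
            a = rng.exponential(5.0, 150)
            b = rng.exponential(5.0, 150)
            fa = (1 / a.mean(), 1 / a.mean() / np.sqrt(a.size), a.size)
            fb = (1 / b.mean(), 1 / b.mean() / np.sqrt(b.size), b.size)
            ps.append(compare_decay_rates(fa, fb)[1])
        _, p_ks = stats.kstest(ps, "uniform")
        assert p_ks > 0.01

    def test_missing_standard_error_rejected(self):
        with pytest.raises(ValueError):
            compare_decay_rates((0.1, np.nan, 10), (0.2, 0.01, 10))


class TestEC50:
    def test_exact_hyperbola_recovered_to_machine_precision(self):
        x = np.array([0, 50, 100, 200, 400, 800, 1600, 5000], float)
        y = 0.02 + 0.25 * x / (200.0 + x)
        fit = fit_ec50(x, y)
        assert fit.ec50 == pytest.approx(200.0, rel=1e-6)
        assert fit.floor == pytest.approx(0.02, abs=1e-6)
        assert fit.ceiling == pytest.approx(0.27, abs=1e-6)

    def test_constant_readout_flagged_without_dose_dependence(self):
        x = np.array([0, 10, 100, 1000], float)
        fit = fit_ec50(x, np.full(4, 0.2))
        assert "no_dose_dependence" in fit.flags
        assert fit.ci_ec50[1] == np.inf

    def test_unit_relabeling_scales_ec50_consistently(self):
        x = np.array([0, 50, 100, 200, 400, 800, 1600, 5000], float)
        rng = np.random.default_rng(9)
        y = 0.02 + 0.25 * x / (200.0 + x) + rng.normal(0, 0.004, x.size)
        fit_uM = fit_ec50(x, y)
        fit_mM = fit_ec50(x / 1000.0, y)
        assert fit_mM.ec50 * 1000.0 == pytest.approx(fit_uM.ec50, rel=1e-6)

    def test_pipeline_dose_panel_recovers_the_readout_ec50(self, cf_true):
        # oracle: EC50 of the expected dynamic-fraction curve from the CTMC
        from scipy.optimize import brentq
        sc = ef.KineticScenario()
        T = sc.n_frames_green * sc.frame_time
        fr = sc.frac_responsive * (1 - sc.frac_inactive)

        def p_dyn(atp):
            kd = sc.k_diss_max * atp / (sc.K_atp + atp)
            return fr * (1.0 - np.exp(-kd * T))

        half = 0.5 * (p_dyn(0) + p_dyn(1e12))
        oracle = brentq(lambda x: p_dyn(x) - half, 1e-3, 1e9)

        grid = [0, 5, 10, 25, 60, 150, 400, 1000, 10000]
        panel = ef.simulate_dose_response(sc, grid, n_traces=150, seed=11)
        fracs = []
        for atp in grid:
            labs = [ef.classify_trace(ef.process_trace(tr, cf_true)).label
                    for tr, truth in panel[float(atp)]
                    if truth.spot_class == "pair"]
            fracs.append(np.mean([l == "dynamic" for l in labs]))
        fit = fit_ec50(np.array(grid, float), np.array(fracs))
        # binomial noise at ~120 pair traces/level dominates the error
        assert fit.ec50 == pytest.approx(oracle, rel=0.40)
        assert fit.ci_ec50[0] < oracle < fit.ci_ec50[1]


class TestWelchAnova:
    # summaries of three normal samples; expected values frozen from R:
    # oneway.test(var.equal=FALSE) -> F = 3.9302, df = (2, 14.41), p = 0.04343
    R_GROUPS = [(9.378533000254789, 2.06582785629692, 8),
                (12.299610537709638, 2.3008565978281847, 10),
                (11.215148756004979, 1.7446687870693058, 7)]

    def test_matches_published_welch_f_to_four_decimals(self):
        res = welch_anova_tukey(self.R_GROUPS)
        assert res.F == pytest.approx(3.9302, abs=1e-4)
        assert res.df2 == pytest.approx(14.41, abs=0.01)
        assert res.p_omnibus == pytest.approx(0.04343, abs=1e-5)

    def test_identical_groups_give_f_near_zero(self):
        res = welch_anova_tukey([(10.0, 2.0, 9)] * 3)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p_omnibus > 0.99

    def test_pairwise_table_covers_all_pairs_two_tailed(self):
        res = welch_anova_tukey(self.R_GROUPS, labels=["apo", "atp", "b12"])
        assert len(res.pairwise) == 3
        assert ((res.pairwise["p"] >= 0) & (res.pairwise["p"] <= 1)).all()

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_anova_tukey([(10, 0.0, 5), (11, 1.0, 5)])
        with pytest.raises(ValueError):
            welch_anova_tukey([(10, 1.0, 1), (11, 1.0, 5)])

    @settings(deadline=None, max_examples=20)
    @given(st.floats(-50, 50))
    def test_location_shift_leaves_f_unchanged(self, shift):
        res0 = welch_anova_tukey(self.R_GROUPS)
        shifted = [(m + shift, s, n) for m, s, n in self.R_GROUPS]
        res1 = welch_anova_tukey(shifted)
        assert res1.F == pytest.approx(res0.F, rel=1e-9)
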