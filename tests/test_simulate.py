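"""Forward-simulator behaviour: kinetics, rendering, movies, photon streams."""

import numpy as np
import pytest
from scipy import stats

import ecfret as ef
from ecfret.simulate import (
    ASSOCIATED, DISSOCIATED, GroundTruth, SPOT_ACCEPTOR_ONLY, SPOT_DONOR_ONLY,
    render_trace, simulate_movie, simulate_photon_stream, simulate_state_path,
)


def responsive_scenario(**kw):
    defaults = dict(frac_responsive=1.0, frac_inactive=0.0,
                    frac_donor_only=0.0, frac_acceptor_only=0.0)
    defaults.update(kw)
    return ef.KineticScenario(**defaults)


class TestScenario:
    def test_half_saturation_gives_half_maximal_dissociation_rate(self):
        sc = responsive_scenario(k_diss_max=1.0, K_atp=200.0, atp=200.0)
        assert sc.k_diss == pytest.approx(0.5)

    def test_zero_atp_means_zero_dissociation(self):
        assert responsive_scenario(atp=0.0).k_diss == 0.0

    @pytest.mark.parametrize("field,value", [
        ("k_assoc", -0.1), ("E_assoc", 1.5), ("frac_responsive", -0.2),
        ("n_frames_green", 0), ("atp", -1.0),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ValueError):
            responsive_scenario(**{field: value})

    def test_single_dye_fractions_bounded(self):
        with pytest.raises(ValueError):
            responsive_scenario(frac_donor_only=0.6, frac_acceptor_only=0.6)


class TestStatePath:
    def test_zero_atp_path_is_absorbing_associated(self):
        sc = responsive_scenario(atp=0.0)
        truth = simulate_state_path(sc, 1000.0, seed=1)
        assert truth.initial_state == ASSOCIATED
        assert truth.transition_times.size == 0

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_state_path(responsive_scenario(), -5.0, seed=0)

    def test_stationary_occupancy_matches_ctmc(self):
        # k_assoc = 0.05, k_diss = 0.125 -> associated fraction 0.05/0.175
        sc = responsive_scenario(k_assoc=0.05, k_diss_max=0.125, K_atp=1.0,
                                 atp=1e9)
        occs = []
        for seed in range(3):
            truth = simulate_state_path(sc, 1e4, seed=seed,
                                        pre_equilibrated=True)
            occs.append(truth.associated_occupancy(np.array([0.0, 1e4]))[0])
        expected = 0.05 / 0.175
        # SE of the time-average from renewal theory, ~3 sigma band
        n_cycles = 1e4 / (1 / 0.05 + 1 / 0.125)
        se = expected * (1 - expected) / np.sqrt(n_cycles) * 2.0
        assert abs(np.mean(occs) - expected) < 3 * se / np.sqrt(3)

    @pytest.mark.parametrize("k_assoc,k_diss", [(0.05, 0.125), (0.125, 0.05),
                                                (0.1, 0.1)])
    def test_occupancy_converges_at_multiple_rate_pairs(self, k_assoc, k_diss):
        sc = responsive_scenario(k_assoc=k_assoc, k_diss_max=k_diss,
                                 K_atp=1.0, atp=1e9)
        truth = simulate_state_path(sc, 3e4, seed=7, pre_equilibrated=True)
        occ = truth.associated_occupancy(np.array([0.0, 3e4]))[0]
        assert occ == pytest.approx(k_assoc / (k_assoc + k_diss), abs=0.03)

    def test_dwell_durations_are_exponential(self):
        # Lilliefors-style KS against Exp(1/k) on >= 1e4 harvested dwells
        sc = responsive_scenario(k_assoc=1.0, k_diss_max=1.0, K_atp=1.0,
                                 atp=1e9)
        truth = simulate_state_path(sc, 25_000.0, seed=11,
                                    pre_equilibrated=True)
        ts = truth.transition_times
        mids = (ts[:-1] + ts[1:]) / 2
        states = truth.state_at(mids)
        dwells = np.diff(ts)[states == ASSOCIATED]
        assert dwells.size >= 1e4
        _, p = stats.kstest(dwells, "expon", args=(0, 1.0))
        assert p > 0.01

    def test_nonresponsive_molecules_never_dissociate(self):
        sc = responsive_scenario(frac_responsive=0.0)
        truth = simulate_state_path(sc, 500.0, seed=3)
        assert truth.transition_times.size == 0 and not truth.responsive

    def test_activation_time_delays_first_dissociation(self):
        sc = responsive_scenario(k_diss_max=5.0, K_atp=1.0, atp=1e9)
        for seed in range(20):
            truth = simulate_state_path(sc, 100.0, seed=seed,
                                        t_activation=10.0)
            if truth.transition_times.size:
                assert truth.transition_times[0] >= 10.0

    def test_transition_times_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            GroundTruth(ASSOCIATED, np.array([5.0, 5.0]), 10.0)


class TestRenderTrace:
    def test_noiseless_associated_trace_reproduces_state_efficiency(self):
        sc = responsive_scenario(noise_sd=0.0, leakage=0.0, direct_exc=0.0,
                                 atp=0.0)
        tr, _ = ef.simulate_trace(sc, seed=1)
        g = tr.green
        E = (tr.I_A - tr.bg_A)[g] / ((tr.I_D - tr.bg_D)[g] + (tr.I_A - tr.bg_A)[g])
        np.testing.assert_allclose(E, sc.E_assoc, atol=1e-12)

    def test_leakage_term_matches_closed_form(self):
        # dissociated state with E_diss = 0: acceptor = leakage * donor
        # + direct excitation + background, exactly
        sc = responsive_scenario(noise_sd=0.0, leakage=0.1, direct_exc=0.05,
                                 E_diss=0.0, atp=0.0)
        truth = GroundTruth(DISSOCIATED, np.array([]), sc.duration)
        tr = render_trace(truth, sc, seed=0)
        g = tr.green
        I_D0 = (tr.I_D - tr.bg_D)[g]
        expected = 0.1 * I_D0 + 0.05 * sc.total_intensity + tr.bg_A[g]
        np.testing.assert_allclose(tr.I_A[g], expected, atol=1e-9)

    def test_acceptor_bleach_drops_fret_and_red_tail_signal(self):
        # leakage off so the acceptor channel carries only FRET signal
        sc = responsive_scenario(noise_sd=0.0, leakage=0.0, direct_exc=0.0,
                                 atp=0.0)
        truth = GroundTruth(ASSOCIATED, np.array([]), sc.duration,
                            bleach_time_a=30.0)
        tr = render_trace(truth, sc, seed=0)
        g, tail = tr.green, tr.mask("red_tail")
        after = g & (tr.time > 31.0)
        np.testing.assert_allclose((tr.I_A - tr.bg_A)[after], 0.0, atol=1e-9)
        np.testing.assert_allclose((tr.I_AA - tr.bg_A)[tail], 0.0, atol=1e-9)
        # donor recovers its full emission once FRET is lost
        np.testing.assert_allclose((tr.I_D - tr.bg_D)[after],
                                   sc.total_intensity, atol=1e-9)

    def test_single_dye_spots_emit_as_expected(self):
        sc = responsive_scenario(noise_sd=0.0, leakage=0.1, direct_exc=0.05,
                                 atp=0.0)
        d_truth = GroundTruth(ASSOCIATED, np.array([]), sc.duration,
                              spot_class=SPOT_DONOR_ONLY)
        d_tr = render_trace(d_truth, sc, seed=0)
        g = d_tr.green
        np.testing.assert_allclose((d_tr.I_A - d_tr.bg_A)[g],
                                   0.1 * sc.total_intensity, atol=1e-9)
        assert np.allclose((d_tr.I_AA - d_tr.bg_A)[~g], 0.0, atol=1e-9)
        a_truth = GroundTruth(ASSOCIATED, np.array([]), sc.duration,
                              spot_class=SPOT_ACCEPTOR_ONLY)
        a_tr = render_trace(a_truth, sc, seed=0)
        np.testing.assert_allclose((a_tr.I_D - a_tr.bg_D)[g], 0.0, atol=1e-9)
        np.testing.assert_allclose((a_tr.I_AA - a_tr.bg_A)[~g],
                                   sc.total_intensity, atol=1e-9)

    def test_seed_determinism_is_bit_identical(self):
        sc = responsive_scenario()
        t1, g1 = ef.simulate_trace(sc, seed=42)
        t2, g2 = ef.simulate_trace(sc, seed=42)
        assert np.array_equal(t1.I_D, t2.I_D)
        assert np.array_equal(t1.I_A, t2.I_A)
        assert np.array_equal(g1.transition_times, g2.transition_times)


class TestBenchmark:
    def test_mixture_labels_match_hidden_paths(self):
        traces, labels = ef.simulate_benchmark(n_traces=60, seed=5)
        assert set(labels) <= {"dynamic", "static_high", "static_low"}
        assert labels.count("dynamic") > 0
        for tr, lab in zip(traces, labels):
            assert tr.metadata["truth_label"] == lab


class TestMovie:
    def test_empty_field_has_no_spots_downstream(self):
        from ecfret.extraction import detect_spots
        stack, centers = simulate_movie([], shape=(32, 32), bg=10.0,
                                        noise_sd=1.0, seed=0)
        assert centers.shape == (0, 2)
        assert detect_spots(np.repeat(stack, 60, axis=0), threshold=20.0,
                            layout=(5, 50, 5)) == []

    def test_overlapping_spot_placement_rejected(self):
        sc = responsive_scenario(noise_sd=0.0)
        tr, _ = ef.simulate_trace(sc, seed=1)
        with pytest.raises(ValueError, match="separation"):
            simulate_movie([tr, tr], shape=(48, 48),
                           centers=[(20, 20), (22, 21)], min_separation=6.0,
                           seed=0)

    def test_single_spot_aperture_mass_matches_analytic_psf_fraction(self):
        from ecfret.extraction import gaussian_aperture_fraction
        sc = responsive_scenario(noise_sd=0.0, bg_D_mean=0.0, bg_A_mean=0.0,
                                 atp=0.0)
        tr, _ = ef.simulate_trace(sc, seed=1)
        stack, centers = simulate_movie([tr], shape=(32, 32),
                                        centers=[(16, 16)], psf_sigma=1.2,
                                        bg=0.0, noise_sd=0.0, seed=0)
        yy, xx = np.mgrid[0:32, 0:32]
        ap = (yy - 16) ** 2 + (xx - 16) ** 2 <= 9
        g = tr.green
        summed = stack[:, :, :32][:, ap].sum(axis=1)[g]
        frac = gaussian_aperture_fraction(1.2, 3)
        ratio = summed.mean() / (tr.I_D - tr.bg_D)[g].mean()
        # discrete pixel grid vs continuous Gaussian: ~1% agreement
        assert ratio == pytest.approx(frac, rel=0.02)


class TestPhotonStream:
    def test_bright_symmetric_bursts_average_half_efficiency(self):
        stream, intervals = simulate_photon_stream(
            n_bursts=200, duration=30.0, E_true=0.5, S_true=0.5,
            burst_rate=200_000.0, bg_rate_dd=0.0, bg_rate_da=0.0,
            bg_rate_aa=0.0, seed=4)
        es = []
        for t0, t1 in intervals:
            m = (stream.timestamps >= t0) & (stream.timestamps <= t1)
            dexc = stream.excitation[m] == 0
            n_da = np.sum(stream.detector[m][dexc] == 1)
            n_dd = np.sum(stream.detector[m][dexc] == 0)
            es.append(n_da / (n_da + n_dd))
        assert np.mean(es) == pytest.approx(0.5, abs=0.01)

    def test_stream_is_sorted_and_duration_covers_it(self):
        stream, _ = simulate_photon_stream(n_bursts=50, duration=10.0, seed=2)
        assert np.all(np.diff(stream.timestamps) >= 0)
        assert stream.duration >= stream.timestamps[-1]

    def test_photon_stream_io_round_trips(self, tmp_path):
        from ecfret.io import (read_photon_hdf5, read_photon_text,
                               write_photon_hdf5, write_photon_text)
        stream, _ = simulate_photon_stream(n_bursts=20, duration=5.0, seed=3)
        write_photon_hdf5(stream, tmp_path / "s.h5")
        back = read_photon_hdf5(tmp_path / "s.h5")
        np.testing.assert_allclose(back.timestamps, stream.timestamps)
        assert np.array_equal(back.detector, stream.detector)
        write_photon_text(stream, tmp_path / "s.tsv")
        back2 = read_photon_text(tmp_path / "s.tsv")
        np.testing.assert_allclose(back2.timestamps, stream.timestamps,
                                   atol=1e-9)
        assert back2.duration == pytest.approx(stream.duration)


class TestDosePanel:
    def test_grid_validation(self):
        sc = responsive_scenario()
        with pytest.raises(ValueError):
            ef.simulate_dose_response(sc, [0, 100], 5, seed=0)
        with pytest.raises(ValueError):
            ef.simulate_dose_response(sc, [-1, 0, 10, 100], 5, seed=0)

    def test_levels_share_everything_but_atp(self):
        sc = responsive_scenario()
        panel = ef.simulate_dose_response(sc, [0, 10, 100, 1000], 3, seed=1)
        assert set(panel) == {0.0, 10.0, 100.0, 1000.0}
        tr, _ = panel[10.0][0]
        assert tr.metadata["atp_uM"] == 10.0
        assert tr.n_frames == sc.n_frames
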