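"""Decay moments, mean-lifetime estimator, phasor transform and fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axonatp import (
    DegenerateDataError,
    IRFHistogram,
    MultiExpModel,
    PhasorPoint,
    fit_multiexp,
    histogram_moments,
    make_bin_times,
    mean_lifetime,
    mono_exp_phasor,
    phasor_transform,
    semicircle_distance,
    simulate_decay,
)

F_R = 8.0e7
NS = 1e-9


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

class TestHistogramMoments:
    def test_single_count(self, hist_factory):
        # one photon in the bin centred at 3.05 ns (bin_width 0.1)
        counts = np.zeros(64)
        counts[30] = 1
        h = hist_factory(counts)
        m0, m1 = histogram_moments(h)
        assert m0 == 1
        assert m1 == pytest.approx(h.bin_times[30])

    def test_two_counts(self, hist_factory):
        counts = np.zeros(64)
        counts[10] = 1
        counts[30] = 1
        h = hist_factory(counts)
        m0, m1 = histogram_moments(h)
        assert m0 == 2
        assert m1 == pytest.approx(h.bin_times[10] + h.bin_times[30])

    def test_matches_naive_loop(self, hist_factory, rng):
        counts = rng.integers(0, 50, size=256)
        h = hist_factory(counts)
        m0, m1 = histogram_moments(h)
        m0_ref = sum(int(c) for c in counts)
        m1_ref = sum(t * int(c) for t, c in zip(h.bin_times, counts))
        assert m0 == m0_ref  # integer sum is exact
        assert m1 == pytest.approx(m1_ref, rel=1e-12)

    def test_all_zero_raises(self, hist_factory):
        with pytest.raises(DegenerateDataError):
            histogram_moments(hist_factory(np.zeros(16)))


# ---------------------------------------------------------------------------
# mean lifetime
# ---------------------------------------------------------------------------

class TestMeanLifetime:
    def test_mono_exponential(self, long_window_cfg, delta_irf, mono_model):
        d = simulate_decay(mono_model, delta_irf, 10**6, long_window_cfg,
                           expectation=True)
        res = mean_lifetime(d, delta_irf)
        assert res.tau_bar == pytest.approx(2.0, abs=0.01)

    def test_irf_shift_cancels(self, long_window_cfg, mono_model):
        # IRF moved to 1 ns: tau_bar unchanged via the H1/H0 correction
        cfg = long_window_cfg
        counts = np.zeros(cfg.n_bins)
        counts[10] = 1.0  # centred at 1.05 ns
        irf = IRFHistogram(bin_times=cfg.bin_times, counts=counts,
                           bin_width=cfg.bin_width,
                           rep_frequency=cfg.rep_frequency)
        d = simulate_decay(mono_model, irf, 10**6, cfg, expectation=True)
        res = mean_lifetime(d, irf)
        assert res.tau_bar == pytest.approx(2.0, abs=0.01)

    def test_bi_exponential_mean(self, long_window_cfg, delta_irf, bi_model):
        # independent closed form: sum(A_j tau_j) / sum(A_j)
        expected = (0.3 * 0.5 + 0.7 * 3.0) / (0.3 + 0.7)
        d = simulate_decay(bi_model, delta_irf, 10**6, long_window_cfg,
                           expectation=True)
        res = mean_lifetime(d, delta_irf)
        assert expected == pytest.approx(2.25)
        assert res.tau_bar == pytest.approx(expected, abs=0.01)

    def test_translation_invariance(self, long_window_cfg, delta_irf,
                                    mono_model):
        d = simulate_decay(mono_model, delta_irf, 10**6, long_window_cfg,
                           expectation=True)
        shift = 7  # bins
        cfg = long_window_cfg
        d_shift = type(d)(bin_times=d.bin_times,
                          counts=np.roll(d.counts, shift),
                          bin_width=d.bin_width,
                          rep_frequency=d.rep_frequency)
        irf_shift = IRFHistogram(bin_times=cfg.bin_times,
                                 counts=np.roll(delta_irf.counts, shift),
                                 bin_width=cfg.bin_width,
                                 rep_frequency=cfg.rep_frequency)
        base = mean_lifetime(d, delta_irf).tau_bar
        # tail rolled around is negligible at 100 ns >> 2 ns
        shifted = mean_lifetime(d_shift, irf_shift).tau_bar
        assert shifted == pytest.approx(base, abs=1e-6)

    def test_scale_invariance(self, long_window_cfg, delta_irf, mono_model):
        d = simulate_decay(mono_model, delta_irf, 10**5, long_window_cfg,
                           rng=np.random.default_rng(7))
        scaled = type(d)(bin_times=d.bin_times, counts=d.counts * 13,
                         bin_width=d.bin_width, rep_frequency=d.rep_frequency)
        assert mean_lifetime(scaled, delta_irf).tau_bar == pytest.approx(
            mean_lifetime(d, delta_irf).tau_bar, rel=1e-12
        )

    def test_background_subtraction(self, long_window_cfg, delta_irf,
                                    mono_model):
        d = simulate_decay(mono_model, delta_irf, 10**6, long_window_cfg,
                           expectation=True)
        polluted = type(d)(bin_times=d.bin_times, counts=d.counts + 50.0,
                           bin_width=d.bin_width,
                           rep_frequency=d.rep_frequency)
        # constant background pulls tau_bar toward the window midpoint
        biased = mean_lifetime(polluted, delta_irf).tau_bar
        corrected = mean_lifetime(polluted, delta_irf, background=50.0).tau_bar
        assert abs(corrected - 2.0) < 0.01 < abs(biased - 2.0)

    def test_geometry_mismatch_raises(self, hist_factory, delta_irf):
        d = hist_factory(np.ones(64))
        with pytest.raises(ValueError):
            mean_lifetime(d, delta_irf)


# ---------------------------------------------------------------------------
# phasor
# ---------------------------------------------------------------------------

class TestPhasor:
    def test_counts_at_delta_irf_give_zero_phase(self, long_window_cfg):
        cfg = long_window_cfg
        irf_counts = np.zeros(cfg.n_bins)
        irf_counts[40] = 1.0
        irf = IRFHistogram(bin_times=cfg.bin_times, counts=irf_counts,
                           bin_width=cfg.bin_width,
                           rep_frequency=cfg.rep_frequency)
        from axonatp import DecayHistogram

        decay = DecayHistogram(bin_times=cfg.bin_times, counts=irf_counts,
                               bin_width=cfg.bin_width,
                               rep_frequency=cfg.rep_frequency)
        p = phasor_transform(decay, irf)
        assert p.g == pytest.approx(1.0, abs=1e-12)
        assert p.s == pytest.approx(0.0, abs=1e-12)

    def test_mono_exp_at_s_maximum(self):
        # tau = 1/(2 pi f_r): the lifetime with the highest s coordinate
        from axonatp import SimConfig

        tau = 1.0 / (2 * math.pi * F_R) / NS  # ns
        period = 1.0 / F_R / NS
        cfg = SimConfig(seed=0, rep_frequency=F_R, bin_width=period / 500,
                        n_bins=500, irf_center=0.0, irf_width_sigma=0.0,
                        wrap=True)
        irf_counts = np.zeros(cfg.n_bins)
        irf_counts[0] = 1.0
        irf = IRFHistogram(bin_times=cfg.bin_times, counts=irf_counts,
                           bin_width=cfg.bin_width, rep_frequency=F_R)
        d = simulate_decay(MultiExpModel([1.0], [tau]), irf, 10**6, cfg,
                           expectation=True)
        p = phasor_transform(d, irf)
        assert p.g == pytest.approx(0.5, abs=1e-3)
        assert p.s == pytest.approx(0.5, abs=1e-3)

    def test_matches_naive_loop(self, hist_factory, rng):
        counts = rng.integers(0, 100, size=128).astype(float)
        counts[0] += 1  # ensure nonzero
        h = hist_factory(counts)
        irf_counts = np.zeros(128)
        irf_counts[3] = 1.0
        irf = hist_factory(irf_counts, cls=IRFHistogram)
        p = phasor_transform(h, irf)
        omega = 2 * math.pi * h.rep_frequency * NS
        g_ref = sum(
            c * math.cos(omega * (t - irf.delta_irf))
            for t, c in zip(h.bin_times, counts)
        ) / counts.sum()
        s_ref = sum(
            c * math.sin(omega * (t - irf.delta_irf))
            for t, c in zip(h.bin_times, counts)
        ) / counts.sum()
        assert p.g == pytest.approx(g_ref, rel=1e-12)
        assert p.s == pytest.approx(s_ref, rel=1e-12)


class TestMonoExpPhasorClosedForm:
    @pytest.mark.parametrize(
        "tau, expected_g, expected_s",
        [
            (0.0, 1.0, 0.0),
            (1.0 / (2 * math.pi * F_R) / NS, 0.5, 0.5),
        ],
    )
    def test_reference_points(self, tau, expected_g, expected_s):
        p = mono_exp_phasor(tau, F_R)
        assert p.g == pytest.approx(expected_g, abs=1e-12)
        assert p.s == pytest.approx(expected_s, abs=1e-12)

    def test_long_lifetime_limit(self):
        p = mono_exp_phasor(1e6 / (2 * math.pi * F_R) / NS, F_R)
        assert p.g < 1e-5 and p.s < 1e-5

    def test_negative_tau_raises(self):
        with pytest.raises(ValueError):
            mono_exp_phasor(-1.0, F_R)

    @given(st.floats(min_value=1e-4, max_value=1e4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_on_semicircle_everywhere(self, tau):
        assert semicircle_distance(mono_exp_phasor(tau, F_R)) == pytest.approx(
            0.25, abs=1e-12
        )

    def test_g_strictly_decreasing_in_tau(self):
        # longer lifetimes shift the phasor counter-clockwise (g decreases)
        taus = np.linspace(0.0, 50.0, 500)
        gs = [mono_exp_phasor(t, F_R).g for t in taus]
        assert np.all(np.diff(gs) < 0)


class TestSemicircleDistance:
    def test_tau_zero_point(self):
        assert semicircle_distance(PhasorPoint(1.0, 0.0)) == pytest.approx(0.25)
        assert semicircle_distance(PhasorPoint(1.0, 0.0), squared=False) == (
            pytest.approx(0.5)
        )

    def test_centre(self):
        assert semicircle_distance(PhasorPoint(0.5, 0.0)) == 0.0

    def test_mixture_falls_inside(self):
        p1 = mono_exp_phasor(0.5, F_R)
        p2 = mono_exp_phasor(3.0, F_R)
        mix = PhasorPoint(0.5 * (p1.g + p2.g), 0.5 * (p1.s + p2.s))
        assert semicircle_distance(mix) < 0.25


# ---------------------------------------------------------------------------
# multi-exponential fit
# ---------------------------------------------------------------------------

class TestFitMultiexp:
    def test_mono_exponential_recovery(self, long_window_cfg, delta_irf,
                                       mono_model):
        d = simulate_decay(mono_model, delta_irf, 10**6, long_window_cfg,
                           expectation=True)
        res = fit_multiexp(d, delta_irf, m=1)
        assert res.success
        assert res.model.lifetimes[0] == pytest.approx(2.0, abs=0.02)

    def test_bi_exponential_recovery(self, long_window_cfg, delta_irf,
                                     bi_model):
        d = simulate_decay(bi_model, delta_irf, 10**6, long_window_cfg,
                           rng=np.random.default_rng(42))
        res = fit_multiexp(d, delta_irf, m=2)
        assert res.success
        assert res.model.lifetimes[0] == pytest.approx(0.5, rel=0.10)
        assert res.model.lifetimes[1] == pytest.approx(3.0, rel=0.10)

    def test_overfit_mono_preserves_mean(self, long_window_cfg, delta_irf,
                                         mono_model):
        # m=2 on mono-exponential data: the amplitude-weighted mean is
        # identifiable even when the split is not
        d = simulate_decay(mono_model, delta_irf, 10**6, long_window_cfg,
                           expectation=True)
        res = fit_multiexp(d, delta_irf, m=2)
        moment = mean_lifetime(d, delta_irf).tau_bar
        assert res.mean_lifetime == pytest.approx(moment, rel=0.01)

    def test_low_counts_rejected(self, hist_factory, delta_irf,
                                 long_window_cfg):
        counts = np.zeros(long_window_cfg.n_bins)
        counts[5] = 10
        d = hist_factory(counts)
        with pytest.raises(DegenerateDataError):
            fit_multiexp(d, delta_irf, m=1)
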