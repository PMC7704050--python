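"""F/C ratio, two-point normalization, and kinetics operators."""

import numpy as np
import pytest

from axonatp import (
    ChannelTimeSeries,
    Epoch,
    NormalizedTrace,
    ProtocolSpec,
    fc_ratio,
    gen_ratio_timeseries,
    max_slope_rate,
    normalize_trace,
    onset_delay,
    ramp_protocol,
    ramp_step_levels,
    recovery_amplitude,
    yfp_stability,
)


def make_series(time, cfp, fret, protocol, yfp=None):
    n = len(time)
    return ChannelTimeSeries(
        time=np.asarray(time, float),
        cfp=np.asarray(cfp, float),
        fret=np.asarray(fret, float),
        yfp=np.full(n, 100.0) if yfp is None else np.asarray(yfp, float),
        protocol=protocol,
    )


def make_trace(time, value, protocol):
    return NormalizedTrace(time=np.asarray(time, float),
                           value=np.asarray(value, float),
                           protocol=protocol, baseline_mean_raw=1.0)


class TestFcRatio:
    def test_equal_channels_give_one(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        s = make_series(t, np.full(t.size, 50.0), np.full(t.size, 50.0),
                        short_protocol)
        assert np.all(fc_ratio(s) == 1.0)

    def test_double_fret_gives_two(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        s = make_series(t, np.full(t.size, 50.0), np.full(t.size, 100.0),
                        short_protocol)
        assert np.all(fc_ratio(s) == 2.0)

    def test_matches_elementwise_division(self, short_protocol, rng):
        t = np.arange(0.0, 2400.0, 10.4)
        cfp = rng.uniform(10, 100, t.size)
        fret = rng.uniform(10, 100, t.size)
        s = make_series(t, cfp, fret, short_protocol)
        ref = [f / c for f, c in zip(fret, cfp)]
        assert np.allclose(fc_ratio(s), ref, rtol=1e-15)

    def test_nonpositive_cfp_names_the_sample(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        cfp = np.full(t.size, 50.0)
        cfp[7] = 0.0
        s = make_series(t, cfp, np.full(t.size, 50.0), short_protocol)
        with pytest.raises(ValueError, match="index 7"):
            fc_ratio(s)


class TestNormalizeTrace:
    def test_anchor_mapping(self, short_protocol, gd_kinetics):
        series, _ = gen_ratio_timeseries(short_protocol, gd_kinetics,
                                         noise_sd=0.005,
                                         rng=np.random.default_rng(1))
        trace = normalize_trace(series.time, fc_ratio(series), short_protocol)
        base = short_protocol.baseline
        assert trace.epoch_values("baseline").mean() == pytest.approx(1.0,
                                                                      abs=1e-12)
        mbgd = short_protocol.single("MBGD")
        tail = (trace.time >= mbgd.end - 120.0) & (trace.time < mbgd.end)
        assert trace.value[tail].mean() == pytest.approx(0.0, abs=1e-12)
        del base

    def test_affine_midpoint(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        raw = np.where(t < 300.0, 2.0, np.where(t >= 2280.0, 1.0, 1.5))
        trace = normalize_trace(t, raw, short_protocol)
        mid = (t >= 300.0) & (t < 2280.0)
        assert np.allclose(trace.value[mid], 0.5)

    def test_idempotence(self, short_protocol, gd_kinetics):
        series, _ = gen_ratio_timeseries(short_protocol, gd_kinetics)
        t = series.time
        trace = normalize_trace(t, fc_ratio(series), short_protocol)
        again = normalize_trace(t, trace.value, short_protocol)
        assert np.allclose(again.value, trace.value, atol=1e-12)

    def test_affine_equivariance(self, short_protocol, gd_kinetics):
        series, _ = gen_ratio_timeseries(short_protocol, gd_kinetics)
        raw = fc_ratio(series)
        a = normalize_trace(series.time, raw, short_protocol)
        b = normalize_trace(series.time, 3.0 * raw + 0.7, short_protocol)
        assert np.allclose(a.value, b.value, atol=1e-10)

    def test_degenerate_anchors(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_trace(t, np.ones(t.size), short_protocol)


class TestMaxSlopeRate:
    def test_linear_segment_recovered_exactly(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        trace = make_trace(t, 1.0 - 0.01 * t, short_protocol)
        assert max_slope_rate(trace) == pytest.approx(-0.01, rel=1e-9)

    def test_flat_then_linear(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        v = np.where(t < 600.0, 1.0, 1.0 - 0.002 * (t - 600.0))
        trace = make_trace(t, v, short_protocol)
        # the maximal-magnitude window sits inside the linear part
        assert max_slope_rate(trace) == pytest.approx(-0.002, rel=1e-6)

    def test_exponential_initial_rate(self, short_protocol):
        tau = 300.0
        t = np.arange(0.0, 2400.0, 10.4)
        v = np.exp(-t / tau)
        trace = make_trace(t, v, short_protocol)
        rate = max_slope_rate(trace)
        # calculus oracle: derivative at 0 is -1/tau; a trailing window of
        # span W biases the estimate by at most a factor ~W/(2 tau)
        W = 52.0
        assert rate < 0
        assert abs(rate) <= 1.0 / tau
        assert abs(rate) >= (1.0 / tau) * (1 - W / tau)

    def test_epoch_restriction(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        v = np.where(t < 900.0, 1.0, 0.0)  # step at reperfusion start
        trace = make_trace(t, v, short_protocol)
        # GD epoch ends at 900; windows inside GD never see the step
        assert max_slope_rate(trace, epoch="GD") == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_short_epoch_rejected(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        trace = make_trace(t, np.ones(t.size), short_protocol)
        with pytest.raises(ValueError):
            max_slope_rate(trace, epoch=(890.0, 900.0))


class TestOnsetDelay:
    def test_immediate_rise_detected_within_one_sample(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        v = np.where(t < 900.0, 0.2, 0.2 + 0.01 * (t - 900.0))
        trace = make_trace(t, v, short_protocol)
        delay = onset_delay(trace, 900.0, direction="up")
        assert delay <= 2 * 10.4

    def test_flat_trace_not_detected(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        trace = make_trace(t, np.full(t.size, 0.5), short_protocol)
        assert np.isnan(onset_delay(trace, 900.0))

    def test_value_mode(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        v = np.where(t < 1100.0, 1.0, 2.0)
        trace = make_trace(t, v, short_protocol)
        delay = onset_delay(trace, 900.0, mode="value", direction="up")
        assert delay == pytest.approx(200.0, abs=10.5)

    def test_event_outside_trace(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        trace = make_trace(t, np.ones(t.size), short_protocol)
        with pytest.raises(ValueError):
            onset_delay(trace, 5000.0)


class TestRecoveryAmplitude:
    def test_full_recovery_reads_one(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        trace = make_trace(t, np.ones(t.size), short_protocol)
        assert recovery_amplitude(trace) == pytest.approx(1.0)

    @pytest.mark.parametrize("plateau", [0.6, 0.82])
    def test_generator_plateau_recovered(self, short_protocol, gd_kinetics,
                                         plateau):
        kin = {**gd_kinetics,
               "reperfusion": {"delay_s": 60.0, "tau_s": 80.0,
                               "plateau": plateau}}
        series, _ = gen_ratio_timeseries(short_protocol, kin, noise_sd=0.0)
        trace = normalize_trace(series.time, fc_ratio(series), short_protocol)
        assert recovery_amplitude(trace) == pytest.approx(plateau, abs=1e-3)

    def test_empty_window_rejected(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        trace = make_trace(t, np.ones(t.size), short_protocol)
        with pytest.raises(ValueError):
            recovery_amplitude(trace, (1700.0, 1700.0))


class TestRampStepLevels:
    def test_constant_trace(self):
        protocol = ramp_protocol()
        t = np.arange(0.0, protocol.end, 10.4)
        trace = make_trace(t, np.full(t.size, 0.8), protocol)
        levels = ramp_step_levels(trace)
        assert list(levels.index) == [1, 4, 7, 15, 25, 50, 75, 100]
        assert np.allclose(levels.to_numpy(), 0.8)

    def test_staircase_recovered_exactly(self):
        protocol = ramp_protocol()
        t = np.arange(0.0, protocol.end, 1.0)  # 1 s sampling
        v = np.ones(t.size)
        plateaus = {}
        for i, ep in enumerate(protocol.by_label("stim_step")):
            level = 1.0 - 0.08 * (i + 1)
            v[(t >= ep.start) & (t < ep.end)] = level
            plateaus[ep.payload["frequency_hz"]] = level
        trace = make_trace(t, v, protocol)
        levels = ramp_step_levels(trace)
        for f, level in plateaus.items():
            assert levels[f] == pytest.approx(level, rel=1e-12)

    def test_only_tail_samples_contribute(self):
        protocol = ramp_protocol()
        t = np.arange(0.0, protocol.end, 1.0)
        v = np.zeros(t.size)
        # mark only the final 15 s of each step with a sentinel value
        for ep in protocol.by_label("stim_step"):
            v[(t >= ep.end - 15.0) & (t < ep.end)] = 7.0
        trace = make_trace(t, v, protocol)
        assert np.allclose(ramp_step_levels(trace).to_numpy(), 7.0)

    def test_short_step_rejected(self):
        protocol = ProtocolSpec([
            Epoch("baseline", 0.0, 60.0),
            Epoch("stim_step", 60.0, 70.0, {"frequency_hz": 5.0}),
        ])
        t = np.arange(0.0, 70.0, 1.0)
        trace = make_trace(t, np.ones(t.size), protocol)
        with pytest.raises(ValueError):
            ramp_step_levels(trace)


class TestYfpStability:
    def test_constant_yfp(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        s = make_series(t, np.full(t.size, 50.0), np.full(t.size, 50.0),
                        short_protocol)
        _, dev, flagged = yfp_stability(s)
        assert dev == 0.0 and not flagged

    def test_five_percent_step(self, short_protocol):
        t = np.arange(0.0, 2400.0, 10.4)
        yfp = np.full(t.size, 100.0)
        yfp[t >= 1200.0] = 105.0
        s = make_series(t, np.full(t.size, 50.0), np.full(t.size, 50.0),
                        short_protocol, yfp=yfp)
        _, dev, flagged = yfp_stability(s)
        assert dev == pytest.approx(0.05)
        assert not flagged  # below the default 10% QC threshold

    def test_drifting_yfp_is_flagged(self, short_protocol, gd_kinetics):
        series, _ = gen_ratio_timeseries(short_protocol, gd_kinetics,
                                         yfp_drift=0.3)
        _, dev, flagged = yfp_stability(series)
        assert flagged and dev > 0.10
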