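"""Feature extraction: round trips against generators and counting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import optopace as op


class TestRatioTrace:
    t = np.arange(0, 2, 1e-3)

    def test_equal_channels_ratio_one(self):
        f = op.Trace(self.t, np.full(self.t.size, 500.0))
        assert np.allclose(op.ratio_trace(f, f).values, 1.0)

    def test_doubled_numerator(self):
        f380 = op.Trace(self.t, np.full(self.t.size, 400.0))
        f340 = op.Trace(self.t, np.full(self.t.size, 800.0))
        assert np.allclose(op.ratio_trace(f340, f380).values, 2.0)

    def test_interleaved_channels_match_cosampled(self):
        """One-sample excitation offset: interpolation alignment agrees with
        the directly co-sampled ratio on a smooth trace."""
        smooth = 500.0 + 50.0 * np.sin(2 * np.pi * 0.8 * self.t)
        f340 = op.Trace(self.t, 1.3 * smooth)
        f380_co = op.Trace(self.t, smooth)
        offset = self.t + 0.5e-3
        f380_off = op.Trace(offset, 500.0 + 50.0 * np.sin(2 * np.pi * 0.8 * offset))
        direct = op.ratio_trace(f340, f380_co).values
        aligned = op.ratio_trace(f340, f380_off).values
        assert np.abs(aligned[1:-1] / direct[1:-1] - 1).max() < 1e-3

    def test_nonpositive_denominator_rejected(self):
        f340 = op.Trace(self.t, np.full(self.t.size, 500.0))
        bad = np.full(self.t.size, 400.0)
        bad[100] = -1.0
        with pytest.raises(ValueError, match="non-positive"):
            op.ratio_trace(f340, op.Trace(self.t, bad))


class TestDetectAps:
    def test_constant_trace_no_events(self):
        t = np.arange(0, 5, 1e-3)
        assert len(op.detect_aps(op.VoltageTrace(t, np.full(t.size, -42.0)))) == 0

    def test_half_hertz_train_counted(self):
        spec = op.SyntheticTraceSpec(
            duration=20.0, dt=1e-3, event_times=tuple(1.0 + 2.0 * np.arange(10))
        )
        trace, _ = op.make_ap_train(spec)
        assert len(op.detect_aps(trace)) == 10

    def test_unreachable_threshold(self):
        spec = op.SyntheticTraceSpec(duration=5.0, dt=1e-3, event_times=(1.0,))
        trace, truth = op.make_ap_train(spec)
        assert len(op.detect_aps(trace, dVdt_threshold=2 * truth["dVdt_max"])) == 0

    def test_coarse_sampling_rejected(self):
        t = np.arange(0, 5, 5e-3)
        with pytest.raises(ValueError, match="1 kHz"):
            op.detect_aps(op.VoltageTrace(t, np.zeros(t.size)))


class TestApFeatures:
    def test_round_trip_against_generator(self, ap_train_10khz):
        spec, trace, truth = ap_train_10khz
        feats = op.ap_features(trace, op.EventTimes(truth["event_times"], kind="AP"))
        assert feats.apa == pytest.approx(70.0, abs=1e-3)
        assert feats.mdp == pytest.approx(-42.0, abs=1e-3)
        assert feats.apd90 == pytest.approx(300.0, abs=2e3 * spec.dt)
        assert feats.dvdt_max == pytest.approx(truth["dVdt_max"], rel=0.02)
        assert feats.frequency == pytest.approx(0.4, abs=1e-9)

    def test_identical_intervals_zero_freq_sd(self, ap_train_10khz):
        _, trace, truth = ap_train_10khz
        feats = op.ap_features(trace, op.EventTimes(truth["event_times"], kind="AP"))
        assert feats.freq_sd == pytest.approx(0.0, abs=1e-12)
        assert feats.apd_sd == pytest.approx(0.0, abs=0.01)

    def test_truncated_final_ap_excluded_and_flagged(self):
        spec = op.SyntheticTraceSpec(
            duration=2.1, dt=1e-3, event_times=(0.5, 2.0), APD90=300.0
        )
        trace, _ = op.make_ap_train(spec)
        feats = op.ap_features(trace, op.EventTimes((0.5, 2.0), kind="AP"))
        assert feats.apd90.size == 1
        assert any("truncated" in f or "too_short" in f for f in feats.flags)

    def test_light_locking_shrinks_variability(self):
        """Fixed-period light-driven APs cluster both APD90 and the
        instantaneous frequency relative to a jittered spontaneous train."""
        rng = np.random.default_rng(4)
        dt = 1e-3

        def stitched_train(intervals, apd90s):
            vals, times, t0 = [], [], 0.0
            for gap, apd in zip(intervals, apd90s):
                spec = op.SyntheticTraceSpec(
                    duration=gap, dt=dt, event_times=(0.5,), APD90=apd
                )
                seg, _ = op.make_ap_train(spec)
                vals.append(seg.V)
                times.append(t0 + 0.5)
                t0 += gap
            v = np.concatenate(vals)
            return op.VoltageTrace(np.arange(v.size) * dt, v), times

        pre_trace, pre_times = stitched_train(
            3.0 + rng.uniform(-1.0, 1.0, 8), 300.0 + rng.uniform(-60, 60, 8)
        )
        post_trace, post_times = stitched_train(np.full(8, 2.0), np.full(8, 280.0))
        pre = op.ap_features(pre_trace, op.EventTimes(pre_times, kind="AP"))
        post = op.ap_features(post_trace, op.EventTimes(post_times, kind="AP"))
        assert post.apd_sd < pre.apd_sd
        assert post.freq_sd < pre.freq_sd


class TestCatFeatures:
    def test_round_trip_against_generator(self, ca_train):
        spec, trace, truth = ca_train
        feats = op.cat_features(trace, op.EventTimes(truth["event_times"], kind="CaT"))
        assert feats.cad == pytest.approx(1.0, rel=0.02)
        assert np.mean(feats.amplitude) == pytest.approx(0.5, rel=0.02)
        assert np.mean(feats.t_peak) == pytest.approx(0.15, rel=0.02)
        assert np.nanmean(feats.tau_decay) == pytest.approx(0.8, rel=0.02)

    def test_no_events_gives_global_median(self):
        t = np.arange(0, 5, 5e-3)
        trace = op.CaTrace(t, np.full(t.size, 1.07))
        feats = op.cat_features(trace, op.EventTimes([], kind="CaT"))
        assert feats.cad == pytest.approx(1.07)
        assert feats.amplitude.size == 0
        assert feats.frequency == 0.0

    def test_identical_transients_identical_features(self):
        """Split-trace oracle: each half, analysed alone, gives the same
        per-transient numbers as the joint analysis."""
        spec = op.SyntheticTraceSpec(
            duration=12.0, dt=5e-3, event_times=(1.0, 7.0), CaD=1.0
        )
        trace, _ = op.make_ca_trace(spec)
        joint = op.cat_features(trace, op.EventTimes((1.0, 7.0), kind="CaT"))
        for j, (lo, hi, ev) in enumerate([(0.0, 6.0, 1.0), (6.0, 12.0, 7.0)]):
            half = trace.window(lo, hi)
            alone = op.cat_features(
                op.CaTrace(half.t, half.values), op.EventTimes((ev,), kind="CaT")
            )
            # the halves see marginally different diastolic baselines
            assert alone.amplitude[0] == pytest.approx(joint.amplitude[j], rel=1e-3)
            assert alone.t_peak[0] == pytest.approx(joint.t_peak[j], rel=1e-6)
            assert alone.tau_decay[0] == pytest.approx(joint.tau_decay[j], rel=5e-3)
        assert joint.amplitude[0] == pytest.approx(joint.amplitude[1], rel=1e-3)


class TestWindowFrequencies:
    def test_counting(self):
        events = op.EventTimes([1.0, 5.0, 15.0], kind="AP")
        freqs = op.window_frequencies(events, {"pre": (0.0, 20.0)})
        assert freqs["pre"] == pytest.approx(0.15)

    def test_empty_window(self):
        events = op.EventTimes([1.0], kind="AP")
        assert op.window_frequencies(events, {"post": (10.0, 20.0)})["post"] == 0.0

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_frequency_conservation_over_partition(self, seed):
        """Sum of frequency x duration over disjoint covering windows equals
        the total event count (brute-force counting oracle)."""
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0, 90.0, rng.integers(0, 40)))
        times = np.unique(times)
        events = op.EventTimes(times, kind="AP")
        windows = {"pre": (0.0, 30.0), "light": (30.0, 60.0), "post": (60.0, 90.0)}
        freqs = op.window_frequencies(events, windows)
        total = sum(freqs[k] * (b - a) for k, (a, b) in windows.items())
        assert total == pytest.approx(len(times), abs=1e-9)
        for name, (a, b) in windows.items():
            assert freqs[name] * (b - a) == pytest.approx(
                np.count_nonzero((times >= a) & (times < b)), abs=1e-9
            )

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            op.window_frequencies(
                op.EventTimes([], kind="AP"), {"a": (0, 10), "b": (9, 20)}
            )


class TestPercentChange:
    @pytest.mark.parametrize(
        "pre,post,printed",
        [
            (14.2, 17.5, 23),
            (14.2, 22.2, 56),
            (17.5, 15.0, -14),
            (22.2, 19.5, -12),
            (0.22, 0.16, -27),
            (5.0, 5.0, 0),
        ],
    )
    def test_reported_percents(self, pre, post, printed):
        assert op.report_percent(op.percent_change(pre, post)) == printed

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="zero baseline"):
            op.percent_change(0.0, 1.0)

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(0.1, 100.0, allow_nan=False),
        st.floats(0.1, 100.0, allow_nan=False),
    )
    def test_exchange_antisymmetry(self, a, b):
        """pc(a,b) = -100 pc(b,a) / (100 + pc(b,a))."""
        fwd = op.percent_change(a, b)
        rev = op.percent_change(b, a)
        assert fwd == pytest.approx(-100.0 * rev / (100.0 + rev), rel=1e-9)


class TestRespondingFraction:
    protocol = op.LightProtocol.train(1.0, 10, 2.0, 20.0)

    def test_every_pulse_answered(self):
        events = op.EventTimes(np.asarray(self.protocol.onsets) + 0.1, kind="AP")
        assert op.responding_fraction(events, self.protocol) == 100.0

    def test_no_events(self):
        assert op.responding_fraction(op.EventTimes([], kind="AP"), self.protocol) == 0.0

    def test_bernoulli_responder_within_binomial_ci(self):
        """Per-pulse success p = 0.72 over 200 pulses: the measured fraction
        must fall within the binomial 95% interval around 72%."""
        rng = np.random.default_rng(17)
        protocol = op.LightProtocol.train(1.0, 200, 2.0, 20.0)
        hits = rng.random(200) < 0.72
        times = np.asarray(protocol.onsets)[hits] + rng.uniform(0.05, 0.3, hits.sum())
        frac = op.responding_fraction(op.EventTimes(np.sort(times), kind="AP"), protocol)
        half_width = 1.96 * np.sqrt(0.72 * 0.28 / 200) * 100
        assert abs(frac - 72.0) <= half_width

    def test_window_overlapping_next_pulse_rejected(self):
        protocol = op.LightProtocol.train(1.0, 5, 0.2, 20.0)
        with pytest.raises(ValueError, match="overlap"):
            op.responding_fraction(op.EventTimes([], kind="AP"), protocol, 0.35)


class TestLatencyHistogram:
    def test_identical_latencies_degenerate_mode(self):
        protocol = op.LightProtocol.train(0.0, 8, 5.0, 20.0)
        events = op.EventTimes(np.asarray(protocol.onsets) + 0.5, kind="contraction")
        res = op.latency_histogram(events, protocol)
        assert "degenerate" in res.flags
        assert res.mode == pytest.approx(0.5)

    def test_gamma_mode_recovered_from_draws(self):
        """1e4 gamma(k=4, theta=0.167 s) latencies: fitted mode = (k-1) theta
        = 0.5 s within 5 %."""
        rng = np.random.default_rng(3)
        n = 10_000
        protocol = op.LightProtocol.train(0.0, n, 10.0, 20.0)
        lats = rng.gamma(4.0, 0.167, n)
        events = op.EventTimes(np.asarray(protocol.onsets) + lats, kind="contraction")
        res = op.latency_histogram(events, protocol)
        assert res.mode == pytest.approx(3.0 * 0.167, rel=0.05)

    def test_uniform_latencies_fit_converges(self):
        rng = np.random.default_rng(8)
        protocol = op.LightProtocol.train(0.0, 200, 5.0, 20.0)
        events = op.EventTimes(
            np.asarray(protocol.onsets) + rng.uniform(0.1, 1.0, 200), kind="contraction"
        )
        res = op.latency_histogram(events, protocol)
        assert np.isfinite(res.gamma_shape) and res.gamma_shape > 0
        assert np.isfinite(res.log_likelihood)

    def test_too_few_latencies_no_fit(self):
        protocol = op.LightProtocol.train(0.0, 3, 5.0, 20.0)
        events = op.EventTimes(np.asarray(protocol.onsets) + 0.4, kind="contraction")
        res = op.latency_histogram(events, protocol)
        assert "too_few_latencies" in res.flags
        assert np.isnan(res.gamma_shape)


class TestLightLocking:
    def test_perfectly_locked_events(self):
        protocol = op.LightProtocol.train(0.0, 50, 2.0, 20.0)
        events = op.EventTimes(np.asarray(protocol.onsets) + 0.05, kind="AP")
        res = op.light_locking_histogram(events, protocol)
        assert res.concentration_index == 1.0

    def test_uniform_events_index_near_point_one(self):
        rng = np.random.default_rng(12)
        protocol = op.LightProtocol.train(0.0, 1000, 2.0, 20.0)
        events = op.EventTimes(np.sort(rng.uniform(0, 2000.0, 10_000)), kind="AP")
        res = op.light_locking_histogram(events, protocol)
        assert res.concentration_index == pytest.approx(0.10, abs=0.01)

    def test_empty_events(self):
        protocol = op.LightProtocol.train(0.0, 10, 2.0, 20.0)
        res = op.light_locking_histogram(op.EventTimes([], kind="AP"), protocol)
        assert res.counts.sum() == 0
        assert np.isnan(res.concentration_index)

    def test_non_periodic_protocol_rejected(self):
        protocol = op.LightProtocol((0.0, 1.0, 5.0), 20.0)
        with pytest.raises(ValueError, match="periodic"):
            op.light_locking_histogram(op.EventTimes([], kind="AP"), protocol)
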