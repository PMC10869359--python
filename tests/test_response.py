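"""Window extraction, envelope smoothing and the per-pulse metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hivereflex as hr
from hivereflex.response import AccelTrace, envelope, extract_windows


@pytest.fixture()
def flat_trace():
    rng = np.random.default_rng(0)
    return AccelTrace(rng.standard_normal(8000 * 12), 8000.0, 100.0)


class TestExtractWindows:
    def test_pulse_one_second_in_starts_at_sample_zero(self, flat_trace):
        w, = extract_windows(flat_trace, [101.0], pre=1.0, post=4.0)
        assert np.array_equal(w.pre, flat_trace.samples[:8000])
        assert w.pre.size == 8000 and w.post.size == 32000
        assert w.pulse.size == 800

    def test_concatenated_segments_round_trip(self, flat_trace):
        w, = extract_windows(flat_trace, [103.0])
        span = np.concatenate([w.pre, w.pulse, w.post])
        i0 = int(round((103.0 - 1.0 - flat_trace.start_epoch) * 8000))
        assert np.array_equal(span, flat_trace.samples[i0 : i0 + span.size])

    def test_boundary_pulses_skipped(self, flat_trace):
        # brute-force the boundary: pulses every 0.5 s across and beyond the
        # trace; keep exactly those with full pre/post coverage
        times = flat_trace.start_epoch + np.arange(-2.0, 16.0, 0.5)
        fits = [
            t
            for t in times
            if t - 1.0 >= flat_trace.start_epoch
            and t + 0.1 + 4.0 <= flat_trace.end_epoch + 1e-9
        ]
        windows = extract_windows(flat_trace, times)
        assert len(windows) == len(fits)

    def test_empty_schedule_gives_empty_list(self, flat_trace):
        assert extract_windows(flat_trace, []) == []

    def test_bad_window_parameters_rejected(self, flat_trace):
        with pytest.raises(ValueError):
            extract_windows(flat_trace, [101.0], pre=0.0)


class TestEnvelope:
    def test_constant_input_gives_rectified_constant(self):
        out = envelope(np.full(1000, -3.0), 8000.0)
        assert np.allclose(out, 3.0)

    def test_zero_input_gives_zero(self):
        assert not envelope(np.zeros(500), 8000.0).any()

    def test_pure_sine_envelope_is_two_over_pi(self):
        # mean of |A sin| over whole periods is 2A/pi
        fs, f, amp = 8000.0, 200.0, 1.7
        t = np.arange(int(fs)) / fs
        out = envelope(amp * np.sin(2 * np.pi * f * t), fs, window=0.05)
        inner = out[2000:-2000]
        assert np.allclose(inner, 2 * amp / np.pi, rtol=0.01)

    def test_window_shorter_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            envelope(np.ones(100), 100.0, window=0.005)

    def test_output_length_and_nonnegativity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(3000)
        out = envelope(x, 8000.0)
        assert out.size == x.size and np.all(out >= 0)


@settings(max_examples=30, deadline=None)
@given(scale=st.floats(0.0, 50.0), seed=st.integers(0, 2**16))
def test_envelope_homogeneous_in_scale(scale, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(512)
    a = envelope(scale * x, 8000.0)
    b = scale * envelope(x, 8000.0)
    assert np.allclose(a, b, rtol=1e-9, atol=1e-12)


class TestMetrics:
    def test_pulse_magnitude_linear_in_gain_over_silence(self):
        spec = hr.StimulusSpec()
        beep = hr.make_beep(spec)
        mags = []
        for g in (1.0, 2.0, 5.0):
            samples = np.zeros(8000 * 6)
            samples[8000 : 8000 + beep.size] = g * beep
            trace = AccelTrace(samples, 8000.0, 0.0)
            w, = extract_windows(trace, [1.0])
            mags.append(hr.pulse_magnitude(w))
        assert mags[1] / mags[0] == pytest.approx(2.0, rel=1e-9)
        assert mags[2] / mags[0] == pytest.approx(5.0, rel=1e-9)

    def test_pulse_magnitude_zero_on_silence(self, flat_trace):
        w, = extract_windows(AccelTrace(np.zeros(8000 * 6), 8000.0, 0.0), [1.0])
        assert hr.pulse_magnitude(w) == 0.0

    def test_doubled_pulse_gain_doubles_magnitude(self):
        base = hr.ColonySimConfig(immob_depth=0, buzz_amp=0, whoop_rate=0, seed=5)
        mags = {}
        for g in (20.0, 40.0):
            traces, sched, _ = hr.simulate_pulse_extracts(base.replace(pulse_gain=g), 30)
            ws = [extract_windows(t, [e])[0] for t, e in zip(traces, sched.times)]
            mags[g] = np.mean([hr.pulse_magnitude(w) for w in ws])
        assert mags[40.0] / mags[20.0] == pytest.approx(2.0, rel=0.02)

    def test_null_effect_metrics_centred_on_zero(self, null_extracts):
        pos = np.array([hr.positive_response(w) for w in null_extracts])
        neg = np.array([hr.negative_response(w) for w in null_extracts])
        n = len(null_extracts)
        assert abs(pos.mean()) <= 3 * pos.std(ddof=1) / np.sqrt(n)
        assert abs(neg.mean()) <= 3 * neg.std(ddof=1) / np.sqrt(n)

    def test_negative_response_matches_analytic_integral(self):
        # depth 0.5, tau 1 s: windowed mean of the drop over [0, 0.25] s is
        # depth * tau * (1 - exp(-0.25/tau)) / 0.25 times the baseline envelope
        cfg = hr.ColonySimConfig(
            immob_depth=0.5, immob_recovery_tau=1.0, buzz_amp=0.0, whoop_rate=0.0, seed=9
        )
        traces, sched, _ = hr.simulate_pulse_extracts(cfg, 150)
        rel = []
        for t, e in zip(traces, sched.times):
            w, = extract_windows(t, [e])
            pre = envelope(w.pre, 8000.0).mean()
            rel.append(hr.negative_response(w) / pre)
        expected = 0.5 * 1.0 * (1 - np.exp(-0.25)) / 0.25
        assert np.mean(rel) == pytest.approx(expected, rel=0.05)

    def test_positive_response_matches_analytic_buzz_excess(self):
        cfg = hr.ColonySimConfig(immob_depth=0.0, whoop_rate=0.0, seed=5)
        traces, sched, truth = hr.simulate_pulse_extracts(cfg, 200)
        pos = np.array(
            [hr.positive_response(extract_windows(t, [e])[0]) for t, e in zip(traces, sched.times)]
        )
        from hivereflex.simulate import RECTIFIED_MEAN, buzz_templates

        lag = np.arange(32000) / 8000.0
        short, long_ = buzz_templates(lag, cfg)
        amps = np.array([r.buzz_amp for r in truth.records])
        amps_l = np.array([r.buzz_amp_long for r in truth.records])
        expected = RECTIFIED_MEAN * (amps.mean() * short.mean() + amps_l.mean() * long_.mean())
        assert pos.mean() == pytest.approx(expected, rel=0.05)

    def test_doubling_buzz_amp_doubles_positive_response(self):
        means = {}
        for amp in (0.5, 1.0):
            cfg = hr.ColonySimConfig(immob_depth=0.0, whoop_rate=0.0, buzz_amp=amp, seed=5)
            traces, sched, _ = hr.simulate_pulse_extracts(cfg, 200)
            means[amp] = np.mean(
                [hr.positive_response(extract_windows(t, [e])[0]) for t, e in zip(traces, sched.times)]
            )
        assert means[1.0] / means[0.5] == pytest.approx(2.0, rel=0.05)

    def test_compute_metrics_table_shape(self, null_extracts):
        df = hr.compute_metrics(null_extracts[:5])
        assert list(df.columns) == [
            "pulse_epoch", "pulse_magnitude", "positive_response", "negative_response",
        ]
        assert len(df) == 5 and (df["pulse_magnitude"] >= 0).all()
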