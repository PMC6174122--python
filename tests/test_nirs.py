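"""Filtering, segmentation, delta extraction and set-duration normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.interpolate import interp1d
from scipy.signal import butter, freqz

from sprintox.core import ChannelTrace, SprintTimeline
from sprintox.nirs import (
    lowpass_zero_phase,
    normalize_set_duration,
    segment_sprints,
    sprint_deltas,
    sprint_maxima,
    summarize_nirs,
    total_hemoglobin,
)
from sprintox.synthetic import generate_nirs_traces


def sine_trace(freq, amp, duration=600.0, fs=10.0):
    t = np.arange(0.0, duration, 1.0 / fs)
    return t, ChannelTrace(amp * np.sin(2 * np.pi * freq * t), fs=fs)


class TestZeroPhaseFilter:
    def test_deep_passband_amplitude_preserved(self):
        t, tr = sine_trace(0.02, 1.0)
        y = lowpass_zero_phase(tr).values
        mid = slice(1000, -1000)  # avoid edges when measuring amplitude
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.01)

    def test_pedal_artifact_attenuated_over_40db_carrier_intact(self):
        t = np.arange(0.0, 600.0, 0.1)
        carrier = np.sin(2 * np.pi * 0.02 * t)
        artifact = np.sin(2 * np.pi * 1.4 * t)
        y = lowpass_zero_phase(ChannelTrace(carrier + artifact, fs=10.0)).values
        resid = y[1000:-1000] - carrier[1000:-1000]
        # residual power bounds what is left of the artifact
        atten_db = -20 * np.log10(max(np.sqrt(2) * resid.std(), 1e-300))
        assert atten_db > 40.0
        assert np.abs(y[1000:-1000]).max() == pytest.approx(1.0, rel=0.02)

    def test_attenuation_matches_cascaded_analytic_response(self):
        """Forward-backward filtering squares the single-pass magnitude."""
        fs = 10.0
        b, a = butter(4, 0.2, btype="low", fs=fs)
        for freq in (0.05, 0.1, 0.2, 0.5, 1.4):
            w, h = freqz(b, a, worN=[freq], fs=fs)
            expected_gain = np.abs(h[0]) ** 2
            t, tr = sine_trace(freq, 1.0, duration=2000.0)
            y = lowpass_zero_phase(tr).values
            measured = np.sqrt(2) * y[2000:-2000].std()
            assert measured == pytest.approx(expected_gain, rel=0.03, abs=1e-6)

    def test_dc_gain_unity(self):
        tr = ChannelTrace(np.full(500, 3.25), fs=10.0)
        assert np.allclose(lowpass_zero_phase(tr).values, 3.25)

    def test_slow_peak_not_displaced(self):
        t = np.arange(0.0, 300.0, 0.1)
        bump = np.exp(-0.5 * ((t - 150.0) / 15.0) ** 2)
        y = lowpass_zero_phase(ChannelTrace(bump, fs=10.0)).values
        assert abs(int(np.argmax(y)) - int(np.argmax(bump))) <= 1

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            lowpass_zero_phase(ChannelTrace(np.zeros(10), fs=10.0))

    def test_undersampled_trace_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            lowpass_zero_phase(ChannelTrace(np.zeros(100), fs=0.3))


class TestTotalHemoglobin:
    def test_pointwise_sum(self):
        o2 = ChannelTrace(np.array([-3.0, 0.0, 2.0]), fs=10.0, site="m")
        hh = ChannelTrace(np.array([5.0, 0.0, 1.0]), fs=10.0, site="m")
        thb = total_hemoglobin(o2, hh)
        assert np.allclose(thb.values, [2.0, 0.0, 3.0])
        assert thb.channel == "tHb"

    def test_zero_hhb_identity(self):
        o2 = ChannelTrace(np.random.default_rng(0).normal(size=50), fs=10.0)
        hh = ChannelTrace(np.zeros(50), fs=10.0)
        assert np.array_equal(total_hemoglobin(o2, hh).values, o2.values)

    def test_mismatched_channels_rejected(self):
        o2 = ChannelTrace(np.zeros(50), fs=10.0)
        hh = ChannelTrace(np.zeros(40), fs=10.0)
        with pytest.raises(ValueError):
            total_hemoglobin(o2, hh)


class TestSegmentation:
    def test_hint_takes_precedence(self, flat_trace):
        hint = SprintTimeline.regular(3, first_start_s=30.0)
        assert segment_sprints(flat_trace, timeline_hint=hint) is hint

    def test_flat_signal_yields_empty_timeline_with_warning(self, flat_trace):
        with pytest.warns(UserWarning, match="no sprint"):
            tl = segment_sprints(flat_trace)
        assert tl.n_sprints == 0

    def test_detects_clean_synthetic_sprints(self):
        true_tl = SprintTimeline.regular(10, first_start_s=30.0)
        out = generate_nirs_traces(true_tl, delta_schedule=np.linspace(10, 7, 10))
        filtered = lowpass_zero_phase(out.hhb)
        det = segment_sprints(filtered)
        assert det.n_sprints == 10
        assert np.all(np.abs(det.starts - true_tl.starts) <= 0.5)


class TestSprintDeltas:
    def test_monotone_segment(self):
        tl = SprintTimeline(starts=[0.0], ends=[7.0])
        tr = ChannelTrace(np.linspace(2.0, 9.0, 71), fs=10.0)
        assert sprint_deltas(tr, tl)[0] == pytest.approx(7.0)

    def test_constant_segment_zero(self):
        tl = SprintTimeline(starts=[0.0], ends=[5.0])
        tr = ChannelTrace(np.full(60, 4.2), fs=10.0)
        assert sprint_deltas(tr, tl)[0] == 0.0

    def test_empty_timeline_rejected(self):
        tr = ChannelTrace(np.zeros(100), fs=10.0)
        tl = SprintTimeline(starts=np.empty(0), ends=np.empty(0))
        with pytest.raises(ValueError):
            sprint_deltas(tr, tl)

    @given(offset=st.floats(-50, 50), scale=st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_translation_invariant_and_scales_linearly(self, offset, scale):
        rng = np.random.default_rng(7)
        vals = rng.normal(0.0, 3.0, 400)
        tl = SprintTimeline(starts=[5.0, 20.0], ends=[12.0, 30.0])
        base = sprint_deltas(ChannelTrace(vals, fs=10.0), tl)
        shifted = sprint_deltas(ChannelTrace(vals + offset, fs=10.0), tl)
        scaled = sprint_deltas(ChannelTrace(vals * scale, fs=10.0), tl)
        assert np.allclose(shifted, base, atol=1e-9)
        assert np.allclose(scaled, np.abs(scale) * base, rtol=1e-9)

    def test_tsi_per_sprint_maximum(self):
        tl = SprintTimeline(starts=[0.0, 10.0], ends=[5.0, 15.0])
        vals = np.concatenate([np.linspace(70, 60, 50),
                               np.linspace(60, 72, 50),
                               np.full(60, 65.0)])
        tr = ChannelTrace(vals, fs=10.0)
        mx = sprint_maxima(tr, tl)
        assert mx[0] == pytest.approx(70.0)


class TestSetDurationNormalization:
    def test_identity_when_n_is_five(self):
        vals = [10.0, 9.0, 8.0, 7.0, 6.0]
        assert np.allclose(normalize_set_duration(vals), vals)

    def test_even_indexing_when_n_is_ten(self):
        v = np.arange(1.0, 11.0)
        assert np.allclose(normalize_set_duration(v), [v[1], v[3], v[5], v[7], v[9]])

    def test_fractional_interpolation_n_seven(self):
        v = np.array([10.0, 9.5, 8.0, 7.5, 7.0, 6.0, 5.0])
        out = normalize_set_duration(v)
        # f=0.2 -> index 1.4 on the 1-based line
        assert out[0] == pytest.approx(0.6 * v[0] + 0.4 * v[1])
        # independent piecewise-linear evaluator over the same index line
        oracle = interp1d(np.arange(1, 8), v)
        expected = oracle(np.array([0.2, 0.4, 0.6, 0.8, 1.0]) * 7)
        assert np.allclose(out, expected, atol=1e-12)

    def test_final_fraction_is_last_sprint_exactly(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=13)
        assert normalize_set_duration(v)[-1] == v[-1]

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            normalize_set_duration([])


class TestSummarizeNirs:
    def test_noise_free_pipeline_recovers_schedule(self):
        tl = SprintTimeline.regular(8, first_start_s=30.0)
        sched = np.linspace(12.0, 8.0, 8)
        out = generate_nirs_traces(tl, delta_schedule=sched)
        summary = summarize_nirs(out.o2hb, out.hhb, out.tsi,
                                 detect_from_signal=True)
        assert summary.deltas["HHb"].size == 8
        assert np.all(np.abs(summary.deltas["HHb"] - sched) <= 0.5)
        assert len(summary.normalized["delta_HHb"]) == 5
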