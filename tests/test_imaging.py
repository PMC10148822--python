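"""Unit and property tests for dF/F0 normalization and responder calling."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drgquant.imaging import (
    DffTrace,
    ImagingSession,
    analyze_session,
    area_histogram,
    call_response,
    compute_dff,
    estimate_total_neurons,
    expected_false_positive_rate,
    extract_traces,
    peak_auc,
    percent_responders,
    summarize_session,
)


# ---------------------------------------------------------------- compute_dff

class TestComputeDff:
    def test_constant_trace_gives_zero_dff_and_sd(self):
        d = compute_dff(np.full(90, 100.0), range(30))
        assert d.f0 == 100.0
        assert np.allclose(d.dff, 0.0)
        assert d.baseline_sd == 0.0

    def test_single_frame_value(self):
        trace = np.full(60, 100.0)
        trace[45] = 150.0
        d = compute_dff(trace, range(30))
        assert d.dff[45] == pytest.approx(0.5)

    def test_alternating_baseline_sd_matches_hand_computation(self):
        # baseline alternates 90/110 (mean 100) -> dff alternates -0.1/+0.1;
        # oracle: sample SD of that +-0.1 sequence via the statistics module
        trace = np.tile([90.0, 110.0], 30)
        d = compute_dff(trace, range(30))
        oracle = statistics.stdev([-0.1, 0.1] * 15)
        assert d.baseline_sd == pytest.approx(oracle, rel=1e-12)

    def test_population_sd_convention(self):
        trace = np.tile([90.0, 110.0], 30)
        d = compute_dff(trace, range(30), ddof=0)
        assert d.baseline_sd == pytest.approx(0.1, rel=1e-12)

    def test_rejects_bad_baseline(self):
        with pytest.raises(ValueError):
            compute_dff(np.ones(10), [])
        with pytest.raises(ValueError):
            compute_dff(np.ones(10), range(20))
        with pytest.raises(ValueError):
            compute_dff(np.zeros(10), range(5))

    @settings(deadline=None, max_examples=50)
    @given(
        gain=st.floats(min_value=0.1, max_value=100.0),
        seed=st.integers(0, 2**16),
    )
    def test_gain_invariance_offset_sensitivity(self, gain, seed):
        """Multiplicative gain leaves dF/F0 unchanged; an additive offset
        does not (it dilutes the relative change)."""
        rng = np.random.default_rng(seed)
        trace = rng.uniform(50.0, 150.0, size=60)
        d0 = compute_dff(trace, range(30))
        d_gain = compute_dff(gain * trace, range(30))
        np.testing.assert_allclose(d_gain.dff, d0.dff, atol=1e-9)
        d_off = compute_dff(trace + 50.0, range(30))
        assert not np.allclose(d_off.dff, d0.dff, atol=1e-6)


# -------------------------------------------------------------- call_response

class TestCallResponse:
    def _dff(self, values, sd):
        return DffTrace(neuron_id=0, f0=100.0, dff=np.asarray(values), baseline_sd=sd)

    def test_responder_above_threshold(self):
        d = self._dff([0.0] * 9 + [0.21], 0.05)
        assert call_response(d, range(10)).responder

    def test_boundary_is_not_a_responder(self):
        # peak exactly 4 x SD: the rule is strictly "greater than"
        d = self._dff([0.0] * 9 + [0.20], 0.05)
        call = call_response(d, range(10))
        assert not call.responder
        assert call.threshold == pytest.approx(0.20)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            call_response(self._dff([0.1], 0.0), [])

    def test_noise_specificity_small_scale(self):
        """False-positive rate of the 4-sigma rule on pure noise approaches
        1 - Phi(4)^10 when the true sigma is supplied (quick check at 1e5
        windows; the full-scale check lives in the acceptance suite)."""
        from drgquant.imaging import noise_false_positive_rate

        n = 100_000
        p = expected_false_positive_rate(4.0, 10)
        rate = noise_false_positive_rate(n, window_len=10, sigma=0.03, seed=5)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(rate - p) <= 4 * se


# ------------------------------------------------------------------ peak_auc

class TestPeakAuc:
    def _dff(self, values):
        return DffTrace(neuron_id=0, f0=1.0, dff=np.asarray(values, float),
                        baseline_sd=0.0)

    def test_zero_trace_gives_zero(self):
        assert peak_auc(self._dff(np.zeros(30)), range(10, 20), 0.7) == 0.0

    def test_constant_run_matches_hand_trapezoid(self):
        # 0.5 dF/F0 on 7 consecutive frames at 0.7 Hz:
        # trapezoid = 0.5 * 6 intervals * (1/0.7) s = 3/0.7
        y = np.zeros(30)
        y[12:19] = 0.5
        got = peak_auc(self._dff(y), range(10, 20), 0.7)
        assert got == pytest.approx(3.0 / 0.7, rel=1e-12)

    def test_run_extends_into_post_frames(self):
        y = np.zeros(30)
        y[15:25] = 1.0  # run continues past the window end at frame 20
        got = peak_auc(self._dff(y), range(10, 20), 0.7)
        assert got == pytest.approx(9.0 / 0.7, rel=1e-12)

    def test_run_bounds_clip_the_expansion(self):
        y = np.ones(30)
        got = peak_auc(self._dff(y), range(10, 20), 1.0, run_bounds=(10, 20))
        assert got == pytest.approx(9.0, rel=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        scale=st.floats(min_value=0.1, max_value=10.0),
        seed=st.integers(0, 2**16),
    )
    def test_linearity_in_dff(self, scale, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(0.2, 0.5, size=40)
        base = peak_auc(self._dff(y), range(15, 25), 0.7)
        scaled = peak_auc(self._dff(scale * y), range(15, 25), 0.7)
        assert scaled == pytest.approx(scale * base, rel=1e-9, abs=1e-12)


# ------------------------------------------------- extrapolation and percents

class TestSessionArithmetic:
    def test_extrapolation_examples(self):
        assert estimate_total_neurons(30, 10.0, 100.0) == 300
        assert estimate_total_neurons(42, 50.0, 50.0) == 42

    def test_extrapolation_field_scale(self):
        # 25 neurons counted in 96,000 um^2 of the full 981.36^2 um^2 field;
        # independent arithmetic oracle with half-away-from-zero rounding
        imaged = 981.36**2
        x = 25 * imaged / 96_000.0
        oracle = math.floor(x + 0.5)
        assert estimate_total_neurons(25, 96_000.0, imaged) == oracle == 251

    def test_extrapolation_rejects_bad_areas(self):
        with pytest.raises(ValueError):
            estimate_total_neurons(1, 0.0, 10.0)
        with pytest.raises(ValueError):
            estimate_total_neurons(1, 20.0, 10.0)

    @pytest.mark.parametrize(
        "n,total,expected", [(18, 300, 6.0), (0, 50, 0.0), (300, 300, 100.0)]
    )
    def test_percent_responders(self, n, total, expected):
        assert percent_responders(n, total) == pytest.approx(expected)

    def test_percent_responders_rejects_zero_total(self):
        with pytest.raises(ValueError):
            percent_responders(0, 0)


class TestAreaHistogram:
    def test_single_bin(self):
        h = area_histogram([150.0, 160.0, 170.0], np.array([100.0, 200.0, 300.0]))
        assert h["frequency"].tolist() == [1.0, 0.0]

    def test_split_bins(self):
        h = area_histogram([100.0, 300.0], np.array([0.0, 200.0, 400.0]))
        assert h["frequency"].tolist() == [0.5, 0.5]

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(7)
        areas = np.exp(rng.normal(6.0, 0.5, size=1000))
        edges = np.arange(0.0, 2100.0, 100.0)
        h = area_histogram(areas, edges)
        # brute-force per-bin counting, out-of-range folded into end bins
        oracle = [0] * (len(edges) - 1)
        for a in areas:
            a = min(max(a, edges[0]), edges[-1] - 1e-9)
            for i in range(len(edges) - 1):
                hi_edge = edges[i + 1]
                if edges[i] <= a < hi_edge or (i == len(edges) - 2 and a >= hi_edge):
                    oracle[i] += 1
                    break
        assert h["count"].tolist() == oracle
        assert h["frequency"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_is_flagged_by_zero_frequencies(self):
        h = area_histogram([], np.array([0.0, 100.0]))
        assert h["frequency"].sum() == 0.0


# --------------------------------------------------------- session level flow

class TestSessionAnalysis:
    def test_extract_traces_uniform_frame(self):
        stack = np.full((4, 8, 8), 7.0)
        rois = np.zeros((8, 8), dtype=int)
        rois[2:4, 2:4] = 1
        traces, labels, areas = extract_traces(stack, rois, pixel_size_um=1.92)
        assert np.allclose(traces, 7.0)
        assert labels.tolist() == [1]
        assert areas[0] == pytest.approx(4 * 1.92**2)

    def test_extract_traces_area_rule(self):
        rois = np.zeros((20, 20), dtype=int)
        rois.ravel()[:100] = 1
        _, _, areas = extract_traces(np.ones((1, 20, 20)), rois, 1.92)
        assert areas[0] == pytest.approx(368.64)

    def test_extract_traces_shape_mismatch(self):
        with pytest.raises(ValueError):
            extract_traces(np.ones((2, 4, 4)), np.zeros((5, 5), dtype=int))

    def test_analysis_is_deterministic(self, noiseless_session):
        session, _ = noiseless_session
        a = analyze_session(session)
        b = analyze_session(session)
        pd.testing.assert_frame_equal(a, b)

    def test_summary_no_responders_reports_missing_auc(self, protocol):
        session = ImagingSession(
            protocol=protocol,
            traces=np.full((3, protocol.n_frames), 50.0),
            neuron_ids=np.arange(3),
            areas_um2=np.full(3, 400.0),
        )
        summary = summarize_session(analyze_session(session))
        assert (summary.per_stimulus["n_responders"] == 0).all()
        assert summary.per_stimulus["mean_peak_auc"].isna().all()

    def test_summary_single_responder_auc(self, protocol):
        traces = np.full((2, protocol.n_frames), 100.0)
        win = protocol.application_frames("30g")
        traces[0, list(win)] = 150.0  # sustained 0.5 dF/F0 response
        session = ImagingSession(
            protocol=protocol, traces=traces, neuron_ids=np.arange(2),
            areas_um2=np.array([300.0, 400.0]),
        )
        calls = analyze_session(session)
        summary = summarize_session(calls, total_neurons=300)
        row = summary.per_stimulus.set_index("stimulus").loc["30g"]
        assert row["n_responders"] == 1
        assert row["percent_responders"] == pytest.approx(100 / 300)
        only_call = calls[(calls.stimulus == "30g") & calls.responder].iloc[0]
        assert row["mean_peak_auc"] == pytest.approx(only_call.peak_auc)
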