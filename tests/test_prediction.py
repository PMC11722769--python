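"""Monotonic-rise prediction rule and the threshold sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fogkit import (
    EventInterval,
    PredictionConfig,
    ProbabilityTrace,
    combine_feet,
    detect_events,
    evaluate_predictions,
    extract_pre_onset_window,
    find_monotone_crossings,
    generate_cohort,
    threshold_sweep,
)
from conftest import make_trace_config


def trace(values, fs=10.0, start=0.0):
    return ProbabilityTrace(np.asarray(values, float), fs, start_time=start)


def oracle_crossings(values, fs, threshold, min_run_s, refractory_s):
    """Exhaustive scan over all candidate run starts (O(n^2))."""
    out, last = [], -np.inf
    for i in range(len(values)):
        if values[i] > threshold and i > 0 and values[i - 1] <= threshold:
            starts = [
                j
                for j in range(i + 1)
                if all(values[k] <= values[k + 1] for k in range(j, i))
            ]
            run = (i - min(starts)) / fs
            t = i / fs
            if run >= min_run_s and t - last >= refractory_s:
                out.append(t)
                last = t
    return out


class TestPreOnsetWindow:
    def test_full_window_sample_count(self):
        tr = trace(np.linspace(0, 0.5, 60))
        win = extract_pre_onset_window(tr, onset=3.0, window_s=3.0)
        assert len(win) == 30
        assert win.start_time == pytest.approx(0.0)

    def test_truncated_at_trace_start(self):
        tr = trace(np.linspace(0, 0.5, 60))
        win = extract_pre_onset_window(tr, onset=1.0, window_s=3.0)
        assert len(win) == 10

    def test_constant_trace_gives_constant_window(self):
        win = extract_pre_onset_window(trace([0.3] * 50), onset=4.0)
        assert np.all(win.values == 0.3)

    def test_onset_before_start_rejected(self):
        with pytest.raises(ValueError):
            extract_pre_onset_window(trace([0.1] * 10, start=5.0), onset=4.0)


class TestMonotoneCrossings:
    CFG = PredictionConfig(min_run_s=0.2, refractory_s=0.0)

    def test_single_ramp_single_crossing(self):
        v = np.linspace(0.1, 0.9, 21)  # 2 s rise at 10 Hz
        got = find_monotone_crossings(trace(v), 0.35, self.CFG)
        assert len(got) == 1
        assert got[0].time == pytest.approx(np.flatnonzero(v > 0.35)[0] / 10.0)

    def test_constant_above_threshold_never_crosses(self):
        assert find_monotone_crossings(trace([0.5] * 40), 0.35, self.CFG) == []

    def test_two_rises_two_crossings(self):
        v = [0.1, 0.2, 0.4, 0.3, 0.2, 0.3, 0.4]
        got = find_monotone_crossings(trace(v), 0.35, self.CFG)
        assert [c.time for c in got] == pytest.approx([0.2, 0.6])
        assert [c.run_length_s for c in got] == pytest.approx([0.2, 0.2])

    def test_short_run_disqualified(self):
        # dip right before the crossing: run of one sample < min_run
        v = [0.3, 0.2, 0.4, 0.5]
        assert find_monotone_crossings(trace(v), 0.35, self.CFG) == []

    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(
        values=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=60
        ),
        threshold=st.sampled_from([0.2, 0.35, 0.5]),
        min_run=st.sampled_from([0.0, 0.2, 0.5]),
        refractory=st.sampled_from([0.0, 1.0]),
    )
    def test_matches_exhaustive_oracle(self, values, threshold, min_run, refractory):
        cfg = PredictionConfig(min_run_s=min_run, refractory_s=refractory)
        got = find_monotone_crossings(trace(values), threshold, cfg)
        assert [c.time for c in got] == pytest.approx(
            oracle_crossings(values, 10.0, threshold, min_run, refractory)
        )


def linear_ramp_trace(t_start=5.0, fs=100.0, total=30.0):
    """Baseline 0.05, linear rise to 0.95 over 3 s, 3 s hold, fall."""
    t = np.arange(int(total * fs)) / fs
    v = np.full(t.size, 0.05)
    rise = (t >= t_start) & (t < t_start + 3.0)
    v[rise] = 0.05 + 0.3 * (t[rise] - t_start)
    hold = (t >= t_start + 3.0) & (t < t_start + 6.0)
    v[hold] = 0.95
    fall = (t >= t_start + 6.0) & (t < t_start + 7.0)
    v[fall] = 0.95 - 0.9 * (t[fall] - t_start - 6.0)
    return trace(v, fs=fs)


class TestEvaluatePredictions:
    def test_lead_time_decides_prediction(self):
        """Closed form: slope 0.3/s, onset at ramp+2.167 s; the 0.2 crossing
        leads by 1.67 s (predicted), the 0.5 crossing by 0.67 s (not)."""
        tr = linear_ramp_trace()
        events = detect_events(tr)
        assert len(events) == 1
        cfg = PredictionConfig()
        low = evaluate_predictions(tr, events, 0.2, cfg)
        high = evaluate_predictions(tr, events, 0.5, cfg)
        assert (low.n_events, low.n_predicted) == (1, 1)
        assert low.true_rate == 1.0 and low.false_rate == 0.0
        assert (high.n_events, high.n_predicted) == (1, 0)
        assert high.true_rate == 0.0

    def test_false_rise_counts_as_false_alarm(self):
        t = np.arange(300) / 10.0
        v = np.full(t.size, 0.05)
        rise = (t >= 5.0) & (t < 8.0)
        v[rise] = 0.05 + (0.6 - 0.05) / 3.0 * (t[rise] - 5.0)
        v[(t >= 8.0) & (t < 9.0)] = 0.6
        tr = trace(v, fs=10.0)
        counts = evaluate_predictions(tr, [], 0.35, PredictionConfig())
        assert counts.n_events == 0
        assert counts.n_crossings == 1 and counts.n_false_crossings == 1
        assert counts.false_rate == 1.0 and counts.true_rate is None

    def test_empty_denominators_reported_absent(self):
        tr = trace([0.05] * 100)
        counts = evaluate_predictions(
            tr, [EventInterval(3.0, 5.0), EventInterval(7.0, 8.0), EventInterval(9.0, 9.5)],
            0.2, PredictionConfig(),
        )
        assert counts.n_crossings == 0
        assert counts.true_rate == 0.0 and counts.false_rate is None

    def test_overlapping_events_rejected(self):
        tr = trace([0.05] * 100)
        with pytest.raises(ValueError, match="overlap"):
            evaluate_predictions(
                tr, [EventInterval(1.0, 4.0), EventInterval(3.0, 5.0)], 0.2, PredictionConfig()
            )

    def test_in_event_crossings_discarded(self):
        # a rise inside an ongoing event is not a prediction or a false alarm
        tr = linear_ramp_trace()
        events = detect_events(tr)
        counts = evaluate_predictions(tr, events, 0.2, PredictionConfig(lead_min_s=0.0))
        assert counts.n_crossings == 1  # only the pre-onset crossing


class TestThresholdSweep:
    def build_cohort(self, n=4, seed=33):
        cfg = make_trace_config(
            seed=seed, freeze_counts={"GOT": 1, "Hallway": 1, "Community": 1}
        )
        cohort = generate_cohort(cfg, n, seed=seed)
        return [
            (session, detect_events(combine_feet(session.left, session.right)))
            for session, _truth in cohort
        ]

    def test_true_rate_nonincreasing_down_the_table(self):
        sweep = threshold_sweep(self.build_cohort())
        rates = sweep["true_rate_mean"].to_numpy()
        assert np.all(np.diff(rates) <= 1e-12)
        assert rates[0] == 1.0  # every ramp starts below 0.2

    def test_all_predicted_gives_mean_one_sd_zero(self):
        sweep = threshold_sweep(self.build_cohort(n=1), PredictionConfig(lead_min_s=0.0))
        assert np.all(sweep["true_rate_mean"].to_numpy() == 1.0)
        assert np.all(sweep["true_rate_sd"].to_numpy() == 0.0)

    def test_false_rise_only_cohort(self):
        cfg = make_trace_config(
            seed=91, freezes_per_task=0.0, false_rise_rate=2.0, false_rise_peak=0.65
        )
        cohort = generate_cohort(cfg, 3, seed=91)
        pairs = [
            (s, detect_events(combine_feet(s.left, s.right))) for s, _t in cohort
        ]
        sweep = threshold_sweep(pairs)
        assert np.all(sweep["false_rate_mean"].to_numpy() == 1.0)
        assert np.all(np.isnan(sweep["true_rate_mean"].to_numpy()))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([])
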