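"""Event extraction and time-based confusion scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fogkit import (
    AnnotationSet,
    EventInterval,
    ProbabilityTrace,
    classify_time,
    combine_feet,
    detect_events,
)


def trace(values, fs=10.0, foot="combined", start=0.0):
    return ProbabilityTrace(np.asarray(values, float), fs, start_time=start, foot=foot)


def oracle_detect(values, fs, threshold, merge_gap):
    """Naive mark-scan-merge: O(n*m), merging repeatedly to a fixed point."""
    n = len(values)
    runs = []
    i = 0
    while i < n:
        if values[i] > threshold:
            j = i
            while j < n and values[j] > threshold:
                j += 1
            runs.append([i / fs, j / fs])
            i = j
        else:
            i += 1
    changed = True
    while changed:
        changed = False
        for k in range(len(runs) - 1):
            if runs[k + 1][0] - runs[k][1] < merge_gap:
                runs[k][1] = max(runs[k][1], runs[k + 1][1])
                del runs[k + 1]
                changed = True
                break
    return [tuple(r) for r in runs]


class TestCombineFeet:
    def test_elementwise_max(self):
        left = trace([0.1, 0.8, 0.2], foot="left")
        right = trace([0.9, 0.1, 0.2], foot="right")
        out = combine_feet(left, right)
        assert out.foot == "combined"
        np.testing.assert_allclose(out.values, [0.9, 0.8, 0.2])

    def test_idempotent_on_equal_inputs(self):
        left = trace([0.2, 0.5, 0.7], foot="left")
        right = trace([0.2, 0.5, 0.7], foot="right")
        np.testing.assert_array_equal(combine_feet(left, right).values, left.values)

    def test_one_silent_foot(self):
        left = trace([0.0] * 5, foot="left")
        right = trace([0.8] * 5, foot="right")
        np.testing.assert_allclose(combine_feet(left, right).values, 0.8)

    def test_mismatched_geometry_rejected(self):
        with pytest.raises(ValueError):
            combine_feet(trace([0.1, 0.2], foot="left"), trace([0.1], foot="right"))


class TestDetectEvents:
    def test_all_subthreshold_is_empty(self):
        assert detect_events(trace([0.7, 0.1, 0.69, 0.0])) == []

    def test_exactly_at_threshold_is_not_freezing(self):
        # "above 0.7" is strict: a sample equal to the threshold is non-freeze
        assert detect_events(trace([0.7] * 10)) == []

    def test_nearby_runs_merge(self):
        v = np.zeros(60)
        v[10:15] = 0.9  # [1.0, 1.5)
        v[20:25] = 0.9  # [2.0, 2.5), gap 0.5 s < 2 s
        events = detect_events(trace(v), 0.7, 2.0)
        assert [(e.start, e.end) for e in events] == [(1.0, 2.5)]

    def test_distant_runs_stay_separate(self):
        v = np.zeros(60)
        v[10:15] = 0.9  # [1.0, 1.5)
        v[40:45] = 0.9  # [4.0, 4.5), gap 2.5 s >= 2 s
        events = detect_events(trace(v), 0.7, 2.0)
        assert [(e.start, e.end) for e in events] == [(1.0, 1.5), (4.0, 4.5)]

    def test_transitive_merging(self):
        # chain of short runs, each gap < 2 s: all collapse into one episode
        v = np.zeros(100)
        for k in range(0, 100, 20):
            v[k : k + 5] = 0.95
        events = detect_events(trace(v), 0.7, 2.0)
        assert len(events) == 1
        assert events[0].start == 0.0 and events[0].end == 8.5

    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(
        values=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=80
        ),
        threshold=st.sampled_from([0.3, 0.5, 0.7]),
        merge_gap=st.floats(min_value=0.0, max_value=3.0),
        fs=st.sampled_from([5.0, 10.0, 32.0]),
    )
    def test_matches_bruteforce_oracle(self, values, threshold, merge_gap, fs):
        got = detect_events(trace(values, fs=fs), threshold, merge_gap)
        expected = oracle_detect(values, fs, threshold, merge_gap)
        assert [(e.start, e.end) for e in got] == pytest.approx(expected)
        # raising the threshold never increases pre-merge supra-threshold time
        v = np.asarray(values)
        assert np.count_nonzero(v > threshold + 0.1) <= np.count_nonzero(v > threshold)


class TestClassifyTime:
    def test_perfect_agreement(self):
        ivs = [EventInterval(1.0, 3.0), EventInterval(5.0, 6.0)]
        truth = AnnotationSet(tuple(EventInterval(i.start, i.end, source="video") for i in ivs))
        conf = classify_time(ivs, truth, np.ones(100, bool), 10.0)
        assert conf.fp_s == 0 and conf.fn_s == 0
        assert conf.tp_s == pytest.approx(3.0)
        assert conf.analyzed_s == pytest.approx(10.0)

    def test_missed_truth_is_fn(self):
        truth = AnnotationSet((EventInterval(10.0, 16.0, source="video"),))
        conf = classify_time([], truth, np.ones(600, bool), 10.0)
        assert conf.fn_s == pytest.approx(6.0)
        assert conf.tn_s == pytest.approx(54.0)

    def test_partial_overlap_counts(self):
        # algo [2,5), truth [4,8) on an all-active 10 s session at 10 Hz
        conf = classify_time(
            [EventInterval(2.0, 5.0)],
            AnnotationSet((EventInterval(4.0, 8.0, source="video"),)),
            np.ones(100, bool),
            10.0,
        )
        assert (conf.tp_s, conf.fp_s, conf.fn_s, conf.tn_s) == pytest.approx((1, 2, 3, 4))

    def test_interval_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            classify_time([EventInterval(5.0, 12.0)], AnnotationSet(()), np.ones(100, bool), 10.0)

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_conservation_and_swap_symmetry(self, data):
        fs = data.draw(st.sampled_from([8.0, 10.0, 25.0]))
        n = data.draw(st.integers(min_value=40, max_value=300))
        dur = n / fs

        def draw_intervals():
            k = data.draw(st.integers(min_value=0, max_value=3))
            points = sorted(
                data.draw(
                    st.lists(
                        st.floats(min_value=0.0, max_value=dur),
                        min_size=2 * k,
                        max_size=2 * k,
                        unique=True,
                    )
                )
            )
            return [
                EventInterval(points[2 * i], points[2 * i + 1], source="video")
                for i in range(k)
                if points[2 * i] < points[2 * i + 1]
            ]

        algo = draw_intervals()
        truth = draw_intervals()
        mask = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
        conf = classify_time(algo, truth, mask, fs)
        total = conf.tp_s + conf.fp_s + conf.tn_s + conf.fn_s
        assert total == pytest.approx(conf.analyzed_s)
        assert conf.analyzed_s == pytest.approx(np.count_nonzero(mask) / fs)
        swapped = classify_time(truth, algo, mask, fs)
        assert swapped.fp_s == pytest.approx(conf.fn_s)
        assert swapped.fn_s == pytest.approx(conf.fp_s)
        assert swapped.tp_s == pytest.approx(conf.tp_s)
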