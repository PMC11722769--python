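"""Freeze-event extraction and time-based scoring.

An FOG event is any maximal run of samples whose combined (either-foot)
probability is strictly above a threshold (0.7 by convention); events
separated by strictly less than a merge gap (2 s) are merged into one
episode. Scoring against video-style ground truth is done sample-wise
over active time only, yielding true/false positive/negative *durations*
rather than event counts.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .core import (
    AnnotationSet,
    ConfusionTimes,
    EventInterval,
    ProbabilityTrace,
    intervals_to_mask,
)

__all__ = ["combine_feet", "detect_events", "merge_intervals", "classify_time"]


def combine_feet(left: ProbabilityTrace, right: ProbabilityTrace) -> ProbabilityTrace:
    """Pointwise either-foot maximum of the two per-foot traces."""
    if (
        len(left) != len(right)
        or left.sampling_rate != right.sampling_rate
        or left.start_time != right.start_time
    ):
        raise ValueError("left and right traces must share length, rate and start")
    return ProbabilityTrace(
        values=np.maximum(left.values, right.values),
        sampling_rate=left.sampling_rate,
        start_time=left.start_time,
        foot="combined",
    )


def merge_intervals(
    intervals: Sequence[EventInterval], merge_gap: float
) -> list[EventInterval]:
    """Merge sorted disjoint intervals whose gap is strictly below ``merge_gap``.

    Applied transitively left-to-right; the result's inter-event gaps are
    all >= merge_gap.
    """
    if merge_gap < 0:
        raise ValueError("merge_gap must be non-negative")
    merged: list[EventInterval] = []
    for iv in sorted(intervals, key=lambda i: i.start):
        if merged and iv.start - merged[-1].end < merge_gap:
            prev = merged.pop()
            merged.append(
                EventInterval(prev.start, max(prev.end, iv.end), source=prev.source)
            )
        else:
            merged.append(iv)
    return merged


def detect_events(
    trace: ProbabilityTrace,
    threshold: float = 0.7,
    merge_gap: float = 2.0,
) -> list[EventInterval]:
    """Extract FOG events from a probability trace.

    Maximal runs of samples strictly above ``threshold`` become half-open
    intervals on the sample grid; runs separated by strictly less than
    ``merge_gap`` seconds are merged into single episodes.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    v = trace.values
    above = v > threshold
    if not above.any():
        return []
    # run boundaries: starts where above turns on, ends where it turns off
    padded = np.concatenate(([False], above, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)  # exclusive sample index
    fs = trace.sampling_rate
    t0 = trace.start_time
    raw = [
        EventInterval(t0 + s / fs, t0 + e / fs, source="algorithm")
        for s, e in zip(starts, ends)
    ]
    return merge_intervals(raw, merge_gap)


def classify_time(
    algo: Iterable[EventInterval],
    truth: AnnotationSet | Iterable[EventInterval],
    active_mask: np.ndarray,
    sampling_rate: float,
    start_time: float = 0.0,
) -> ConfusionTimes:
    """Sample-wise time-based confusion over active samples only.

    TP where both the algorithm events and the ground truth cover an
    active sample, TN where neither does, FP algorithm-only, FN
    truth-only. Durations are sample counts divided by the sampling rate;
    ``analyzed_s`` is the active time. Sedentary (inactive) samples are
    excluded entirely.
    """
    mask = np.asarray(active_mask, dtype=bool)
    n = mask.size
    if n == 0:
        raise ValueError("active_mask must be non-empty")
    span_start = start_time
    span_end = start_time + n / sampling_rate
    algo = list(algo)
    truth_ivs = list(truth)
    eps = 0.5 / sampling_rate
    for iv in algo + truth_ivs:
        if iv.start < span_start - eps or iv.end > span_end + eps:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) lies outside the session span "
                f"[{span_start}, {span_end})"
            )
    algo_mask = intervals_to_mask(algo, n, sampling_rate, start_time)
    truth_mask = intervals_to_mask(truth_ivs, n, sampling_rate, start_time)
    tp = int(np.count_nonzero(mask & algo_mask & truth_mask))
    fp = int(np.count_nonzero(mask & algo_mask & ~truth_mask))
    fn = int(np.count_nonzero(mask & ~algo_mask & truth_mask))
    tn = int(np.count_nonzero(mask & ~algo_mask & ~truth_mask))
    return ConfusionTimes(
        tp_s=tp / sampling_rate,
        fp_s=fp / sampling_rate,
        tn_s=tn / sampling_rate,
        fn_s=fn / sampling_rate,
        analyzed_s=(tp + fp + fn + tn) / sampling_rate,
    )
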