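"""Pre-onset prediction of freeze events from the probability trace.

A freeze is "predicted" when the probability rises monotonically above a
sub-event threshold (0.2-0.5, below the 0.7 event threshold) within the
three seconds before the event's detected onset, with a minimum lead
time. The sweep evaluates seven thresholds and reports, per participant,
the true prediction rate (fraction of detected events preceded by a
qualifying rise) and the false positive prediction rate (fraction of
qualifying rises not followed by any event).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import EventInterval, ProbabilityTrace, SessionRecording
from .events import combine_feet

__all__ = [
    "PredictionConfig",
    "PredictionCrossing",
    "PredictionCounts",
    "extract_pre_onset_window",
    "find_monotone_crossings",
    "evaluate_predictions",
    "threshold_sweep",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5)


@dataclass(frozen=True)
class PredictionConfig:
    """Tunable parameters of the prediction rule.

    ``window_s`` is how far before an event onset a rise may occur and
    still count; ``lead_min_s`` is the minimum warning time (a crossing
    must fall in [onset - window_s, onset - lead_min_s]). ``min_run_s``
    quantifies "rose monotonically": the non-decreasing run ending at the
    crossing must last at least this long. A crossing is a false alarm if
    no event onset follows within ``fp_horizon_s``. ``refractory_s`` is
    the minimum spacing between counted crossings of one threshold.
    """

    thresholds: tuple = DEFAULT_THRESHOLDS
    window_s: float = 3.0
    lead_min_s: float = 1.0
    min_run_s: float = 0.25
    fp_horizon_s: float = 3.0
    refractory_s: float = 1.0

    def __post_init__(self):
        thr = tuple(float(t) for t in self.thresholds)
        if len(thr) == 0:
            raise ValueError("thresholds must be non-empty")
        if any(not 0.0 < t < 0.7 for t in thr):
            raise ValueError("prediction thresholds must lie in (0, 0.7)")
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if not 0.0 <= self.lead_min_s < self.window_s:
            raise ValueError("need 0 <= lead_min_s < window_s")
        if self.min_run_s < 0:
            raise ValueError("min_run_s must be non-negative")
        if self.fp_horizon_s <= 0 or self.refractory_s < 0:
            raise ValueError("fp_horizon_s must be positive and refractory_s non-negative")
        object.__setattr__(self, "thresholds", thr)


@dataclass(frozen=True)
class PredictionCrossing:
    """First sample strictly above a threshold at the end of a monotone rise."""

    time: float
    threshold: float
    run_length_s: float


@dataclass(frozen=True)
class PredictionCounts:
    """Per-session prediction tallies at one threshold."""

    threshold: float
    n_events: int
    n_predicted: int
    n_crossings: int
    n_false_crossings: int

    def __post_init__(self):
        if not 0 <= self.n_predicted <= self.n_events:
            raise ValueError("need 0 <= n_predicted <= n_events")
        if not 0 <= self.n_false_crossings <= self.n_crossings:
            raise ValueError("need 0 <= n_false_crossings <= n_crossings")

    @property
    def true_rate(self) -> float | None:
        """Fraction of events predicted; None when there are no events."""
        if self.n_events == 0:
            return None
        return self.n_predicted / self.n_events

    @property
    def false_rate(self) -> float | None:
        """Fraction of crossings that are false alarms; None without crossings."""
        if self.n_crossings == 0:
            return None
        return self.n_false_crossings / self.n_crossings


def extract_pre_onset_window(
    trace: ProbabilityTrace, onset: float, window_s: float = 3.0
) -> ProbabilityTrace:
    """Samples in [onset - window_s, onset), truncated at the trace start."""
    if onset < trace.start_time:
        raise ValueError(f"onset {onset} precedes trace start {trace.start_time}")
    if onset > trace.end_time:
        raise ValueError(f"onset {onset} is beyond the trace end {trace.end_time}")
    fs = trace.sampling_rate
    times = trace.times()
    sel = (times >= onset - window_s) & (times < onset)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise ValueError("pre-onset window contains no samples")
    return ProbabilityTrace(
        values=trace.values[idx[0] : idx[-1] + 1],
        sampling_rate=fs,
        start_time=float(times[idx[0]]),
        foot=trace.foot,
    )


def find_monotone_crossings(
    trace: ProbabilityTrace,
    threshold: float,
    config: PredictionConfig | None = None,
) -> list[PredictionCrossing]:
    """Threshold crossings at the end of a non-decreasing run.

    A crossing is the first sample strictly above ``threshold`` within an
    excursion (so the previous sample is at or below the threshold),
    preceded by a non-decreasing run lasting at least ``min_run_s``.
    Run length is measured from the earliest sample of the maximal
    non-decreasing run up to the crossing sample. A trace that starts
    above the threshold never "rises from below", so it yields no
    crossing until it first returns to or below the threshold. Counted
    crossings are spaced at least ``refractory_s`` apart.
    """
    if config is None:
        config = PredictionConfig()
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    v = trace.values
    fs = trace.sampling_rate
    above = v > threshold
    # excursion starts: strictly above now, at-or-below at the previous sample
    starts = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    crossings: list[PredictionCrossing] = []
    last_time = -np.inf
    for i in starts:
        j = i
        while j > 0 and v[j - 1] <= v[j]:
            j -= 1
        run_s = (i - j) / fs
        if run_s < config.min_run_s:
            continue
        t = trace.start_time + i / fs
        if t - last_time < config.refractory_s:
            continue
        crossings.append(PredictionCrossing(time=t, threshold=threshold, run_length_s=run_s))
        last_time = t
    return crossings


def evaluate_predictions(
    trace: ProbabilityTrace,
    events: Sequence[EventInterval],
    threshold: float,
    config: PredictionConfig | None = None,
) -> PredictionCounts:
    """Score one threshold's crossings against the detected events.

    An event counts as predicted iff some crossing lies in
    [onset - window_s, onset - lead_min_s]. A crossing is a false alarm
    iff no event onset occurs in (t, t + fp_horizon_s]. Crossings whose
    time falls inside an event interval are discarded: prediction is only
    meaningful before onset.
    """
    if config is None:
        config = PredictionConfig()
    events = sorted(events, key=lambda e: e.start)
    for a, b in zip(events, events[1:]):
        if b.start < a.end:
            raise ValueError("events overlap; merge them before evaluating predictions")
    crossings = [
        c
        for c in find_monotone_crossings(trace, threshold, config)
        if not any(e.start <= c.time < e.end for e in events)
    ]
    onsets = np.array([e.start for e in events])
    times = np.array([c.time for c in crossings])
    n_predicted = 0
    for onset in onsets:
        lo, hi = onset - config.window_s, onset - config.lead_min_s
        if times.size and np.any((times >= lo) & (times <= hi)):
            n_predicted += 1
    n_false = 0
    for t in times:
        if not (onsets.size and np.any((onsets > t) & (onsets <= t + config.fp_horizon_s))):
            n_false += 1
    return PredictionCounts(
        threshold=threshold,
        n_events=len(events),
        n_predicted=n_predicted,
        n_crossings=len(crossings),
        n_false_crossings=n_false,
    )


def threshold_sweep(
    cohort: Sequence[tuple[SessionRecording, Sequence[EventInterval]]],
    config: PredictionConfig | None = None,
) -> pd.DataFrame:
    """Mean (SD) true/false prediction rates per threshold across participants.

    Participants contribute to the true-rate average only if they have at
    least one event, and to the false-rate average only if they have at
    least one counted crossing at that threshold. Prediction runs on the
    combined (either-foot maximum) trace.
    """
    if config is None:
        config = PredictionConfig()
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    rows = []
    for threshold in config.thresholds:
        true_rates, false_rates = [], []
        for session, events in cohort:
            combined = combine_feet(session.left, session.right)
            counts = evaluate_predictions(combined, events, threshold, config)
            if counts.true_rate is not None:
                true_rates.append(counts.true_rate)
            if counts.false_rate is not None:
                false_rates.append(counts.false_rate)

        def _mean_sd(xs: list[float]) -> tuple[float, float]:
            if not xs:
                return float("nan"), float("nan")
            arr = np.asarray(xs)
            return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0

        tm, tsd = _mean_sd(true_rates)
        fm, fsd = _mean_sd(false_rates)
        rows.append(
            {
                "threshold": threshold,
                "true_rate_mean": tm,
                "true_rate_sd": tsd,
                "false_rate_mean": fm,
                "false_rate_sd": fsd,
                "n_participants_true": len(true_rates),
                "n_participants_false": len(false_rates),
            }
        )
    return pd.DataFrame(rows)
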