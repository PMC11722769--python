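"""Summary measures: detection accuracy, %WTSF, per-task breakdowns,
and task-potency tables.

Accuracy is the time-based ratio (TP time + TN time) / analysed time,
expressed as a percent. %WTSF (percent of walking time spent freezing)
divides total freezing time within active samples by total active time.
Task potency summarises, per provocation task, how many participants
froze at all and how much ground-truth freezing time the task elicited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    AnnotationSet,
    ConfusionTimes,
    EventInterval,
    SessionRecording,
    TaskSegment,
    intervals_to_mask,
)

__all__ = [
    "AccuracyReport",
    "PotencyRow",
    "accuracy",
    "wtsf",
    "per_task_metrics",
    "task_potency",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AccuracyReport:
    """Overall / per-task / per-category detection accuracy, in percent.

    Tasks (or categories) that contribute no analysed time are absent
    from the maps rather than reported as 0 or 100.
    """

    overall_pct: float
    per_task: Mapping[str, float] = field(default_factory=dict)
    per_category: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for value in (self.overall_pct, *self.per_task.values(), *self.per_category.values()):
            if not 0.0 <= value <= 100.0 + 1e-9:
                raise ValueError(f"accuracy percentage out of [0, 100]: {value}")


@dataclass(frozen=True)
class PotencyRow:
    task_name: str
    n_participants_with_fog: int
    pct_of_sample: float
    total_fog_duration_s: float

    def __post_init__(self):
        if self.n_participants_with_fog < 0 or self.total_fog_duration_s < 0:
            raise ValueError("counts and durations must be non-negative")


def accuracy(conf: ConfusionTimes) -> float:
    """Percent of analysed time classified correctly: 100 (TP + TN) / total."""
    if conf.analyzed_s <= 0:
        raise ValueError("analyzed_s must be positive")
    return 100.0 * (conf.tp_s + conf.tn_s) / conf.analyzed_s


def wtsf(
    events: Iterable[EventInterval],
    active_mask: np.ndarray,
    sampling_rate: float,
    start_time: float = 0.0,
) -> float:
    """Percent of active walking time spent freezing.

    Only freezing samples that are also active count toward the
    numerator; the denominator is the total active time.
    """
    mask = np.asarray(active_mask, dtype=bool)
    active_n = int(np.count_nonzero(mask))
    if active_n == 0:
        raise ValueError("no active time in the mask")
    ev_mask = intervals_to_mask(list(events), mask.size, sampling_rate, start_time)
    freeze_n = int(np.count_nonzero(ev_mask & mask))
    return float(np.clip(100.0 * freeze_n / active_n, 0.0, 100.0))


def _segment_confusion(
    segment: TaskSegment,
    algo_mask: np.ndarray,
    truth_mask: np.ndarray,
    active: np.ndarray,
    centers: np.ndarray,
    sampling_rate: float,
) -> ConfusionTimes:
    sel = (centers >= segment.start) & (centers < segment.end) & active
    tp = int(np.count_nonzero(sel & algo_mask & truth_mask))
    fp = int(np.count_nonzero(sel & algo_mask & ~truth_mask))
    fn = int(np.count_nonzero(sel & ~algo_mask & truth_mask))
    tn = int(np.count_nonzero(sel & ~algo_mask & ~truth_mask))
    return ConfusionTimes(
        tp_s=tp / sampling_rate,
        fp_s=fp / sampling_rate,
        tn_s=tn / sampling_rate,
        fn_s=fn / sampling_rate,
        analyzed_s=(tp + fp + tn + fn) / sampling_rate,
    )


def per_task_metrics(
    session: SessionRecording,
    algo_events: Sequence[EventInterval],
    truth: AnnotationSet,
    segments: Sequence[TaskSegment] | None = None,
) -> tuple[AccuracyReport, dict[str, float]]:
    """Accuracy restricted to each task segment, plus per-task %WTSF.

    Confusion times are computed per segment over that segment's active
    samples; same-named segments pool their times. Category and overall
    aggregates pool confusion *times* across segments rather than
    averaging task percentages, so the overall figure equals the
    duration-weighted mean of the per-task figures. Active samples
    outside every segment are excluded (with a logged warning).
    """
    if segments is None:
        segments = session.segments
    fs = session.sampling_rate
    n = session.n_samples
    t0 = session.start_time
    centers = t0 + (np.arange(n) + 0.5) / fs
    active = session.active_mask
    algo_mask = intervals_to_mask(list(algo_events), n, fs, t0)
    truth_mask = intervals_to_mask(list(truth), n, fs, t0)

    in_any = np.zeros(n, dtype=bool)
    per_task_conf: dict[str, ConfusionTimes] = {}
    per_cat_conf: dict[str, ConfusionTimes] = {}
    total: ConfusionTimes | None = None
    for seg in segments:
        conf = _segment_confusion(seg, algo_mask, truth_mask, active, centers, fs)
        in_any |= (centers >= seg.start) & (centers < seg.end)
        if conf.analyzed_s <= 0:
            continue  # e.g. a fully sedentary task contributes no analysed time
        per_task_conf[seg.name] = (
            per_task_conf[seg.name] + conf if seg.name in per_task_conf else conf
        )
        per_cat_conf[seg.category] = (
            per_cat_conf[seg.category] + conf if seg.category in per_cat_conf else conf
        )
        total = conf if total is None else total + conf

    stray = int(np.count_nonzero(active & ~in_any))
    if stray:
        logger.warning(
            "%d active samples (%.2f s) fall outside every task segment and are excluded",
            stray,
            stray / fs,
        )
    if total is None or total.analyzed_s <= 0:
        raise ValueError("segments contain no analysed (active) time")

    report = AccuracyReport(
        overall_pct=accuracy(total),
        per_task={name: accuracy(c) for name, c in per_task_conf.items()},
        per_category={cat: accuracy(c) for cat, c in per_cat_conf.items()},
    )
    # per-task %WTSF; same-named segments pool freeze/active sample counts
    counts: dict[str, list[int]] = {}
    for seg in segments:
        sel = (centers >= seg.start) & (centers < seg.end) & active
        a = int(np.count_nonzero(sel))
        if a == 0:
            continue
        f = int(np.count_nonzero(sel & algo_mask))
        if seg.name in counts:
            counts[seg.name][0] += f
            counts[seg.name][1] += a
        else:
            counts[seg.name] = [f, a]
    task_wtsf = {name: 100.0 * f / a for name, (f, a) in counts.items()}
    return report, task_wtsf


def task_potency(
    cohort: Sequence[tuple[AnnotationSet, Sequence[TaskSegment]]],
) -> list[PotencyRow]:
    """Which tasks elicited freezing, and how much, across a cohort.

    Per task: the number (and percent) of participants with at least one
    ground-truth freezing interval overlapping that task's segments, and
    the total ground-truth freezing duration within the task summed
    across participants. Potency is assessed on the video-style ground
    truth, not on algorithm events.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    order: list[str] = []
    n_with: dict[str, int] = {}
    dur: dict[str, float] = {}
    for truth, segments in cohort:
        seen: dict[str, float] = {}
        for seg in segments:
            if seg.name not in order:
                order.append(seg.name)
                n_with[seg.name] = 0
                dur[seg.name] = 0.0
            seen[seg.name] = seen.get(seg.name, 0.0) + truth.overlap(seg.start, seg.end)
        for name, t in seen.items():
            if t > 0:
                n_with[name] += 1
            dur[name] += t
    n = len(cohort)
    return [
        PotencyRow(
            task_name=name,
            n_participants_with_fog=n_with[name],
            pct_of_sample=100.0 * n_with[name] / n,
            total_fog_duration_s=dur[name],
        )
        for name in order
    ]
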