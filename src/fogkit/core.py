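"""Core domain types shared across the fogkit pipeline.

Conventions used throughout the package:

* All intervals are half-open ``[start, end)`` in seconds.
* Sample ``i`` of a uniformly sampled series covers
  ``[start_time + i/fs, start_time + (i+1)/fs)``; its *center*
  ``start_time + (i + 0.5)/fs`` decides whether an interval covers it.
* Sample indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "ProbabilityTrace",
    "EventInterval",
    "AnnotationSet",
    "TaskSegment",
    "SessionRecording",
    "ConfusionTimes",
    "intervals_to_mask",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


def _as_float_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D sequence of values")
    return arr


@dataclass(frozen=True)
class ProbabilityTrace:
    """Uniformly sampled freeze-probability values in [0, 1] for one foot.

    Parameters
    ----------
    values : array-like of float
        Per-sample probabilities, each in [0, 1].
    sampling_rate : float
        Sampling rate in Hz; must be positive.
    start_time : float
        Time of the first sample's left edge, seconds.
    foot : str
        One of ``"left"``, ``"right"``, ``"combined"``.
    """

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    foot: str = "combined"

    def __post_init__(self):
        arr = _as_float_array(self.values)
        if arr.size < 1:
            raise ValueError("trace must contain at least one sample")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.foot not in ("left", "right", "combined"):
            raise ValueError(f"unknown foot label {self.foot!r}")
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            bad = int(np.argmax((arr < 0.0) | (arr > 1.0)))
            raise ValueError(
                f"probability out of [0, 1] at sample {bad}: {arr[bad]!r}"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Covered duration in seconds (n / fs)."""
        return self.values.size / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        """Left-edge time of every sample."""
        return self.start_time + np.arange(self.values.size) / self.sampling_rate

    def sample_centers(self) -> np.ndarray:
        return self.start_time + (np.arange(self.values.size) + 0.5) / self.sampling_rate

    def with_values(self, values, foot: str | None = None) -> "ProbabilityTrace":
        return ProbabilityTrace(
            values=values,
            sampling_rate=self.sampling_rate,
            start_time=self.start_time,
            foot=foot if foot is not None else self.foot,
        )


@dataclass(frozen=True, order=True)
class EventInterval:
    """A half-open [start, end) freezing interval, in seconds."""

    start: float
    end: float
    source: str = field(default="algorithm", compare=False)

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"interval must satisfy start < end, got [{self.start}, {self.end})")
        if self.source not in ("algorithm", "video"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def overlap(self, start: float, end: float) -> float:
        """Length of intersection with [start, end), in seconds."""
        return max(0.0, min(self.end, end) - max(self.start, start))


@dataclass(frozen=True)
class AnnotationSet:
    """Sorted, pairwise-disjoint ground-truth freezing intervals."""

    intervals: tuple
    rater_id: str = "video"

    def __post_init__(self):
        ivs = tuple(sorted(self.intervals, key=lambda iv: iv.start))
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"annotations overlap: [{a.start}, {a.end}) and [{b.start}, {b.end})"
                )
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def total_duration(self) -> float:
        return sum(iv.duration for iv in self.intervals)

    def overlap(self, start: float, end: float) -> float:
        """Total annotated time intersecting [start, end)."""
        return sum(iv.overlap(start, end) for iv in self.intervals)


# The ten in-lab provocation tasks: three walking tasks in single- and
# dual-task form (counting backwards by threes), plus four simulated
# instrumental activities of daily living.
CLINIC_FOG_TASKS = (
    "Hallway",
    "Hallway-DT",
    "GOT",
    "GOT-DT",
    "360",
    "360-DT",
)
IADL_TASKS = ("Vacuuming", "Dishwasher", "Sitting", "Community")


def default_category(name: str) -> str:
    return "clinic_fog" if name in CLINIC_FOG_TASKS else "iadl"


@dataclass(frozen=True)
class TaskSegment:
    """One contiguous task block within a session, half-open [start, end)."""

    name: str
    start: float
    end: float
    category: str = ""
    dual_task: bool = False

    def __post_init__(self):
        if not self.name:
            raise ValueError("segment name must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"segment must satisfy start < end, got [{self.start}, {self.end})")
        if self.category == "":
            object.__setattr__(self, "category", default_category(self.name))
        if self.category not in ("clinic_fog", "iadl"):
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SessionRecording:
    """One participant's lab session.

    Holds the paired per-foot probability traces, an optional surrogate
    raw tri-axial acceleration channel per foot, the hip-sensor-derived
    active-time mask, and the ordered task segmentation. All per-sample
    series share one length and one sampling rate.
    """

    left: ProbabilityTrace
    right: ProbabilityTrace
    active_mask: np.ndarray
    segments: tuple
    raw_imu: dict | None = None  # {"left": (n, 3) array, "right": (n, 3) array}

    def __post_init__(self):
        if self.left.foot != "left" or self.right.foot != "right":
            raise ValueError("traces must be labelled foot='left' and foot='right'")
        if (
            len(self.left) != len(self.right)
            or self.left.sampling_rate != self.right.sampling_rate
            or self.left.start_time != self.right.start_time
        ):
            raise ValueError("left and right traces must share length, rate and start")
        mask = np.asarray(self.active_mask, dtype=bool)
        if mask.shape != (len(self.left),):
            raise ValueError("active_mask length must match the traces")
        mask.setflags(write=False)
        object.__setattr__(self, "active_mask", mask)
        segs = tuple(sorted(self.segments, key=lambda s: s.start))
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(f"segments overlap: {a.name} and {b.name}")
        object.__setattr__(self, "segments", segs)
        if self.raw_imu is not None:
            raw = {}
            for foot in ("left", "right"):
                if foot not in self.raw_imu:
                    raise ValueError(f"raw_imu missing channel for foot {foot!r}")
                ch = np.asarray(self.raw_imu[foot], dtype=float)
                if ch.shape != (len(self.left), 3):
                    raise ValueError(f"raw_imu[{foot!r}] must have shape (n_samples, 3)")
                ch.setflags(write=False)
                raw[foot] = ch
            object.__setattr__(self, "raw_imu", raw)

    @property
    def sampling_rate(self) -> float:
        return self.left.sampling_rate

    @property
    def start_time(self) -> float:
        return self.left.start_time

    @property
    def n_samples(self) -> int:
        return len(self.left)

    @property
    def duration(self) -> float:
        return self.left.duration

    @property
    def end_time(self) -> float:
        return self.left.end_time


@dataclass(frozen=True)
class ConfusionTimes:
    """Time-based confusion durations over the analysed (active) time, seconds."""

    tp_s: float
    fp_s: float
    tn_s: float
    fn_s: float
    analyzed_s: float

    def __post_init__(self):
        for name in ("tp_s", "fp_s", "tn_s", "fn_s", "analyzed_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        total = self.tp_s + self.fp_s + self.tn_s + self.fn_s
        if abs(total - self.analyzed_s) > 1e-6 * max(1.0, self.analyzed_s):
            raise ValueError(
                f"confusion times sum to {total}, expected analyzed_s={self.analyzed_s}"
            )

    def __add__(self, other: "ConfusionTimes") -> "ConfusionTimes":
        return ConfusionTimes(
            tp_s=self.tp_s + other.tp_s,
            fp_s=self.fp_s + other.fp_s,
            tn_s=self.tn_s + other.tn_s,
            fn_s=self.fn_s + other.fn_s,
            analyzed_s=self.analyzed_s + other.analyzed_s,
        )


def intervals_to_mask(
    intervals: Iterable[EventInterval],
    n_samples: int,
    sampling_rate: float,
    start_time: float = 0.0,
) -> np.ndarray:
    """Rasterise half-open intervals onto a sample grid.

    A sample is covered iff its center ``start_time + (i + 0.5)/fs`` lies
    inside some interval.
    """
    mask = np.zeros(n_samples, dtype=bool)
    centers = start_time + (np.arange(n_samples) + 0.5) / sampling_rate
    for iv in intervals:
        lo = np.searchsorted(centers, iv.start, side="left")
        hi = np.searchsorted(centers, iv.end, side="left")
        mask[lo:hi] = True
    return mask
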