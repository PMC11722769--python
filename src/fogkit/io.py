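"""CSV/YAML/JSON readers and writers plus the end-to-end pipeline runner.

Formats (all plain text; times in seconds at fixed 6-decimal precision so
repeated runs are byte-identical):

* trace CSV — ``time_s, left_prob, right_prob, active`` plus optional
  ``raw_{left,right}_{x,y,z}`` columns; one row per sample.
* interval CSV — ``start_s, end_s, label, task``; half-open rows.
* segments CSV — ``name, start_s, end_s, category, dual_task``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .core import (
    AnnotationSet,
    EventInterval,
    ProbabilityTrace,
    SessionRecording,
    TaskSegment,
)
from .detector import make_surrogate_detector
from .events import combine_feet, detect_events
from .metrics import task_potency
from .prediction import PredictionConfig, threshold_sweep
from .resample import sampling_study
from .synthetic import SyntheticConfig, generate_cohort

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_intervals_csv",
    "write_intervals_csv",
    "read_segments_csv",
    "write_segments_csv",
    "load_synthetic_config",
    "save_synthetic_config",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_FMT = "%.6f"
_RAW_COLS = [f"raw_{foot}_{ax}" for foot in ("left", "right") for ax in "xyz"]


class ParseError(ValueError):
    """Malformed input file; the message cites the file and data row."""


def write_trace_csv(session: SessionRecording, path) -> None:
    cols = {
        "time_s": session.left.times(),
        "left_prob": session.left.values,
        "right_prob": session.right.values,
        "active": session.active_mask.astype(int),
    }
    if session.raw_imu is not None:
        for foot in ("left", "right"):
            for k, ax in enumerate("xyz"):
                cols[f"raw_{foot}_{ax}"] = session.raw_imu[foot][:, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FMT)


def read_trace_csv(path, segments: Sequence[TaskSegment] | None = None) -> SessionRecording:
    """Read a trace CSV, inferring the rate from the median time step.

    The time base must be uniform within 1e-6 relative tolerance and
    probabilities must lie in [0, 1]; violations raise ParseError citing
    the offending data row (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "left_prob", "right_prob", "active"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if len(df) < 2:
        raise ParseError(f"{path}: need at least two samples to infer a rate")
    t = df["time_s"].to_numpy(dtype=float)
    steps = np.diff(t)
    step = float(np.median(steps))
    if step <= 0:
        raise ParseError(f"{path}: non-increasing time base")
    bad = np.flatnonzero(np.abs(steps - step) > 1e-6 * max(step, 1.0))
    if bad.size:
        row = int(bad[0]) + 2
        raise ParseError(f"{path}: non-uniform time step at row {row}")
    for col in ("left_prob", "right_prob"):
        v = df[col].to_numpy(dtype=float)
        out = np.flatnonzero((v < 0.0) | (v > 1.0) | ~np.isfinite(v))
        if out.size:
            row = int(out[0]) + 1
            raise ParseError(f"{path}: {col} out of [0, 1] at row {row}: {v[out[0]]}")
    fs = 1.0 / step
    start = float(t[0])
    n = len(df)
    if segments is None:
        segments = (TaskSegment("session", start, start + n / fs, category="iadl"),)
    raw = None
    if all(c in df.columns for c in _RAW_COLS):
        raw = {
            foot: np.column_stack([df[f"raw_{foot}_{ax}"].to_numpy(float) for ax in "xyz"])
            for foot in ("left", "right")
        }
    return SessionRecording(
        left=ProbabilityTrace(df["left_prob"].to_numpy(float), fs, start, "left"),
        right=ProbabilityTrace(df["right_prob"].to_numpy(float), fs, start, "right"),
        active_mask=df["active"].to_numpy().astype(bool),
        segments=tuple(segments),
        raw_imu=raw,
    )


def write_intervals_csv(intervals, path, tasks: Sequence[str] | None = None) -> None:
    """Write events or annotations as an interval CSV."""
    rows = []
    intervals = list(intervals)
    if tasks is None:
        tasks = [""] * len(intervals)
    for iv, task in zip(intervals, tasks):
        rows.append(
            {"start_s": iv.start, "end_s": iv.end, "label": iv.source, "task": task}
        )
    pd.DataFrame(rows, columns=["start_s", "end_s", "label", "task"]).to_csv(
        path, index=False, float_format=_FMT
    )


def read_intervals_csv(path, source: str | None = None) -> AnnotationSet:
    """Read a sorted, validated interval CSV into an AnnotationSet.

    Touching half-open intervals ([1,2), [2,3)) are fine; overlap is an
    error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("start_s", "end_s"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    intervals = []
    for i, row in df.iterrows():
        s, e = float(row["start_s"]), float(row["end_s"])
        if not s < e:
            raise ParseError(f"{path}: start >= end at row {int(i) + 1}")
        label = source if source is not None else str(row.get("label", "video"))
        intervals.append(EventInterval(s, e, source=label if label in ("algorithm", "video") else "video"))
    try:
        return AnnotationSet(tuple(intervals))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_segments_csv(segments: Sequence[TaskSegment], path) -> None:
    pd.DataFrame(
        [
            {
                "name": s.name,
                "start_s": s.start,
                "end_s": s.end,
                "category": s.category,
                "dual_task": int(s.dual_task),
            }
            for s in segments
        ]
    ).to_csv(path, index=False, float_format=_FMT)


def read_segments_csv(path) -> tuple[TaskSegment, ...]:
    df = pd.read_csv(path)
    return tuple(
        TaskSegment(
            name=str(r["name"]),
            start=float(r["start_s"]),
            end=float(r["end_s"]),
            category=str(r["category"]),
            dual_task=bool(r["dual_task"]),
        )
        for _, r in df.iterrows()
    )


def save_synthetic_config(config: SyntheticConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["task_plan"] = [list(entry) for entry in config.task_plan]
    d["tremble_band"] = list(config.tremble_band)
    d["impact_carrier_band"] = list(config.impact_carrier_band)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_synthetic_config(path) -> SyntheticConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "task_plan" in d:
        d["task_plan"] = tuple((str(n), float(dur), bool(sed)) for n, dur, sed in d["task_plan"])
    for key in ("tremble_band", "impact_carrier_band"):
        if key in d:
            d[key] = tuple(d[key])
    return SyntheticConfig(**d)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    Exactly one of (``trace_csv``) or (``synthetic``) must be provided;
    file-based runs analyse a single recorded session, synthetic runs
    generate a seeded cohort.
    """

    out_dir: str
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    n_participants: int = 13
    trace_csv: str | None = None
    intervals_csv: str | None = None
    segments_csv: str | None = None
    prediction: PredictionConfig = field(default_factory=PredictionConfig)
    rates: tuple = (100.0, 60.0, 30.0)
    threshold: float = 0.7
    merge_gap: float = 2.0
    log_level: str = "INFO"

    def __post_init__(self):
        has_files = self.trace_csv is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ValueError("provide exactly one of trace_csv or synthetic config")
        if has_files and self.intervals_csv is None:
            raise ValueError("file-based runs need intervals_csv ground truth")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"cannot serialise {type(o)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run detection, prediction, potency and the sampling study; write reports.

    Outputs in ``out_dir``: ``events.csv``, ``prediction_sweep.csv``,
    ``task_potency.csv``, ``sampling_accuracy.csv``, ``sampling_wtsf.csv``,
    ``sampling_stats.json`` and ``run_log.json``. Identical config + seed
    give byte-identical files. The sampling study requires raw IMU
    channels and is skipped (with a log message) when they are absent.
    Returns the artifact paths keyed by name.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        synth = dataclasses.replace(config.synthetic, seed=config.seed)
        cohort = generate_cohort(synth, config.n_participants, seed=config.seed)
    else:
        segments = read_segments_csv(config.segments_csv) if config.segments_csv else None
        session = read_trace_csv(config.trace_csv, segments)
        truth = read_intervals_csv(config.intervals_csv, source="video")
        cohort = [(session, truth)]

    artifacts: dict[str, str] = {}

    # -- events ----------------------------------------------------------
    all_events = []
    for session, _truth in cohort:
        combined = combine_feet(session.left, session.right)
        all_events.append(detect_events(combined, config.threshold, config.merge_gap))
    ev_rows = []
    for pid, events in enumerate(all_events):
        for iv in events:
            ev_rows.append({"participant": pid, "start_s": iv.start, "end_s": iv.end, "label": iv.source})
    pd.DataFrame(ev_rows, columns=["participant", "start_s", "end_s", "label"]).to_csv(
        out / "events.csv", index=False, float_format=_FMT
    )
    artifacts["events"] = str(out / "events.csv")

    # -- prediction sweep --------------------------------------------------
    sweep = threshold_sweep(
        [(s, ev) for (s, _t), ev in zip(cohort, all_events)], config.prediction
    )
    sweep.to_csv(out / "prediction_sweep.csv", index=False, float_format=_FMT)
    artifacts["prediction_sweep"] = str(out / "prediction_sweep.csv")

    # -- task potency ------------------------------------------------------
    potency = task_potency([(truth, session.segments) for session, truth in cohort])
    pd.DataFrame([dataclasses.asdict(r) for r in potency]).to_csv(
        out / "task_potency.csv", index=False, float_format=_FMT
    )
    artifacts["task_potency"] = str(out / "task_potency.csv")

    # -- sampling-rate study ----------------------------------------------
    has_raw = all(session.raw_imu is not None for session, _ in cohort)
    if has_raw:
        study = sampling_study(
            [s for s, _ in cohort],
            make_surrogate_detector(),
            [t for _, t in cohort],
            rates=config.rates,
            threshold=config.threshold,
            merge_gap=config.merge_gap,
        )
        acc_rows, wtsf_rows = [], []
        for rate in study.rates:
            m, sd = study.accuracy_mean_sd(rate)
            acc_rows.append({"rate_hz": rate, "accuracy_mean_pct": m, "accuracy_sd_pct": sd})
            wm, wsd = study.wtsf_mean_sd(rate)
            wtsf_rows.append({"rate_hz": rate, "wtsf_mean_pct": wm, "wtsf_sd_pct": wsd})
        pd.DataFrame(acc_rows).to_csv(out / "sampling_accuracy.csv", index=False, float_format=_FMT)
        pd.DataFrame(wtsf_rows).to_csv(out / "sampling_wtsf.csv", index=False, float_format=_FMT)
        stats_doc = {
            "anova": dataclasses.asdict(study.anova) if study.anova else None,
            "tukey": [dataclasses.asdict(c) for c in study.tukey] if study.tukey else None,
        }
        (out / "sampling_stats.json").write_text(
            json.dumps(stats_doc, indent=2, sort_keys=True, default=_json_default) + "\n"
        )
        artifacts["sampling_accuracy"] = str(out / "sampling_accuracy.csv")
        artifacts["sampling_wtsf"] = str(out / "sampling_wtsf.csv")
        artifacts["sampling_stats"] = str(out / "sampling_stats.json")
    else:
        logger.info("no raw IMU channels present; sampling-rate study skipped")

    # -- run log -----------------------------------------------------------
    cfg_doc = dataclasses.asdict(config)
    cfg_doc.pop("out_dir", None)  # the bundle must not depend on where it lands
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_doc, sort_keys=True, default=_json_default).encode()
    ).hexdigest()
    (out / "run_log.json").write_text(
        json.dumps(
            {
                "package_version": _pkg_version,
                "seed": config.seed,
                "config_sha256": cfg_hash,
                "n_participants": len(cohort),
                "artifacts": sorted(artifacts),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    artifacts["run_log"] = str(out / "run_log.json")
    return artifacts
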