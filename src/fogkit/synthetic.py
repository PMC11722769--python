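"""Seeded synthetic sessions with the statistical structure the analyses assume.

The generator stands in for undeposited participant recordings. A session
is an ordered plan of provocation tasks (hallway pivoting, go-outside-and-
turn, 360-degree turning — each single or dual-task — plus simulated
activities of daily living and a sedentary sitting block). Each planted
freeze is a probability pattern on one randomly chosen foot:

* a monotonic pre-onset ramp from ``ramp_start_prob`` to
  ``ramp_peak_prob`` over ``ramp_duration`` seconds (piecewise-linear by
  default, so threshold crossing times are closed-form),
* a supra-0.7 plateau held for ``freeze_hold`` seconds,
* a linear decay back to baseline.

Ground truth is the half-open interval from the moment the ramp reaches
0.7 to the moment the decay falls below it, optionally jittered to mimic
video-rater onset/offset noise. Sub-0.7 "false rises" with the same ramp
shape exercise the false-alarm accounting. Optional surrogate tri-axial
acceleration channels carry a ~2 Hz locomotion component while walking
and, during freezes, a trembling complex: a direct 3-8 Hz component plus
shuffle-impact transients synthesised as a 13-19 Hz carrier amplitude-
modulated at the trembling rate (content near the 15 Hz Nyquist of a
30 Hz recording, which is what the sampling-rate study degrades).

Everything is a pure function of (config, seed): identical seeds give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .core import (
    AnnotationSet,
    ConfigError,
    EventInterval,
    ProbabilityTrace,
    SessionRecording,
    TaskSegment,
    default_category,
)
from .events import detect_events

__all__ = [
    "SyntheticConfig",
    "DEFAULT_TASK_PLAN",
    "generate_session",
    "generate_cohort",
    "synthesize_raw_imu",
]

# (task name, duration s, is_sedentary); a compact lab visit covering the
# three walking tasks in single and dual-task form plus the four
# simulated activities of daily living.
DEFAULT_TASK_PLAN = (
    ("Hallway", 60.0, False),
    ("Hallway-DT", 60.0, False),
    ("GOT", 60.0, False),
    ("GOT-DT", 60.0, False),
    ("360", 60.0, False),
    ("360-DT", 60.0, False),
    ("Vacuuming", 90.0, False),
    ("Dishwasher", 90.0, False),
    ("Sitting", 120.0, True),
    ("Community", 180.0, False),
)

_EVENT_THRESHOLD = 0.7  # probability defining a freeze event
_MIN_EVENT_GAP_S = 4.0  # spacing between planted patterns (> 2 s merge gap)
_FALSE_RISE_CLEARANCE_S = 6.5  # keep false rises clear of true-event onsets


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything that defines one synthetic participant session."""

    seed: int = 0
    sampling_rate: float = 100.0
    task_plan: tuple = DEFAULT_TASK_PLAN
    freezes_per_task: float = 1.5  # Poisson mean per non-sedentary task
    freeze_counts: Mapping[str, int] | None = None  # exact-count override
    ramp_duration: float = 3.0
    ramp_start_prob: float = 0.05
    ramp_peak_prob: float = 0.95
    ramp_shape: str = "linear"  # or "logistic"
    freeze_hold: float = 3.0  # seconds held at the peak (above 0.7)
    fall_duration: float = 1.0
    false_rise_rate: float = 0.5  # expected sub-0.7 rises per active minute
    false_rise_peak: float = 0.6
    baseline_mean: float = 0.05
    baseline_sd: float = 0.02
    annotation_jitter_sd: float = 0.1
    emit_raw_imu: bool = False
    locomotion_freq: float = 2.0
    tremble_band: tuple = (3.0, 8.0)
    # raw-IMU amplitudes (units of g); see docs/methods.md for the rationale
    loco_amp: float = 0.5
    tremble_amp: float = 0.2  # direct 3-8 Hz trembling component
    impact_amp: float = 1.2  # shuffle-impact carrier, AM at the trembling rate
    impact_carrier_band: tuple = (13.0, 19.0)
    shuffle_factor: float = 0.25  # residual locomotion-band motion during freezes
    amp_jitter_sd: float = 0.25  # lognormal sigma on per-event amplitude
    noise_sd: float = 0.05

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate", "must be positive")
        if not self.task_plan:
            raise ConfigError("task_plan", "must contain at least one task")
        for entry in self.task_plan:
            name, dur, _sed = entry
            if not name:
                raise ConfigError("task_plan", "task names must be non-empty")
            if dur <= 0:
                raise ConfigError("task_plan", f"duration of {name!r} must be positive")
        if not 0.0 <= self.ramp_start_prob < self.ramp_peak_prob <= 1.0:
            raise ConfigError(
                "ramp_start_prob", "need 0 <= ramp_start_prob < ramp_peak_prob <= 1"
            )
        if self.ramp_peak_prob <= _EVENT_THRESHOLD:
            raise ConfigError(
                "ramp_peak_prob", f"must exceed {_EVENT_THRESHOLD} so planted freezes are detectable"
            )
        if not self.ramp_start_prob < _EVENT_THRESHOLD:
            raise ConfigError("ramp_start_prob", "must start below the 0.7 event threshold")
        if not 0.0 < self.false_rise_peak < _EVENT_THRESHOLD:
            raise ConfigError("false_rise_peak", "must lie strictly below 0.7")
        for name in ("ramp_duration", "freeze_hold", "fall_duration"):
            if getattr(self, name) <= 0:
                raise ConfigError(name, "must be positive")
        if self.freezes_per_task < 0:
            raise ConfigError("freezes_per_task", "must be non-negative")
        if self.false_rise_rate < 0:
            raise ConfigError("false_rise_rate", "must be non-negative")
        if self.baseline_sd < 0 or not 0.0 <= self.baseline_mean <= 1.0:
            raise ConfigError("baseline_mean", "baseline noise parameters out of range")
        if self.annotation_jitter_sd < 0:
            raise ConfigError("annotation_jitter_sd", "must be non-negative")
        if self.ramp_shape not in ("linear", "logistic"):
            raise ConfigError("ramp_shape", "must be 'linear' or 'logistic'")
        lo, hi = self.tremble_band
        if not 0 < lo < hi:
            raise ConfigError("tremble_band", "must be an increasing positive (lo, hi) pair")
        clo, chi = self.impact_carrier_band
        if not 0 < clo < chi:
            raise ConfigError("impact_carrier_band", "must be an increasing positive pair")

    @property
    def pattern_duration(self) -> float:
        """Full ramp + hold + decay length of one planted freeze, seconds."""
        return self.ramp_duration + self.freeze_hold + self.fall_duration

    def segments(self) -> tuple[TaskSegment, ...]:
        segs = []
        t = 0.0
        for name, dur, _sed in self.task_plan:
            segs.append(
                TaskSegment(
                    name=name,
                    start=t,
                    end=t + dur,
                    category=default_category(name),
                    dual_task=name.endswith("-DT") or name.endswith(" DT"),
                )
            )
            t += dur
        return tuple(segs)


def _ramp_values(cfg: SyntheticConfig, rel_t: np.ndarray, peak: float) -> np.ndarray:
    """Probability during the rise, for times since ramp start."""
    frac = np.clip(rel_t / cfg.ramp_duration, 0.0, 1.0)
    if cfg.ramp_shape == "linear":
        return cfg.ramp_start_prob + (peak - cfg.ramp_start_prob) * frac
    # logistic, normalised so the endpoints hit start/peak exactly
    k = 10.0
    raw = 1.0 / (1.0 + np.exp(-k * (frac - 0.5)))
    lo, hi = 1.0 / (1.0 + math.exp(k / 2)), 1.0 / (1.0 + math.exp(-k / 2))
    return cfg.ramp_start_prob + (peak - cfg.ramp_start_prob) * (raw - lo) / (hi - lo)


def _rise_crossing_offset(cfg: SyntheticConfig, peak: float, level: float) -> float:
    """Time after ramp start at which the rise reaches ``level`` (continuous)."""
    frac_level = (level - cfg.ramp_start_prob) / (peak - cfg.ramp_start_prob)
    if cfg.ramp_shape == "linear":
        return cfg.ramp_duration * frac_level
    k = 10.0
    lo, hi = 1.0 / (1.0 + math.exp(k / 2)), 1.0 / (1.0 + math.exp(-k / 2))
    raw = lo + frac_level * (hi - lo)
    return cfg.ramp_duration * (0.5 + math.log(raw / (1.0 - raw)) / k)


def _plant_pattern(
    values: np.ndarray, cfg: SyntheticConfig, t_start: float, peak: float
) -> None:
    """Write one ramp/hold/decay pattern into a trace (in place, via max)."""
    fs = cfg.sampling_rate
    n = values.size
    t_hold = t_start + cfg.ramp_duration
    t_fall = t_hold + cfg.freeze_hold
    t_end = t_fall + cfg.fall_duration
    i0 = max(0, int(math.ceil(t_start * fs)))
    i1 = min(n, int(math.ceil(t_end * fs)))
    t = np.arange(i0, i1) / fs
    pat = np.empty(t.size)
    rising = t < t_hold
    pat[rising] = _ramp_values(cfg, t[rising] - t_start, peak)
    holding = (t >= t_hold) & (t < t_fall)
    pat[holding] = peak
    falling = t >= t_fall
    pat[falling] = peak + (cfg.ramp_start_prob - peak) * np.clip(
        (t[falling] - t_fall) / cfg.fall_duration, 0.0, 1.0
    )
    values[i0:i1] = np.maximum(values[i0:i1], pat)


def _truth_interval(cfg: SyntheticConfig, t_start: float) -> tuple[float, float]:
    """Continuous-time [onset, offset) of a pattern planted at ``t_start``."""
    onset = t_start + _rise_crossing_offset(cfg, cfg.ramp_peak_prob, _EVENT_THRESHOLD)
    t_fall = t_start + cfg.ramp_duration + cfg.freeze_hold
    frac = (cfg.ramp_peak_prob - _EVENT_THRESHOLD) / (cfg.ramp_peak_prob - cfg.ramp_start_prob)
    offset = t_fall + cfg.fall_duration * frac
    return onset, offset


def _place_patterns(
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    seg: TaskSegment,
    count: int,
    occupied: list[tuple[float, float]],
    pattern_len: float,
    margin: float = 0.3,
) -> list[float]:
    """Choose non-overlapping pattern start times inside one segment."""
    placed = []
    lo = seg.start + margin
    hi = seg.end - pattern_len - margin
    if hi <= lo:
        return placed
    for _ in range(count):
        for _try in range(200):
            t = float(rng.uniform(lo, hi))
            span = (t - _MIN_EVENT_GAP_S, t + pattern_len + _MIN_EVENT_GAP_S)
            if all(e <= span[0] or s >= span[1] for s, e in occupied):
                occupied.append((t, t + pattern_len))
                placed.append(t)
                break
    return placed


def generate_session(config: SyntheticConfig) -> tuple[SessionRecording, AnnotationSet]:
    """Generate one seeded synthetic session and its ground-truth annotations.

    The returned annotations contain exactly the planted freeze intervals
    (onset = the moment the ramp reaches 0.7, offset = the moment the
    decay falls below it), each jittered by ``annotation_jitter_sd`` with
    truncation so intervals never invert or overlap. Baseline noise is a
    truncated Gaussian (clipped at four standard deviations and to
    [0, 1]); with the defaults all baseline samples remain far below the
    smallest prediction threshold.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    segments = config.segments()
    total = segments[-1].end
    n = int(round(total * fs))

    sedentary_names = {name for name, _d, sed in config.task_plan if sed}
    active = np.ones(n, dtype=bool)
    centers = (np.arange(n) + 0.5) / fs
    for seg in segments:
        if seg.name in sedentary_names:
            active[(centers >= seg.start) & (centers < seg.end)] = False

    def _baseline() -> np.ndarray:
        noise = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
        lo = config.baseline_mean - 4.0 * config.baseline_sd
        hi = config.baseline_mean + 4.0 * config.baseline_sd
        return np.clip(noise, max(lo, 0.0), min(hi, 1.0))

    values = {"left": _baseline(), "right": _baseline()}

    # ---- plant freezes ------------------------------------------------
    occupied: list[tuple[float, float]] = []
    truth: list[EventInterval] = []
    pattern_len = config.pattern_duration
    for seg in segments:
        if seg.name in sedentary_names:
            continue
        if config.freeze_counts is not None:
            count = int(config.freeze_counts.get(seg.name, 0))
        else:
            count = int(rng.poisson(config.freezes_per_task))
        for t_start in _place_patterns(rng, config, seg, count, occupied, pattern_len):
            foot = "left" if rng.random() < 0.5 else "right"
            _plant_pattern(values[foot], config, t_start, config.ramp_peak_prob)
            onset, offset = _truth_interval(config, t_start)
            truth.append(EventInterval(onset, offset, source="video"))
    truth.sort(key=lambda iv: iv.start)

    # ---- rater jitter (truncated so intervals never invert/overlap) ---
    if config.annotation_jitter_sd > 0 and truth:
        jittered = []
        max_dev = 2.0 * config.annotation_jitter_sd
        for i, iv in enumerate(truth):
            lo_bound = jittered[-1].end if jittered else 0.0
            hi_bound = truth[i + 1].start if i + 1 < len(truth) else total
            s = iv.start + float(np.clip(rng.normal(0, config.annotation_jitter_sd), -max_dev, max_dev))
            e = iv.end + float(np.clip(rng.normal(0, config.annotation_jitter_sd), -max_dev, max_dev))
            s = min(max(s, lo_bound), iv.end - 0.2)
            e = max(min(e, hi_bound), s + 0.2)
            jittered.append(EventInterval(s, e, source="video"))
        truth = jittered

    # ---- sub-0.7 false rises ------------------------------------------
    active_minutes = float(active.sum()) / fs / 60.0
    n_rises = int(rng.poisson(config.false_rise_rate * active_minutes))
    rise_len = config.ramp_duration + 0.3 + config.fall_duration
    for _ in range(n_rises):
        for _try in range(200):
            t = float(rng.uniform(0.3, total - rise_len - 0.3))
            span = (t - _FALSE_RISE_CLEARANCE_S, t + rise_len + _FALSE_RISE_CLEARANCE_S)
            idx = int(np.clip(round(t * fs), 0, n - 1))
            if not active[idx]:
                continue
            if all(e <= span[0] or s >= span[1] for s, e in occupied):
                occupied.append((t, t + rise_len))
                foot = "left" if rng.random() < 0.5 else "right"
                _plant_false_rise(values[foot], config, t)
                break

    left = ProbabilityTrace(np.clip(values["left"], 0.0, 1.0), fs, foot="left")
    right = ProbabilityTrace(np.clip(values["right"], 0.0, 1.0), fs, foot="right")
    session = SessionRecording(left=left, right=right, active_mask=active, segments=segments)
    annotations = AnnotationSet(tuple(truth), rater_id="synthetic-video")
    if config.emit_raw_imu:
        session = synthesize_raw_imu(session, config)
    return session, annotations


def _plant_false_rise(values: np.ndarray, cfg: SyntheticConfig, t_start: float) -> None:
    """A monotone rise to a sub-0.7 peak, brief hold, then decay."""
    sub = replace(cfg, emit_raw_imu=False)  # reuse the ramp shape machinery
    fs = cfg.sampling_rate
    n = values.size
    peak = cfg.false_rise_peak
    t_hold = t_start + cfg.ramp_duration
    t_fall = t_hold + 0.3
    t_end = t_fall + cfg.fall_duration
    i0 = max(0, int(math.ceil(t_start * fs)))
    i1 = min(n, int(math.ceil(t_end * fs)))
    t = np.arange(i0, i1) / fs
    pat = np.empty(t.size)
    rising = t < t_hold
    pat[rising] = _ramp_values(sub, t[rising] - t_start, peak)
    holding = (t >= t_hold) & (t < t_fall)
    pat[holding] = peak
    falling = t >= t_fall
    pat[falling] = peak + (cfg.ramp_start_prob - peak) * np.clip(
        (t[falling] - t_fall) / cfg.fall_duration, 0.0, 1.0
    )
    values[i0:i1] = np.maximum(values[i0:i1], pat)


def generate_cohort(
    config: SyntheticConfig,
    n_participants: int,
    seed: int | None = None,
    n_with_fog: int | None = None,
) -> list[tuple[SessionRecording, AnnotationSet]]:
    """Generate ``n_participants`` independent sessions.

    Per-participant seeds are derived from ``seed`` (default: the
    config's seed) through a SeedSequence, so the cohort is reproducible
    from (config, seed) and participant i's session equals
    ``generate_session`` with that derived seed. With ``n_with_fog`` set,
    a seeded random subset of exactly that many participants keeps the
    config's freeze plan; the rest have no freezes planted.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if seed is None:
        seed = config.seed
    state = np.random.SeedSequence(seed).generate_state(n_participants + 1)
    per_seed = [int(s) & 0x7FFFFFFF for s in state[:n_participants]]
    with_fog = [True] * n_participants
    if n_with_fog is not None:
        if not 0 <= n_with_fog <= n_participants:
            raise ValueError("n_with_fog must lie in [0, n_participants]")
        pick_rng = np.random.default_rng(int(state[-1]) & 0x7FFFFFFF)
        chosen = pick_rng.choice(n_participants, size=n_with_fog, replace=False)
        with_fog = [i in set(chosen.tolist()) for i in range(n_participants)]
    out = []
    for i in range(n_participants):
        cfg_i = replace(config, seed=per_seed[i])
        if not with_fog[i]:
            cfg_i = replace(cfg_i, freezes_per_task=0.0, freeze_counts=None)
        out.append(generate_session(cfg_i))
    return out


def _smooth_gate(indicator: np.ndarray, fs: float, ramp_s: float = 0.3) -> np.ndarray:
    """Soften a 0/1 indicator with a short Hanning ramp (avoids clicks)."""
    w = int(round(ramp_s * fs))
    if w < 3:
        return indicator.astype(float)
    kern = np.hanning(w)
    kern /= kern.sum()
    return np.convolve(indicator.astype(float), kern, mode="same")


def synthesize_raw_imu(session: SessionRecording, config: SyntheticConfig) -> SessionRecording:
    """Add surrogate tri-axial acceleration channels to a session.

    Channels are in units of g with gravity (1 g) on the vertical axis.
    While walking (active, non-freeze) the vertical axis carries a
    locomotion sinusoid near ``locomotion_freq``; during each planted
    freeze (recovered from that foot's probability trace at the 0.7
    threshold) it carries the trembling complex described in the module
    docstring; sedentary stretches carry sensor noise only.
    """
    if not config.emit_raw_imu:
        raise ConfigError("emit_raw_imu", "must be set to synthesise raw channels")
    fs = session.sampling_rate
    n = session.n_samples
    t = session.left.times()
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 17])
    raw = {}
    for foot in ("left", "right"):
        trace = session.left if foot == "left" else session.right
        freezes = detect_events(trace, threshold=_EVENT_THRESHOLD, merge_gap=0.0)
        freeze_ind = np.zeros(n, dtype=bool)
        for iv in freezes:
            i0 = max(0, int(round((iv.start - session.start_time) * fs)))
            i1 = min(n, int(round((iv.end - session.start_time) * fs)))
            freeze_ind[i0:i1] = True
        walk_gate = _smooth_gate(session.active_mask & ~freeze_ind, fs)
        phase = rng.uniform(0, 2 * np.pi)
        vertical = config.loco_amp * walk_gate * np.sin(2 * np.pi * config.locomotion_freq * t + phase)
        lateral = 0.3 * config.loco_amp * walk_gate * np.sin(
            2 * np.pi * config.locomotion_freq * t + phase + 0.8
        )
        for iv in freezes:
            i0 = max(0, int(round((iv.start - session.start_time) * fs)))
            i1 = min(n, int(round((iv.end - session.start_time) * fs)))
            ind = np.zeros(n, dtype=bool)
            ind[i0:i1] = True
            gate = _smooth_gate(ind, fs)
            f0 = float(rng.uniform(*config.tremble_band))
            fc = float(rng.uniform(*config.impact_carrier_band))
            scale = float(rng.lognormal(mean=0.0, sigma=config.amp_jitter_sd))
            psi, chi = rng.uniform(0, 2 * np.pi, size=2)
            direct = config.tremble_amp * scale * np.sin(2 * np.pi * f0 * t + psi)
            am = 0.5 + 0.5 * np.sin(2 * np.pi * f0 * t + chi)
            carrier = config.impact_amp * scale * am * np.sin(2 * np.pi * fc * t)
            f_sh = float(rng.uniform(0.9, 1.4))
            shuffle = config.shuffle_factor * config.loco_amp * np.sin(2 * np.pi * f_sh * t)
            vertical = vertical + gate * (direct + carrier + shuffle)
        acc = np.column_stack(
            [
                lateral + rng.normal(0, config.noise_sd, n),
                rng.normal(0, config.noise_sd, n),
                1.0 + vertical + rng.normal(0, config.noise_sd, n),
            ]
        )
        raw[foot] = acc
    return SessionRecording(
        left=session.left,
        right=session.right,
        active_mask=session.active_mask,
        segments=session.segments,
        raw_imu=raw,
    )
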