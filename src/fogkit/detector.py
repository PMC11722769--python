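"""Detector contract and a spectral-ratio surrogate detector.

The pipeline only requires a *detector*: a callable mapping a session
with raw per-foot acceleration to per-foot freeze-probability traces on
the same sample grid. The surrogate shipped here is a deliberately
simple spectral detector built for testing the pipeline end-to-end; it
makes no claim of equivalence to any published freeze-probability
algorithm.

How it works, per foot and per sliding window:

* locomotion power ``P_l``: band power of the acceleration magnitude in
  the locomotion band (0.5-3 Hz);
* freeze power ``P_f``: band power of the magnitude in the freeze band
  (3-8 Hz) *plus* band power of the rectified high-passed magnitude (its
  envelope) in the same band. The envelope term demodulates a trembling
  rhythm that rides on higher-frequency shuffle-impact transients
  (13-19 Hz carriers), which is how festination shows up in foot-worn
  accelerometers;
* the ratio ``P_f / (P_f + P_l + eps)`` is mapped through a logistic to
  [0, 1].

The envelope term is what makes the surrogate rate-sensitive in the way
the sampling-rate study measures: down-sampling to 30 Hz (Nyquist 15 Hz)
strips the 13-19 Hz carriers, the demodulated trembling rhythm vanishes,
and freezes whose direct 3-8 Hz component is weak drop below the event
threshold. At 60 Hz the carriers survive and output matches 100 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import signal as sig

from .core import ProbabilityTrace, SessionRecording

__all__ = [
    "DetectorSpec",
    "surrogate_probability",
    "make_surrogate_detector",
    "planted_probability_detector",
    "register_detector",
    "get_detector",
    "available_detectors",
]


@dataclass(frozen=True)
class DetectorSpec:
    name: str = "spectral-envelope-surrogate"
    window_s: float = 2.0
    step_s: float = 0.1
    freeze_band: tuple = (3.0, 8.0)
    locomotion_band: tuple = (0.5, 3.0)
    logistic_midpoint: float = 0.5
    logistic_slope: float = 10.0
    power_floor: float = 0.004  # absolute band-power floor (g^2 units)

    def __post_init__(self):
        lo_l, hi_l = self.locomotion_band
        lo_f, hi_f = self.freeze_band
        if not (0 < lo_l < hi_l and 0 < lo_f < hi_f):
            raise ValueError("bands must be positive, increasing (lo, hi) pairs")
        if hi_l > lo_f:
            raise ValueError("locomotion and freeze bands must not overlap")
        if self.window_s <= self.step_s:
            raise ValueError("window_s must exceed step_s")
        if self.power_floor < 0:
            raise ValueError("power_floor must be non-negative")


def _band_power_frames(
    frames: np.ndarray, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Mean PSD-style band power per frame (Hann-tapered periodogram)."""
    w = np.hanning(frames.shape[1])
    spec = np.fft.rfft(frames * w, axis=1)
    freqs = np.fft.rfftfreq(frames.shape[1], d=1.0 / fs)
    psd = (np.abs(spec) ** 2) / (fs * np.sum(w**2))
    sel = (freqs >= band[0]) & (freqs < band[1])
    df = freqs[1] - freqs[0]
    return psd[:, sel].sum(axis=1) * df


def surrogate_probability(
    session: SessionRecording, spec: DetectorSpec | None = None
) -> tuple[ProbabilityTrace, ProbabilityTrace]:
    """Per-foot freeze probabilities from the raw surrogate IMU channels.

    Deterministic in its input; output values always lie in [0, 1] and
    sit on the session's sample grid (window-center values are linearly
    interpolated between steps and held at the edges).
    """
    if spec is None:
        spec = DetectorSpec()
    if session.raw_imu is None:
        raise ValueError("session carries no raw IMU channels; run synthesize_raw_imu first")
    fs = session.sampling_rate
    n = session.n_samples
    win = int(round(spec.window_s * fs))
    step = max(1, int(round(spec.step_s * fs)))
    if n < win:
        raise ValueError(
            f"session ({n} samples) is shorter than the analysis window ({win} samples)"
        )
    # high-pass above the locomotion band for the envelope (demodulation) path
    sos = sig.butter(4, spec.freeze_band[0], btype="highpass", fs=fs, output="sos")
    times = session.left.times()
    traces = {}
    for foot in ("left", "right"):
        acc = session.raw_imu[foot]
        mag = np.linalg.norm(acc, axis=1)
        mag = mag - float(np.mean(mag))
        env = np.abs(sig.sosfiltfilt(sos, mag))
        env = env - float(np.mean(env))
        mag_frames = np.lib.stride_tricks.sliding_window_view(mag, win)[::step]
        env_frames = np.lib.stride_tricks.sliding_window_view(env, win)[::step]
        p_loco = _band_power_frames(mag_frames, fs, spec.locomotion_band)
        p_freeze = _band_power_frames(mag_frames, fs, spec.freeze_band)
        p_freeze = p_freeze + _band_power_frames(env_frames, fs, spec.freeze_band)
        ratio = p_freeze / (p_freeze + p_loco + spec.power_floor)
        prob = 1.0 / (1.0 + np.exp(-spec.logistic_slope * (ratio - spec.logistic_midpoint)))
        centers = session.start_time + (np.arange(len(prob)) * step + win / 2.0) / fs
        values = np.interp(times, centers, prob)
        traces[foot] = ProbabilityTrace(
            np.clip(values, 0.0, 1.0), fs, start_time=session.start_time, foot=foot
        )
    return traces["left"], traces["right"]


def make_surrogate_detector(
    spec: DetectorSpec | None = None,
) -> Callable[[SessionRecording], tuple[ProbabilityTrace, ProbabilityTrace]]:
    """Bind a DetectorSpec into a session -> (left, right) callable."""

    def detector(session: SessionRecording):
        return surrogate_probability(session, spec)

    return detector


def planted_probability_detector(
    session: SessionRecording,
) -> tuple[ProbabilityTrace, ProbabilityTrace]:
    """An "ideal" detector returning the session's stored probability traces."""
    return session.left, session.right


_REGISTRY: dict[str, Callable] = {
    "surrogate": make_surrogate_detector(),
    "planted": planted_probability_detector,
}


def register_detector(name: str, detector: Callable) -> None:
    """Register an external detector (e.g. one reading precomputed CSV output)."""
    _REGISTRY[name] = detector


def get_detector(name: str) -> Callable:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown detector {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def available_detectors() -> list[str]:
    return sorted(_REGISTRY)
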