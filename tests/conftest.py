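import numpy as np
import pytest

from fogkit import SyntheticConfig, generate_session


def make_trace_config(**overrides) -> SyntheticConfig:
    """A clean-ramp config: no jitter, no false rises, quiet baseline."""
    base = dict(
        seed=7,
        annotation_jitter_sd=0.0,
        false_rise_rate=0.0,
        baseline_mean=0.05,
        baseline_sd=0.02,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def clean_session():
    """One deterministic session with exactly five planted freezes."""
    cfg = make_trace_config(
        freeze_counts={"GOT": 2, "Hallway": 1, "Community": 2},
    )
    session, truth = generate_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def imu_session():
    """A session with surrogate raw IMU channels and a few freezes."""
    cfg = make_trace_config(
        seed=21,
        emit_raw_imu=True,
        freeze_counts={"GOT": 1, "360": 1, "Community": 2},
    )
    session, truth = generate_session(cfg)
    return cfg, session, truth


def sine_amplitude(x: np.ndarray, fs: float, freq: float, trim_s: float = 0.5) -> float:
    """Least-squares amplitude of a sinusoid at ``freq`` (edges trimmed)."""
    k = int(trim_s * fs)
    x = np.asarray(x, float)[k : len(x) - k]
    t = np.arange(len(x)) / fs
    c = 2.0 / len(x)
    return float(np.hypot(c * np.sum(x * np.sin(2 * np.pi * freq * t)),
                          c * np.sum(x * np.cos(2 * np.pi * freq * t))))
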