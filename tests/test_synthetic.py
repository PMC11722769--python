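"""Synthetic session generator: determinism, planted truth, raw IMU."""

import dataclasses

import numpy as np
import pytest

from fogkit import (
    ConfigError,
    SyntheticConfig,
    combine_feet,
    detect_events,
    generate_cohort,
    generate_session,
    synthesize_raw_imu,
)
from conftest import make_trace_config


def band_power(x, fs, lo, hi):
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    psd = np.abs(np.fft.rfft(x - np.mean(x))) ** 2
    return float(psd[(freqs >= lo) & (freqs < hi)].sum())


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(sampling_rate=0), "sampling_rate"),
            (dict(ramp_start_prob=0.5, ramp_peak_prob=0.4), "ramp_start_prob"),
            (dict(ramp_peak_prob=0.65), "ramp_peak_prob"),
            (dict(false_rise_peak=0.8), "false_rise_peak"),
            (dict(freeze_hold=-1.0), "freeze_hold"),
            (dict(annotation_jitter_sd=-0.1), "annotation_jitter_sd"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            SyntheticConfig(**kwargs)


class TestGenerateSession:
    def test_nothing_planted_stays_quiet(self):
        cfg = make_trace_config(freezes_per_task=0.0)
        session, truth = generate_session(cfg)
        assert len(truth) == 0
        combined = combine_feet(session.left, session.right)
        assert combined.values.max() < 0.7
        # baseline stays far below the smallest prediction threshold
        assert combined.values.max() < 0.2 - 2 * cfg.baseline_sd

    def test_seeded_determinism(self):
        cfg = make_trace_config(seed=42, emit_raw_imu=True)
        s1, t1 = generate_session(cfg)
        s2, t2 = generate_session(cfg)
        np.testing.assert_array_equal(s1.left.values, s2.left.values)
        np.testing.assert_array_equal(s1.right.values, s2.right.values)
        np.testing.assert_array_equal(s1.raw_imu["left"], s2.raw_imu["left"])
        assert t1.intervals == t2.intervals

    def test_planted_freezes_match_detection_within_one_sample(self, clean_session):
        cfg, session, truth = clean_session
        combined = combine_feet(session.left, session.right)
        events = detect_events(combined, 0.7, 2.0)
        assert len(events) == len(truth) == 5
        dt = 1.0 / cfg.sampling_rate
        for ev, ann in zip(events, truth):
            assert abs(ev.start - ann.start) <= dt
            assert abs(ev.end - ann.end) <= dt

    def test_ramp_is_strictly_increasing_before_onset(self, clean_session):
        cfg, session, truth = clean_session
        fs = cfg.sampling_rate
        for ann in truth:
            foot = max(
                (session.left, session.right),
                key=lambda tr: tr.values[int(ann.start * fs) + 2],
            )
            onset_i = int(np.ceil(ann.start * fs))
            seg = foot.values[onset_i - int(1.5 * fs) : onset_i]
            assert np.all(np.diff(seg) > 0)

    def test_mask_false_during_sedentary_tasks(self):
        cfg = make_trace_config()
        session, _ = generate_session(cfg)
        sitting = next(s for s in session.segments if s.name == "Sitting")
        centers = (np.arange(session.n_samples) + 0.5) / cfg.sampling_rate
        inside = (centers >= sitting.start) & (centers < sitting.end)
        assert not session.active_mask[inside].any()
        assert session.active_mask[~inside].all()

    def test_jitter_never_inverts_or_overlaps(self):
        cfg = make_trace_config(seed=77, annotation_jitter_sd=0.5, freezes_per_task=3.0)
        _, truth = generate_session(cfg)
        assert len(truth) > 3
        for a, b in zip(truth.intervals, truth.intervals[1:]):
            assert a.start < a.end <= b.start < b.end


class TestGenerateCohort:
    def test_single_participant_equals_derived_seed_session(self):
        cfg = make_trace_config()
        (session, truth), = generate_cohort(cfg, 1, seed=9)
        state = np.random.SeedSequence(9).generate_state(2)
        expected, _ = generate_session(
            dataclasses.replace(cfg, seed=int(state[0]) & 0x7FFFFFFF)
        )
        np.testing.assert_array_equal(session.left.values, expected.left.values)

    def test_participants_are_pairwise_different(self):
        cfg = make_trace_config(freezes_per_task=1.0)
        cohort = generate_cohort(cfg, 5, seed=1)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not np.array_equal(
                    cohort[i][0].left.values, cohort[j][0].left.values
                )

    def test_n_with_fog_controls_nonempty_annotations(self):
        cfg = make_trace_config(freeze_counts={"GOT": 1, "Hallway": 1})
        cohort = generate_cohort(cfg, 20, seed=4, n_with_fog=14)
        nonempty = sum(1 for _, truth in cohort if len(truth) > 0)
        assert nonempty == 14

    def test_invalid_counts_rejected(self):
        cfg = make_trace_config()
        with pytest.raises(ValueError):
            generate_cohort(cfg, 0)
        with pytest.raises(ValueError):
            generate_cohort(cfg, 3, n_with_fog=5)


class TestSynthesizeRawImu:
    def test_requires_flag(self):
        cfg = make_trace_config(emit_raw_imu=False)
        session, _ = generate_session(cfg)
        with pytest.raises(ConfigError, match="emit_raw_imu"):
            synthesize_raw_imu(session, cfg)

    def test_sedentary_only_session_is_noise_floor(self):
        cfg = make_trace_config(
            seed=3,
            emit_raw_imu=True,
            task_plan=(("Sitting", 60.0, True),),
            freezes_per_task=0.0,
        )
        session, _ = generate_session(cfg)
        for foot in ("left", "right"):
            mag = np.linalg.norm(session.raw_imu[foot], axis=1)
            # nothing but sensor noise: variance ~ 3 axes x noise_sd^2
            assert np.var(mag - mag.mean()) < 4 * cfg.noise_sd**2

    def test_band_power_contrast_between_freeze_and_walking(self, imu_session):
        cfg, session, truth = imu_session
        fs = cfg.sampling_rate
        ann = truth.intervals[0]
        foot = max(
            ("left", "right"),
            key=lambda f: getattr(session, f).values[int(ann.start * fs) + 2],
        )
        mag = np.linalg.norm(session.raw_imu[foot], axis=1)
        i0, i1 = int(ann.start * fs) + int(0.5 * fs), int(ann.end * fs) - int(0.5 * fs)
        freeze_seg = mag[i0:i1]
        assert band_power(freeze_seg, fs, 3, 8) > band_power(freeze_seg, fs, 0.5, 3)
        # a clean walking stretch: first seconds of the session, away from events
        walk_seg = mag[int(2 * fs) : int(8 * fs)]
        assert band_power(walk_seg, fs, 0.5, 3) > band_power(walk_seg, fs, 3, 8)

    def test_same_seed_identical_channels(self):
        cfg = make_trace_config(seed=10, emit_raw_imu=True)
        s1, _ = generate_session(cfg)
        s2, _ = generate_session(cfg)
        np.testing.assert_array_equal(s1.raw_imu["right"], s2.raw_imu["right"])
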