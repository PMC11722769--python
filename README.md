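# fogkit

Analysis tools for **freezing of gait (FOG)** detection and prediction from
foot-worn sensor data in Parkinson disease research.

Wearable-sensor FOG algorithms emit, per foot, a probability trace
p(t) ∈ [0, 1] that a freeze is occurring. `fogkit` implements everything a
study does *around* such a trace:

* **Event extraction** — an FOG event is any time either foot's probability
  exceeds 0.7 (pointwise either-foot maximum); events separated by less than
  2 s are merged into one episode.
* **Time-based scoring** — every active (non-sedentary) sample is classified
  TP/FP/TN/FN against video-style ground-truth intervals;
  accuracy = 100 · (TP + TN) / analysed time, and
  %WTSF = 100 · freezing time / active walking time.
* **Pre-onset prediction** — a freeze counts as predicted when p(t) rises
  monotonically above a sub-event threshold τ ∈ {0.2, 0.25, …, 0.5} within
  the 3 s before the detected onset and at least 1 s ahead of it; the sweep
  reports per-threshold true and false prediction rates, averaged across
  participants.
* **Task potency** — per provocation task (hallway pivoting, go-outside-and-
  turn, 360° turning, each single/dual-task, plus simulated daily
  activities): how many participants froze and how much freezing time the
  task elicited.
* **Sampling-rate study** — raw signals are converted between rates with a
  21-point Hanning-windowed sinc filter (cutoff at half the lower rate), a
  detector recomputes probabilities at 100/60/30 Hz, and per-rate accuracies
  are compared with a one-way ANOVA and Tukey HSD (studentized range,
  Tukey–Kramer for unbalanced groups).
* **Synthetic cohorts** — a seeded generator plants freezes as closed-form
  probability ramps (baseline 0.05 → peak 0.95 over 3 s) with matching
  ground truth, sub-0.7 false rises, rater-style annotation jitter, and
  optional surrogate tri-axial acceleration so the whole chain — including a
  spectral surrogate detector — runs end-to-end without any private
  recordings.

The package is a library first: import it, or start from the narrative
scripts in `examples/`. A thin CLI (`fog simulate|detect|predict|potency|
resample-study|run`) wraps the same functions for shell use.

## Worked example

```python
from fogkit import (SyntheticConfig, generate_session, combine_feet,
                    detect_events, classify_time, accuracy, wtsf)

session, truth = generate_session(SyntheticConfig(seed=42))
events = detect_events(combine_feet(session.left, session.right),
                       threshold=0.7, merge_gap=2.0)
conf = classify_time(events, truth, session.active_mask, session.sampling_rate)
print(len(events), round(accuracy(conf), 1),
      round(wtsf(events, session.active_mask, session.sampling_rate), 1))
```

prints `10 99.8 5.7`: the ten planted freezes are all recovered, 99.8% of
active time is classified correctly (the 0.2% being rater-jitter disagreement
at event edges), and 5.7% of walking time was spent frozen.

Running `python examples/05_sampling_rate_study.py` (13 synthetic
participants, surrogate detector) prints

```
  100 Hz: accuracy  99.1% (SD 0.3), %WTSF  7.3%
   60 Hz: accuracy  99.1% (SD 0.3), %WTSF  7.3%
   30 Hz: accuracy  97.3% (SD 1.0), %WTSF  5.5%
ANOVA: F(2, 36) = 32.50, p = 8.6e-09
  Tukey 100 Hz vs 60 Hz: diff  -0.03 pts, p = 0.991
  Tukey 100 Hz vs 30 Hz: diff  +1.78 pts, p = 1.24e-07 *
  Tukey 60 Hz vs 30 Hz: diff  +1.81 pts, p = 8.53e-08 *
```

— detection is unchanged at 60 Hz but significantly worse at 30 Hz, because
the 30 Hz anti-alias filter strips the 13–19 Hz shuffle-impact content the
surrogate detector demodulates (see `docs/methods.md`).

## Conventions

All intervals are half-open `[start, end)` in seconds; sample `i` covers
`[i/fs, (i+1)/fs)` and its center decides interval membership; indexing is
0-based. "Above a threshold" is strict (`>`), and event merging applies to
gaps strictly below the merge gap.
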