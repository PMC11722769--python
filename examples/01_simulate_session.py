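"""Generate one synthetic lab session and inspect what was planted.

A session is a sequence of freeze-provocation tasks and simulated daily
activities. Each planted freeze is a monotonic probability ramp into a
supra-0.7 plateau on one foot; the ground-truth annotations record the
[onset, offset) of every planted freeze the way a video rater would.
"""

from fogkit import SyntheticConfig, generate_session

config = SyntheticConfig(seed=42, freezes_per_task=1.5, emit_raw_imu=False)
session, truth = generate_session(config)

print(f"session: {session.duration:.0f} s at {session.sampling_rate:g} Hz, "
      f"{session.active_mask.mean() * 100:.0f}% active time")
print(f"tasks: {', '.join(s.name for s in session.segments)}")
print(f"planted freezes (ground truth): {len(truth)}")
for iv in truth:
    task = next(s.name for s in session.segments if s.start <= iv.start < s.end)
    print(f"  [{iv.start:7.2f}, {iv.end:7.2f}) s  during {task}")
print("Each interval is where the freeze probability exceeded 0.7; the "
      "pre-onset ramp before each onset is what the prediction rule exploits.")
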