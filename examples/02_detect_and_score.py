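"""Extract freeze events from the probability traces and score them.

Detection applies the either-foot rule (pointwise maximum of the two
per-foot traces), thresholds at 0.7, and merges events separated by less
than 2 s. Scoring is time-based: every active sample is classified
TP/FP/TN/FN against the ground truth, giving a detection accuracy and
the percent of walking time spent freezing (%WTSF).
"""

from fogkit import (
    SyntheticConfig,
    accuracy,
    classify_time,
    combine_feet,
    detect_events,
    generate_session,
    wtsf,
)

session, truth = generate_session(SyntheticConfig(seed=42))
combined = combine_feet(session.left, session.right)
events = detect_events(combined, threshold=0.7, merge_gap=2.0)

conf = classify_time(events, truth, session.active_mask, session.sampling_rate)
print(f"detected {len(events)} events vs {len(truth)} annotated freezes")
print(f"TP {conf.tp_s:.1f} s, FP {conf.fp_s:.1f} s, FN {conf.fn_s:.1f} s, "
      f"TN {conf.tn_s:.1f} s over {conf.analyzed_s:.0f} s of active time")
print(f"accuracy = 100 x (TP + TN) / total = {accuracy(conf):.1f}%")
print(f"%WTSF = {wtsf(events, session.active_mask, session.sampling_rate):.1f}% "
      "(share of active walking time spent freezing)")
print("Accuracy is high even with rater-style annotation jitter because "
      "agreement is measured in time, not in event counts.")
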