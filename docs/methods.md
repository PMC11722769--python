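# Methods

This note documents the models, procedures and numerical choices behind
`fogkit`, and what its synthetic cohorts do and do not establish about real
wearable recordings.

## Event model and time accounting

A freeze-probability trace is a uniformly sampled series p(t) ∈ [0, 1] per
foot. The event rule is deliberately literal:

* the two feet are combined by a pointwise maximum ("either foot above
  threshold");
* "above 0.7" is strict — a sample equal to the threshold is non-freeze;
* maximal supra-threshold runs become half-open intervals on the sample
  grid, and consecutive intervals whose gap is *strictly* less than the
  2 s merge gap are merged transitively, left to right, to a fixed point.

Scoring is done in time, not in event counts. Ground-truth intervals are
rasterised onto the sample grid by sample-center containment, and every
active sample is classified TP/FP/TN/FN; sedentary samples (the hip-sensor
mask) are excluded entirely. Half-open intervals on the grid make the
accounting exact: tp + fp + tn + fn equals the analysed time identically,
and swapping the algorithm and truth rasters swaps FP and FN.

Accuracy is 100·(TP + TN)/analysed time. Per-task and per-category figures
restrict the classification to each task segment's active samples; category
and overall aggregates **pool confusion times** rather than averaging task
percentages, so the overall value is exactly the duration-weighted mean of
the per-task values. (Averaging task percentages would weight a 30 s task
like a 3 min one; the pooled definition follows directly from the
time-ratio form of accuracy.) %WTSF divides freezing time within active
samples by total active time.

## Prediction rule

A crossing of threshold τ is the first sample strictly above τ within an
excursion, preceded by a non-decreasing run lasting at least `min_run_s`
(default 0.25 s). "Monotonic" is read as non-decreasing because plateaus of
identical consecutive samples are ubiquitous in quantised probability
traces; the run length and strictness are configurable. A trace that starts
above τ has not "risen from below" and yields no crossing until it returns
to or below τ; counted crossings are separated by a refractory interval
(default 1 s).

An event counts as predicted iff a crossing lies in
[onset − 3 s, onset − `lead_min_s`], with the onset taken from the
*detected* event (the first 0.7-crossing), not from the video annotation —
prediction is about warning ahead of what the device itself will flag.
`lead_min_s` defaults to 1 s but may be set to 0 to count any pre-onset
rise. A crossing is a false alarm iff no onset follows within
`fp_horizon_s` (default 3 s, symmetric with the pre-onset window — a
design choice, since no horizon is implied by the rule itself). Crossings
inside an ongoing event are discarded. Per participant, the true rate is
n_predicted/n_events and the false rate n_false/n_crossings; participants
with empty denominators are excluded from the corresponding cohort average
(reported absent, not as 0).

With the generator's piecewise-linear ramp (0.05 → 0.95 over 3 s, slope
0.3/s) crossing times are closed-form: τ = 0.2 is crossed 1.67 s before the
0.7 onset (predicted at 1 s minimum lead) and τ = 0.5 only 0.67 s before
(never predicted). These closed forms anchor the prediction tests, and they
also imply the sweep's true-rate column is non-increasing in τ for any
cohort whose pre-onset rises start below the smallest threshold.

## Sampling-rate conversion

The converter is a 21-point Hanning-windowed sinc interpolator with the
anti-alias cutoff at half the lower of the two rates, evaluated directly at
each output position; the input is reflect-padded and per-output weights
are normalised to sum to one (DC is preserved exactly, and equal rates give
the identity). Masks and annotations are never filtered — the mask maps by
nearest sample, annotations stay in seconds.

A 21-tap kernel has a wide transition band (≈ 3.1/21 of the input rate).
At 100 → 30 Hz (cutoff 15 Hz) attenuation therefore starts near 8 Hz:
measured amplitude gains are ≈ 1.00 at 2–8 Hz, 0.80 at 12 Hz, 0.50 at
15 Hz, 0.20 at 18 Hz and 0.07 at 20 Hz, while 100 → 60 Hz is flat (±0.5%)
up to ≈ 22 Hz. Filter transients are confined to the padded edges and are
not trimmed before scoring.

## Surrogate detector and why 30 Hz degrades

The detector contract is a callable mapping a session's raw per-foot
acceleration to per-foot probability traces; external detectors can be
plugged into the registry. The shipped surrogate is a windowed spectral
ratio (2 s windows, 0.1 s step): locomotion-band power (0.5–3 Hz) against
freeze-band power (3–8 Hz) *plus* the 3–8 Hz band power of the rectified
high-passed magnitude — an envelope term that demodulates a trembling
rhythm riding on higher-frequency transients. The ratio
P_f/(P_f + P_l + ε) goes through a logistic (midpoint 0.5, slope 10);
ε = 0.004 g² keeps quiet (sedentary) windows near zero probability. It is
a surrogate by construction: it claims no equivalence to any published
freeze-probability algorithm, only the interface and a documented
rate-sensitivity.

The synthetic trembling complex gives that sensitivity a physical reading.
During each planted freeze the vertical axis carries a direct 3–8 Hz
component, a residual sub-2 Hz shuffle, and shuffle-impact transients
synthesised as a 13–19 Hz carrier amplitude-modulated at the trembling
rate — sharp, repetitive micro-impacts whose energy sits near the 15 Hz
Nyquist of a 30 Hz recording. At 100 and 60 Hz the carriers pass the
converter intact and the envelope term dominates the freeze-band power; at
30 Hz the filter's transition band reduces them to 0.2–0.8 of their
amplitude, the demodulated rhythm collapses, and freezes whose direct
3–8 Hz component is weak drop below the 0.7 event threshold. The result,
on seeded 13-person cohorts, is the pattern the study design probes:
accuracy(100) ≈ accuracy(60) > accuracy(30), with Tukey flagging exactly
the two 30 Hz comparisons. The surrogate's failure mode at 30 Hz is missed
freezes (so %WTSF falls); a detector whose low-rate failure mode is false
alarms would instead inflate %WTSF while accuracy still drops.

## Synthetic data: what it emulates and what it does not

One session is an ordered task plan (defaults: the six walking
provocations at 60 s each, vacuuming and dishwasher at 90 s, sitting
120 s — sedentary, masked out — and 180 s of building navigation; 840 s
total). Freeze counts per non-sedentary task are Poisson (mean 1.5) with
an exact-count override for tests; patterns are placed uniformly at random
with ≥ 4 s separation so that 2 s merging can never fuse planted events.
Each freeze lands on one randomly chosen foot; the other stays at baseline
(this exercises the either-foot rule). Baseline noise is Gaussian
(mean 0.05, sd 0.02) truncated at ±4 sd and clipped to [0, 1], so baseline
samples never reach the smallest prediction threshold. Annotation jitter
(sd 0.1 s, truncated at ±2 sd and clamped) mimics rater onset/offset noise
without inverting or overlapping intervals. False rises reuse the ramp
shape with a 0.6 peak and are kept ≥ 6.5 s clear of true events so their
classification is unambiguous. Raw-IMU amplitudes (g units, gravity on the
vertical axis): locomotion 0.5 at 2 Hz while walking, direct tremble 0.2,
impact carrier 1.2, shuffle fraction 0.25, per-event lognormal amplitude
scatter (σ = 0.25), sensor noise 0.05; bursts are gated with 0.3 s Hanning
ramps to avoid spectral splatter. These values were chosen once, as a
plausible operating point for a foot-worn accelerometer, and give ~99%
surrogate accuracy at 100 Hz with a 2 point drop at 30 Hz.

The generator reproduces the *statistical structure the analyses assume* —
ramp-shaped pre-onset probability, supra-0.7 plateaus, either-foot events,
sedentary masking, band-limited walking vs trembling — not biomechanics.
Real pFOG-style traces have autocorrelated baseline wander, non-ramp
onsets, medication- and severity-dependent dynamics, and rater
disagreement far richer than Gaussian jitter. Passing tests therefore
establish that the *analysis chain* is correct and that the documented
rate-degradation mechanism behaves as designed; they say nothing about how
any particular detector performs on patients.

## Statistics

Sums of squares, F = MSB/MSW and the Tukey–Kramer statistic
q = |m_a − m_b| / √(MSW/2 · (1/n_a + 1/n_b)) are computed directly;
p-values come from scipy's F and studentized-range distributions (the
latter evaluated numerically, not from printed tables). Degenerate input
(all observations identical) returns F = 0, p = 1 by convention. The rate
comparison treats rates as independent groups even though the design is
repeated-measures — that is the comparison the pipeline is specified to
run, and it is conservative here; normality companions (bias-corrected
sample skewness and excess kurtosis) are provided for the usual visual
checks. The sweep and study runners report mean (SD) across participants.

## Problem sizes and determinism

Default test and acceptance runs use 840 s sessions at 100 Hz, cohorts of
4–13 participants for the sampling study and 19 for potency; these sizes
make every property measurable with comfortable margins while the whole
suite runs in well under a minute. Every stochastic component is a pure
function of (config, seed): cohorts derive per-participant seeds through a
`SeedSequence`, the raw-IMU stream is salted independently of the
probability stream, and report writers use fixed 6-decimal formatting so
identical configurations produce byte-identical bundles.

## Known limitations

* The surrogate detector's probability traces have ~1 s of boundary blur
  from the 2 s analysis window; event onsets recovered from raw signals
  are correspondingly softer than planted onsets.
* Up-sampling (e.g. to 128 Hz) uses the same 21-tap kernel; no claim is
  made that any particular device's firmware resamples the same way.
* Potency uses ground-truth annotations only; sensor-based potency would
  confound task difficulty with detector bias.
* Unsegmented active samples are excluded from per-task metrics (with a
  warning) rather than pooled into a pseudo-task.
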