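# Methods

This note defines every measurement the package computes, the defaults it
ships with, the models behind the synthetic generators, and the numerical
choices and known biases of each estimator. All intervals are half-open in
seconds; all defaults are exposed in `thermoneuro.config.RunConfig` and
logged in CLI run manifests.

## 1. Fiber photometry

**Model.** A session pairs a calcium-dependent 465 nm channel with a 405 nm
isosbestic control sampled at 1017 Hz. Both channels share slow
photobleaching and multiplicative motion artifacts; calcium transients
appear only in the signal channel.

**Correction and ΔF/F.** The control channel is fitted with a least-squares
polynomial in time (default degree 2); the fitted curve F̂405 is subtracted
from the signal channel and ΔF/F = (F465 − F̂405)/F̂405. Using the smooth
fit (not the raw 405 samples) as the denominator keeps control-channel
noise out of the ratio. When the two channels have different gains, ΔF/F
carries a constant offset; all downstream statistics are relative to the
baseline mean, so the offset is inert.

**Baseline.** μ and σ come from a random contiguous window of 5–10 s
(duration and position drawn uniformly from a seeded generator). Default
estimators in `analyze_session` are the window median and the
normal-consistent scaled MAD (1.4826 × MAD): with spontaneous activity at
0.5 events/s a 5–10 s window is expected to contain 2–5 transients, which
inflate a plain mean/SD and with it the μ+3σ threshold. Plain mean/SD is
available (`robust=False`, the `select_baseline` default) and agrees with
the robust pair on transient-free Gaussian baselines.

**Transient detection.** A transient is a maximal run of samples strictly
above μ + kσ (default k = 3; a peak exactly at threshold is not an event).
Runs shorter than `min_duration_samples` (default 5 ≈ 5 ms at 1017 Hz) are
discarded first; surviving runs separated by less than `merge_gap_s`
(default 0.1 s) are merged. Rationale, assuming broadband baseline noise: a
false event requires ~5 consecutive independent samples above 3σ,
probability ≈ (1.35×10⁻³)⁴ per crossing — effectively zero per 2-minute
session — while a transient of 5σ peak amplitude with a 100 ms decay stays
above 3σ for ~50–60 ms and therefore always contributes at least one
qualifying run. Event time is the peak sample; amplitude is peak ΔF/F
minus μ; frequency is events per second of trace duration.

**Known biases** (measured on the synthetic generator, 120 s sessions,
5σ amplitude, 20 seeds per rate): detected frequency runs ~2% low at
0.1 events/s, ~5% low at 0.3, and ~10% low at 0.5. The dominant term is
merge dead-time: two true events closer than ≈0.16 s (merge gap plus
supra-threshold duration) count once. Reported amplitudes are biased high
by roughly the expected maximum of the baseline noise over the
supra-threshold run (~2–2.5 σ_noise), because the peak sample is an order
statistic.

**Z-scores and peri-event matrices.** Session z-scores use the whole-trace
mean and SD. Peri-event matrices stack [−pre, +post) windows of the
z-scored trace around event onsets; rows that would cross the trace bounds
are dropped and counted.

## 2. Behavior

**Kinematics.** Positions are smoothed with a centered moving average
(default 0.2 s) whose window shrinks symmetrically at the edges — exact for
affine trajectories at every sample, unlike padded filters — and speed is
the central finite difference of the smoothed path. Path length is the
polyline length of the smoothed path.

**Zones.** Arena zones are shapely polygons (`thermoneuro.arenas` builds
the elevated plus maze with 250 × 50 mm arms and a 50 mm centre, an open
field, and chambered arenas). Frames are assigned by point-in-polygon;
boundary points go to the first zone in insertion order, points outside all
zones to the nearest zone (counted as warnings). Occupancy time is frame
count over fps, so zone times sum exactly to session duration. Entries are
debounced: a visit counts only when it lasts ≥ 3 frames.

**Fast running.** Maximal runs of speed strictly exceeding 400 mm/s, merged
across gaps < 0.2 s, kept when ≥ 0.25 s. The threshold comparison is
strict: a speed of exactly 400 mm/s is not fast running.

**Centre-pause outcomes.** A pause is a centre-zone dwell with speed below
20 mm/s lasting ≥ 0.5 s. The outcome is labelled by the first arm entered
afterwards (`pause_then_return_run`/`_walk` to a closed arm,
`pause_then_exit_open` to an open arm); run vs walk uses the peak speed of
the exit bout against the same 400 mm/s threshold. The movement onset is
refined as the first raw-position sample leaving a 5 mm circle around the
pause centroid, because smoothing otherwise anticipates onsets by ~2
frames.

**Open→closed transitions.** From the debounced visit sequence, an open-arm
visit followed (possibly through the centre) by a closed-arm visit with no
open-arm re-entry is a transition; onset is the last open-arm frame, offset
the first closed-arm frame, run/walk by the bout's peak speed. The
closed-to-open direction is never emitted.

**Preference ratios.** Three-chamber: time(stranger)/time(object);
female-encounter: time(female)/time(male); sucrose: sucrose/(sucrose +
water) volumes. A zero denominator yields NaN with `defined=False`, never
infinity.

**Pupil.** From 30 fps keypoints (two orthogonal pupil point pairs plus
eyelid pair), diameter is the mean of the two pair distances and area the
π/4·d₁·d₂ ellipse. Series are normalized to the pre-light mean and sampled
at 5/15/25 s of the 10 s off / 10 s on / 10 s off cycle. Samples with
likelihood < 0.9 are linearly interpolated when the gap is ≤ 1 s; longer
gaps are an error naming the gap.

## 3. Startle / PPI

**Schedule.** ≥ 20 min baseline, 10 habituation pulses 20 s apart, then a
PPI phase of 5 pulse-only plus 15 prepulse+pulse trials in seeded random
order; the prepulse leads the pulse by 0.5 s; stimuli last 0.2 s.

**Amplitude.** For each body part, the reference is the mean position over
the 100 ms before sound onset; the part's amplitude is its peak distance
from the reference within [onset, onset + 0.2 s) (RMS optional). The trial
amplitude averages the body parts; displacement after the window
contributes nothing.

**Exclusion.** A trial is invalid when mean body-part speed over the 1 s
before the (pre)pulse onset exceeds 50 mm/s — the automated stand-in for
manual rejection of trials contaminated by spontaneous movement.

**PPI ratio.** Mean valid prepulse-trial amplitude divided by mean valid
pulse-only amplitude. The ratio is scale-invariant. With the default
generator jitter the measured ratio is biased < 2% high at ratio 0.25
(the peak-over-window statistic is an order statistic of jittered
displacement, and the bias is proportionally larger for smaller true
amplitudes); the bias vanishes at ratio 1 and with zero jitter.

## 4. Slice electrophysiology

**Spikes and F–I.** Spikes are voltage peaks above 0 mV separated by
≥ 1 ms. The F–I protocol steps 0–100 pA in 10 pA increments; rheobase is
the smallest step evoking ≥ 1 spike (absent when nothing fires).

**AP threshold and half-width.** dV/dt is computed by central differences;
the threshold is the voltage at the start of the contiguous supra-criterion
(≥ 20 V/s) upstroke found scanning backward from the peak, flagged `None`
when the criterion is never reached. The worst-case discretization error is
one sample of voltage change (upstroke slope × dt), so it doubles when the
sampling rate halves. Half-width is the full width at half of the
threshold-to-peak amplitude with linearly interpolated crossings; for a
Gaussian spike shape it matches 2√(2 ln 2)·σ within one sample.

**Passive properties.** From a 50 ms hyperpolarizing step producing a
~5 mV deflection, the onset transient is fitted with
dV(t) = dV∞·(1 − e^(−t/τ)), jointly over dV∞ and τ (the late-step mean
seeds the fit). R = dV∞/ΔI, C = τ/R. The fitted asymptote is used rather
than the late-step mean because a membrane with τ = 20 ms reaches only
~89% of dV∞ within the 50 ms step, which would bias R by ~−10%. The fit is
exact for single-exponential membranes (the generator's model class); real
cells are multi-exponential, for which τ is an effective constant.
Voltage-clamp test pulses are supported with command/current roles swapped.

**Miniature PSCs.** The trace is band-pass filtered (1–2000 Hz, zero
phase) and thresholded at 5 pA in the polarity direction (mEPSC inward at
−70 mV, mIPSC outward at +10 mV). An event is a maximal supra-threshold run
of ≥ 1 ms — an isolated noise excursion cannot hold 5 pA for 10 correlated
samples, while a 20 pA PSC with 8 ms decay stays above for ~9 ms — and runs
separated by < 5 ms merge, so a noisy decay flank cannot double-count.
Amplitude is the raw peak minus the median of the 10 ms before run onset,
as a positive magnitude. Measured biases at 2 Hz / 20 pA: frequency 2–5%
low (Poisson overlap merging), amplitude 5–7% high (peak order statistic
plus overlap summation). Event counts are monotone non-increasing in the
threshold once the threshold exceeds the merge-bound regime; at very low
thresholds merging can join neighbors and reduce the count.

**Connectivity.** Each neuron is classified from its light-evoked currents
at the two holding potentials (−70 mV excitatory, +10 mV inhibitory) as
`both`, `excitatory_only`, `inhibitory_only` or `none`; a missing holding
condition excludes the neuron. Percentages are over responding neurons.

**LTP.** Evoked amplitudes are normalized to the mean over the 10 min
pre-induction baseline (×100%), so the baseline mean is exactly 100% by
construction and the series is scale-invariant; post-induction minute bins
are reported at the 1/10/20/30 min marks.

## 5. Synthetic generators

All generators take a required integer seed and reproduce output
bit-identically. Ground truth lists every injected event or parameter.

* **Photometry** — shared exponential bleach (τ = 600 s) times a
  multiplicative motion random walk (SD 0.2% of baseline) on both channels;
  Poisson transients (double-exponential kernel, 10 ms rise / 100 ms decay,
  consistent with fast indicator kinetics) only in the signal channel;
  per-channel baseline noise that is broadband white Gaussian by default
  (as left by lock-in demodulation) with an optional low-pass. Broadband
  noise is what makes the 5–10 s baseline window a good σ estimator
  (~10⁴ effective samples); strongly low-passed noise leaves the window
  only ~15 effective samples and makes the μ+3σ threshold essentially
  random across seeds.
* **Trajectory** — piecewise-linear paths through the arena with scripted
  events (fast runs, centre pauses with chosen outcomes, open→closed
  transitions) realized geometrically, walking filler between them, and
  Gaussian tracking jitter (0.5 mm) added last; event onsets/offsets are
  computed on the noiseless path.
* **Startle** — body parts resting at fixed positions with tracking jitter;
  at each pulse onset a half-sine displacement impulse of the trial's true
  amplitude, confined to the 200 ms window, along a random per-part
  direction; optional scripted pre-stimulus locomotion to exercise the
  validity flag.
* **Ephys** — a leaky integrate-and-fire neuron solved exactly (piecewise
  exponential segments, analytic threshold-crossing times, stereotyped
  Gaussian spike template over a 3 ms refractory window), so rheobase and
  per-step spike times are closed-form; passive test pulses are exact RC
  responses; minis are Poisson trains of double-exponential PSCs with
  Gaussian amplitudes over Gaussian noise; LTP series are step functions
  with optional multiplicative noise.

**What passing tests do and do not show.** The validation demonstrates that
each estimator recovers the generator's ground truth within stated
tolerances under the generator's assumptions (single-exponential membranes,
stationary Gaussian noise, geometric trajectories, stationary resting
posture). It does not demonstrate robustness to real-data pathologies —
non-stationary noise, optical artifacts correlated with behavior, tracking
identity swaps, electrode drift — and the stated biases (merge dead-time,
order-statistic amplitude inflation) are measured on the generator, not
bounded for arbitrary inputs.

## 6. Statistics

Group comparisons report mean ± SEM per group and delegate hypothesis
testing to scipy (unpaired/paired t, Mann-Whitney U, one-way ANOVA with
Tukey HSD post hoc). The package's contribution is the measures feeding the
tests, not the tests.
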