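"""Slice-electrophysiology feature extraction.

Implements the intrinsic-excitability and synaptic measurements used for
thalamic neurons in the chronic-stress experiments:

* firing-rate (F-I) curves from steady-state current steps (0-100 pA in
  10 pA increments) and the rheobase as the smallest step evoking a spike;
* action-potential threshold as the voltage where the depolarization slope
  first reaches 20 V/s, and half-width as the full width at half of the
  threshold-to-peak amplitude;
* passive properties from a 50 ms / 5 mV hyperpolarizing test pulse from
  -70 mV, with the steady state taken over the last 10 ms of the step,
  the membrane time constant from a single-exponential fit of the onset,
  and capacitance as tau / R;
* miniature postsynaptic current (mEPSC at -70 mV, mIPSC at +10 mV hold)
  detection by threshold crossing on a band-passed trace;
* connectivity classification of neurons probed at both holding potentials;
* LTP timecourses normalized to percent of the pre-induction baseline mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

__all__ = [
    "EphysSweep",
    "APFeatures",
    "MiniEventSet",
    "PlasticityTimecourse",
    "ConnectivityCall",
    "FI_STEPS_PA",
    "detect_spikes",
    "fi_curve",
    "rheobase",
    "ap_threshold",
    "ap_half_width",
    "passive_props",
    "detect_minis",
    "classify_connectivity",
    "ltp_normalize",
]

#: Current-step grid of the firing-rate protocol, pA.
FI_STEPS_PA = tuple(range(0, 101, 10))

AP_SLOPE_CRITERION_V_PER_S = 20.0


@dataclass
class EphysSweep:
    """One sweep: voltage (current clamp, mV) or current (voltage clamp, pA).

    ``command`` is the step amplitude (pA for current clamp, mV for voltage
    clamp); ``meta`` carries protocol details such as the step window.
    """

    t: np.ndarray
    trace: np.ndarray
    command: float
    fs: float
    protocol: str = ""
    clamp: str = "current"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.trace = np.asarray(self.trace, dtype=float)
        if len(self.t) != len(self.trace):
            raise ValueError("t and trace must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


@dataclass
class APFeatures:
    """Intrinsic-property summary for one neuron."""

    threshold_mv: float | None = None
    half_width_ms: float | None = None
    rheobase_pa: float | None = None
    fi_curve: dict = field(default_factory=dict)  # step pA -> spike count
    r_m_mohm: float | None = None
    tau_m_ms: float | None = None
    capacitance_pf: float | None = None


@dataclass
class MiniEventSet:
    """Detected miniature postsynaptic currents."""

    polarity: str  # 'mEPSC' (inward at -70 mV) or 'mIPSC' (outward at +10 mV)
    event_times: np.ndarray
    amplitudes: np.ndarray  # pA, magnitude convention (positive)
    frequency: float  # Hz

    @property
    def n_events(self) -> int:
        return len(self.event_times)


@dataclass
class PlasticityTimecourse:
    """Per-sweep evoked-response amplitudes normalized to % of baseline."""

    times_s: np.ndarray
    amplitudes: np.ndarray
    normalized_pct: np.ndarray
    baseline_window_s: tuple[float, float]
    induction_time_s: float
    minute_bins: dict  # minute (int, relative to induction; <0 = baseline) -> mean %
    post_marks_pct: dict  # post-induction minute -> mean % (1, 10, 20, 30 when present)


@dataclass
class ConnectivityCall:
    """Per-neuron input classes and cohort percentages.

    Percentages are computed over responding neurons (at least one evoked
    current); when no neuron responds they are undefined and
    ``n_responding`` is 0.
    """

    classes: list
    counts: dict
    percentages: dict
    n_excluded: int
    n_responding: int


# ---------------------------------------------------------------------------
# spikes and F-I


def detect_spikes(
    v: np.ndarray,
    fs: float,
    height_mv: float = 0.0,
    min_separation_s: float = 0.001,
) -> np.ndarray:
    """Spike times (s) as voltage peaks above ``height_mv`` separated by at
    least ``min_separation_s``."""
    v = np.asarray(v, dtype=float)
    peaks, _ = signal.find_peaks(
        v, height=height_mv, distance=max(1, int(round(min_separation_s * fs)))
    )
    return peaks / fs


def fi_curve(sweeps: list[EphysSweep]) -> dict[int, int]:
    """Spike count per current step for the 0-100 pA / 10 pA protocol.

    Raises
    ------
    ValueError
        If any grid step is missing (the gaps are listed).
    """
    counts: dict[int, int] = {}
    for sw in sweeps:
        step = int(round(sw.command))
        counts[step] = len(detect_spikes(sw.trace, sw.fs))
    missing = [s for s in FI_STEPS_PA if s not in counts]
    if missing:
        raise ValueError(f"missing current steps {missing} pA")
    return {s: counts[s] for s in FI_STEPS_PA}


def rheobase(fi: dict[int, int]) -> float | None:
    """Smallest current step with at least one spike, or None if never firing."""
    for step in sorted(fi):
        if fi[step] >= 1:
            return float(step)
    return None


# ---------------------------------------------------------------------------
# spike shape


def ap_threshold(
    v: np.ndarray,
    fs: float,
    peak_index: int,
    slope_criterion_v_per_s: float = AP_SLOPE_CRITERION_V_PER_S,
) -> float | None:
    """AP threshold: voltage at the first sample of the upstroke where
    dV/dt reaches the slope criterion (default 20 V/s).

    dV/dt is computed by central differences; the upstroke is the contiguous
    supra-criterion run found scanning backward from the spike peak.  Returns
    None (flagged) when the slope never reaches the criterion.
    """
    v = np.asarray(v, dtype=float)
    dvdt = np.gradient(v) * fs / 1000.0  # mV/sample * Hz -> V/s
    i = peak_index
    # skip the low-slope region at the peak itself
    while i > 0 and dvdt[i] < slope_criterion_v_per_s:
        i -= 1
    if i == 0 and dvdt[i] < slope_criterion_v_per_s:
        return None
    # walk back through the supra-criterion upstroke
    while i > 0 and dvdt[i - 1] >= slope_criterion_v_per_s:
        i -= 1
    return float(v[i])


def ap_half_width(
    v: np.ndarray,
    fs: float,
    peak_index: int,
    threshold_mv: float,
) -> float | None:
    """Full width (ms) at half of the threshold-to-peak amplitude.

    Crossing times are linearly interpolated between samples.  Returns None
    (flagged) for malformed spikes (peak not above threshold, or a crossing
    missing on either side).
    """
    v = np.asarray(v, dtype=float)
    peak = v[peak_index]
    if peak <= threshold_mv:
        return None
    half = (peak + threshold_mv) / 2.0

    i = peak_index
    while i > 0 and v[i] > half:
        i -= 1
    if v[i] > half:
        return None
    left = i + (half - v[i]) / (v[i + 1] - v[i])

    j = peak_index
    while j < len(v) - 1 and v[j] > half:
        j += 1
    if v[j] > half:
        return None
    right = j - 1 + (v[j - 1] - half) / (v[j - 1] - v[j])

    return float((right - left) / fs * 1000.0)


# ---------------------------------------------------------------------------
# passive properties


def passive_props(
    sweep: EphysSweep,
    step_start_s: float | None = None,
    step_dur_s: float = 0.05,
    steady_last_s: float = 0.01,
) -> tuple[float, float, float]:
    """Membrane resistance, time constant and capacitance from a test pulse.

    For a current-clamp sweep (hyperpolarizing current step producing a
    ~5 mV deflection from -70 mV), the onset transient is fitted with a
    single exponential dV(t) = dV_inf * (1 - exp(-t/tau)); R = dV_inf / dI
    uses the fitted asymptote rather than the raw late-step mean, because a
    membrane with tau ~ 20 ms settles to only ~88% of dV_inf within a 50 ms
    step and the late-step mean would underestimate R by ~10%.  The mean over
    the last ``steady_last_s`` of the step seeds the fit.  For a
    voltage-clamp sweep (command step in mV, trace in pA), R = dV_command /
    dI_inf with the current asymptote fitted the same way.  C = tau / R.

    Returns
    -------
    (r_m_mohm, tau_m_ms, capacitance_pf)

    Raises
    ------
    ValueError
        On a zero-amplitude command step or an exponential fit that fails to
        converge (the residual is reported).
    """
    if sweep.command == 0:
        raise ValueError("zero-amplitude test step")
    if step_start_s is None:
        step_start_s = sweep.meta.get("step_start_s", 0.01)
    fs = sweep.fs
    i0 = int(round(step_start_s * fs))
    i1 = i0 + int(round(step_dur_s * fs))
    if i1 > len(sweep.trace):
        raise ValueError("test step runs past end of sweep")
    baseline = float(np.mean(sweep.trace[:i0]))
    steady = float(np.mean(sweep.trace[i1 - int(round(steady_last_s * fs)) : i1]))
    delta = steady - baseline
    if delta == 0:
        raise ValueError("no measurable deflection")

    # joint fit of the onset transient: asymptote and time constant
    seg = sweep.trace[i0:i1]
    ts = np.arange(len(seg)) / fs

    def model(t, dv_inf, tau):
        return baseline + dv_inf * (1.0 - np.exp(-t / tau))

    try:
        popt, _ = optimize.curve_fit(
            model, ts, seg, p0=[delta, step_dur_s / 5.0], maxfev=2000
        )
    except RuntimeError as exc:
        raise ValueError(f"exponential fit failed: {exc}") from exc
    dv_inf, tau_s = float(popt[0]), float(popt[1])
    resid = float(np.sqrt(np.mean((model(ts, dv_inf, tau_s) - seg) ** 2)))
    if not 0 < tau_s < 10 * step_dur_s:
        raise ValueError(f"exponential fit implausible (tau={tau_s:.4g} s, rms residual {resid:.3g})")
    if dv_inf == 0 or np.sign(dv_inf) != np.sign(delta):
        raise ValueError(f"exponential fit implausible (asymptote {dv_inf:.4g})")

    if sweep.clamp == "current":
        r_mohm = (dv_inf / sweep.command) * 1000.0  # mV/pA = GOhm
    else:
        r_mohm = (sweep.command / dv_inf) * 1000.0
    tau_ms = tau_s * 1000.0
    cap_pf = tau_ms / r_mohm * 1000.0  # ms/MOhm -> nF; *1000 -> pF
    return float(r_mohm), tau_ms, cap_pf


# ---------------------------------------------------------------------------
# miniature PSCs


def detect_minis(
    trace: np.ndarray,
    fs: float,
    polarity: str,
    threshold_pa: float = 5.0,
    min_interval_s: float = 0.005,
    band_hz: tuple[float, float] = (1.0, 2000.0),
    min_duration_s: float = 0.001,
) -> MiniEventSet:
    """Threshold-crossing mini detection on a band-passed trace.

    ``polarity`` is ``'mEPSC'`` (inward, negative deflections at -70 mV) or
    ``'mIPSC'`` (outward, positive at +10 mV).  The trace is band-pass
    filtered (default 1-2000 Hz, zero-phase) and thresholded at
    ``threshold_pa`` in the polarity direction.  An event is a maximal
    supra-threshold run lasting at least ``min_duration_s`` (a genuine PSC
    with millisecond rise and ~8 ms decay stays above threshold far longer
    than an isolated noise excursion); surviving runs separated by less than
    ``min_interval_s`` are merged so a noisy decay flank cannot double-count
    one event.  Each amplitude is the raw peak relative to the median of the
    10 ms before the run onset, reported as a positive magnitude.
    """
    if polarity not in ("mEPSC", "mIPSC"):
        raise ValueError("polarity must be 'mEPSC' or 'mIPSC'")
    trace = np.asarray(trace, dtype=float)
    lo, hi = band_hz
    hi = min(hi, 0.45 * fs)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, trace)
    s = -filt if polarity == "mEPSC" else filt

    above = s > threshold_pa
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    runs = [
        (a, b)
        for a, b in zip(edges[::2], edges[1::2])
        if b - a >= max(1, int(round(min_duration_s * fs)))
    ]
    gap = max(1, int(round(min_interval_s * fs)))
    merged: list[tuple[int, int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    base_pre = int(round(0.01 * fs))  # local baseline from the 10 ms before onset
    raw = -trace if polarity == "mEPSC" else trace
    peaks = np.empty(len(merged), dtype=int)
    amps = np.empty(len(merged))
    for k, (a, b) in enumerate(merged):
        p = a + int(np.argmax(s[a:b]))
        local = np.median(raw[max(0, a - base_pre) : a]) if a > 0 else 0.0
        peaks[k] = p
        amps[k] = raw[p] - local
    duration = len(trace) / fs
    return MiniEventSet(
        polarity=polarity,
        event_times=peaks / fs,
        amplitudes=amps,
        frequency=len(peaks) / duration if duration > 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# connectivity


def classify_connectivity(
    responses: list[tuple[bool | None, bool | None]],
) -> ConnectivityCall:
    """Classify each neuron by its light-evoked currents at the two holds.

    Each element is ``(excitatory_at_minus70, inhibitory_at_plus10)``; a
    ``None`` in either slot means that holding condition was not recorded and
    the neuron is excluded (counted in ``n_excluded``).  Classes are
    ``both``, ``excitatory_only``, ``inhibitory_only`` and ``none``;
    percentages (to full precision; round for display) are over responding
    neurons.
    """
    classes: list[str] = []
    n_excluded = 0
    for exc, inh in responses:
        if exc is None or inh is None:
            n_excluded += 1
            continue
        if exc and inh:
            classes.append("both")
        elif exc:
            classes.append("excitatory_only")
        elif inh:
            classes.append("inhibitory_only")
        else:
            classes.append("none")
    counts = {c: classes.count(c) for c in ("both", "inhibitory_only", "excitatory_only", "none")}
    n_responding = len(classes) - counts["none"]
    percentages = {}
    if n_responding > 0:
        for c in ("both", "inhibitory_only", "excitatory_only"):
            percentages[c] = 100.0 * counts[c] / n_responding
    return ConnectivityCall(
        classes=classes,
        counts=counts,
        percentages=percentages,
        n_excluded=n_excluded,
        n_responding=n_responding,
    )


# ---------------------------------------------------------------------------
# LTP


def ltp_normalize(
    amplitudes: np.ndarray,
    times_s: np.ndarray,
    induction_time_s: float,
    baseline_min: float = 10.0,
    mark_minutes: tuple[int, ...] = (1, 10, 20, 30),
) -> PlasticityTimecourse:
    """Express evoked-response amplitudes as percent of the baseline mean.

    The baseline is the ``baseline_min`` minutes immediately preceding the
    induction marker; normalized = 100 * amplitude / mean(baseline).  Sweeps
    are binned into whole minutes relative to induction and the mean percent
    at the requested post-induction minute marks is reported.

    Raises
    ------
    ValueError
        If no baseline sweeps exist or the baseline mean is zero.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    b0 = induction_time_s - baseline_min * 60.0
    in_baseline = (times_s >= b0) & (times_s < induction_time_s)
    if not in_baseline.any():
        raise ValueError("no sweeps in the baseline window")
    base_mean = float(np.mean(amplitudes[in_baseline]))
    if base_mean == 0:
        raise ValueError("zero baseline mean; cannot normalize")
    normalized = 100.0 * amplitudes / base_mean

    rel_min = np.floor((times_s - induction_time_s) / 60.0).astype(int)
    minute_bins: dict[int, float] = {}
    for m in np.unique(rel_min):
        minute_bins[int(m)] = float(np.mean(normalized[rel_min == m]))
    # post minute k covers (k-1, k] minutes after induction
    post_marks = {
        k: minute_bins[k - 1] for k in mark_minutes if (k - 1) in minute_bins
    }
    return PlasticityTimecourse(
        times_s=times_s,
        amplitudes=amplitudes,
        normalized_pct=normalized,
        baseline_window_s=(b0, induction_time_s),
        induction_time_s=induction_time_s,
        minute_bins=minute_bins,
        post_marks_pct=post_marks,
    )
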