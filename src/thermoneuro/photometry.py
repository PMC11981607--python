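"""Fiber-photometry calcium-signal pipeline.

Two-channel recordings pair a calcium-dependent 465 nm signal with a 405 nm
isosbestic control that sees the same bleaching and motion artifacts but no
calcium-dependent fluorescence.  The pipeline fits the control channel with a
polynomial in time, subtracts the fit from the signal channel, forms
dF/F = (F465 - F405_fit) / F405_fit, detects transients as excursions
exceeding mu + k*sigma of a randomly chosen 5-10 s baseline window, and builds
peri-event z-score matrices aligned to behavioral event onsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhotometrySession",
    "IsosbesticFit",
    "DffTrace",
    "TransientSet",
    "PeriEventMatrix",
    "fit_isosbestic",
    "compute_dff",
    "select_baseline",
    "detect_transients",
    "zscore_trace",
    "peri_event_matrix",
    "analyze_session",
]


@dataclass
class PhotometrySession:
    """Paired 465/405 nm fluorescence time series.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing.
    f465 : array of float
        Calcium-dependent signal channel, arbitrary fluorescence units.
    f405 : array of float
        Isosbestic control channel, same units and length as ``f465``.
    fs : float
        Sampling rate in Hz (1017 Hz for the TDT acquisition emulated here).
    labels : dict
        Free-form session metadata (mouse id, day, condition).
    """

    t: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    fs: float
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (len(self.t) == len(self.f465) == len(self.f405)):
            raise ValueError("t, f465 and f405 must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return len(self.t) / self.fs


@dataclass
class IsosbesticFit:
    """Polynomial-in-time fit of the 405 nm control channel.

    ``corrected`` is the signal channel minus the fitted control curve;
    ``fitted`` is the smooth control estimate used as the dF/F denominator.
    """

    corrected: np.ndarray
    fitted: np.ndarray
    degree: int
    coefficients: np.ndarray  # polynomial coefficients, highest power first


@dataclass
class DffTrace:
    """Fractional fluorescence change dF/F with its correction metadata."""

    t: np.ndarray
    dff: np.ndarray
    fs: float
    degree: int | None = None
    coefficients: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if len(self.t) != len(self.dff):
            raise ValueError("t and dff must have equal length")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")

    @property
    def duration_s(self) -> float:
        return len(self.dff) / self.fs


@dataclass
class TransientSet:
    """Detected calcium transients with their baseline statistics."""

    event_times: np.ndarray
    event_amplitudes: np.ndarray
    mu: float
    sigma: float
    baseline_window: tuple[float, float]
    frequency: float  # events per second over the analyzed trace
    threshold_multiplier: float = 3.0

    @property
    def n_events(self) -> int:
        return len(self.event_times)


@dataclass
class PeriEventMatrix:
    """Trials x time matrix of signal aligned to event onsets.

    Column 0 of ``time_axis`` corresponds to the event onset; rows whose
    windows would extend past the trace bounds are dropped and counted in
    ``n_dropped``.
    """

    matrix: np.ndarray
    time_axis: np.ndarray
    event_times: np.ndarray
    window: tuple[float, float]
    peak_values: np.ndarray
    peak_latencies: np.ndarray
    n_dropped: int


def fit_isosbestic(session: PhotometrySession, degree: int = 2) -> IsosbesticFit:
    """Fit the 405 nm control channel with a polynomial in time and subtract.

    The least-squares polynomial captures slow fluorescence decay
    (photobleaching); subtracting the fitted curve from the 465 nm channel
    removes the shared slow artifact while leaving calcium transients intact.

    Parameters
    ----------
    session : PhotometrySession
    degree : int
        Polynomial degree; 0 reduces to subtracting the control-channel mean.

    Raises
    ------
    ValueError
        If ``degree`` is negative or the channels are not finite.
    np.linalg.LinAlgError
        If the design matrix is singular (e.g. fewer samples than degree+1).
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if not np.all(np.isfinite(session.f405)) or not np.all(np.isfinite(session.f465)):
        raise ValueError("channels must be finite")
    if len(session.t) < degree + 1:
        raise np.linalg.LinAlgError(
            f"cannot fit degree-{degree} polynomial to {len(session.t)} samples"
        )
    coeffs = np.polyfit(session.t, session.f405, degree)
    fitted = np.polyval(coeffs, session.t)
    return IsosbesticFit(
        corrected=session.f465 - fitted,
        fitted=fitted,
        degree=degree,
        coefficients=coeffs,
    )


def compute_dff(session: PhotometrySession, fit: IsosbesticFit) -> DffTrace:
    """Compute dF/F = (F465 - F405_fit) / F405_fit pointwise.

    The denominator is the fitted (smooth) control curve rather than the raw
    noisy 405 nm samples, so control-channel noise is not injected into the
    ratio.

    Raises
    ------
    ValueError
        If any denominator sample is non-positive; the offending sample
        indices are listed in the message.
    """
    bad = np.flatnonzero(fit.fitted <= 0)
    if bad.size:
        shown = ", ".join(map(str, bad[:10]))
        more = f" (+{bad.size - 10} more)" if bad.size > 10 else ""
        raise ValueError(
            f"non-positive fitted-control samples at indices {shown}{more}"
        )
    dff = fit.corrected / fit.fitted
    return DffTrace(
        t=session.t,
        dff=dff,
        fs=session.fs,
        degree=fit.degree,
        coefficients=fit.coefficients,
    )


def select_baseline(
    dff: DffTrace,
    duration_s: float | None = None,
    seed: int | np.random.Generator = 0,
    robust: bool = False,
) -> tuple[float, float, tuple[float, float]]:
    """Pick a random contiguous baseline window and return (mu, sigma, window).

    The window duration is drawn uniformly from [5, 10] s when not given, and
    its start position uniformly over the admissible range.  By default
    ``mu`` and ``sigma`` are the mean and SD of dF/F inside the half-open
    window [start, end).

    With ``robust=True``, mu is the window median and sigma the
    normal-consistent scaled median absolute deviation (MAD * 1.4826).  Both
    estimators agree on transient-free Gaussian baselines, but the plain
    mean/SD is biased upward whenever the randomly chosen window happens to
    contain calcium transients, which inflates the mu + 3*sigma threshold;
    the robust pair is recommended for spontaneously active sessions.

    Raises
    ------
    ValueError
        If the trace is shorter than the requested duration, or the requested
        duration falls outside [5, 10] s.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if duration_s is None:
        duration_s = float(rng.uniform(5.0, 10.0))
    if not 5.0 <= duration_s <= 10.0:
        raise ValueError(f"baseline duration {duration_s} s outside [5, 10] s")
    total = dff.duration_s
    if total < duration_s:
        raise ValueError(
            f"trace duration {total:.2f} s shorter than baseline {duration_s:.2f} s"
        )
    start = float(rng.uniform(0.0, total - duration_s))
    i0 = int(round(start * dff.fs))
    i1 = i0 + int(round(duration_s * dff.fs))
    segment = dff.dff[i0:i1]
    if robust:
        mu = float(np.median(segment))
        sigma = float(1.4826 * np.median(np.abs(segment - mu)))
    else:
        mu = float(np.mean(segment))
        sigma = float(np.std(segment))
    return mu, sigma, (i0 / dff.fs, i1 / dff.fs)


def _supra_threshold_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index ranges [start, stop)."""
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_transients(
    dff: DffTrace,
    mu: float,
    sigma: float,
    threshold_multiplier: float = 3.0,
    merge_gap_s: float = 0.1,
    min_duration_samples: int = 5,
    baseline_window: tuple[float, float] = (0.0, 0.0),
) -> TransientSet:
    """Detect calcium transients exceeding ``mu + threshold_multiplier*sigma``.

    An event is a maximal contiguous run of samples strictly above the
    threshold.  Runs shorter than ``min_duration_samples`` are discarded
    first (broadband noise produces isolated supra-threshold samples, while
    a genuine indicator transient stays above threshold for tens of
    milliseconds); surviving runs separated by less than ``merge_gap_s`` are
    then merged so that noise dips inside one transient do not split it.
    Event time is the peak sample time; amplitude is peak dF/F minus ``mu``;
    frequency is events per second of trace duration.

    Raises
    ------
    ValueError
        If ``sigma`` is not strictly positive (a degenerate baseline must be
        handled by the caller, e.g. by re-drawing the window).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0; baseline window is degenerate")
    threshold = mu + threshold_multiplier * sigma
    above = dff.dff > threshold  # strict: a peak exactly at threshold is not an event
    runs = _supra_threshold_runs(above)
    runs = [(a, b) for a, b in runs if b - a >= min_duration_samples]

    # merge surviving runs separated by short sub-threshold gaps
    gap_samples = int(round(merge_gap_s * dff.fs))
    merged: list[tuple[int, int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < gap_samples:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))

    times = np.empty(len(merged))
    amps = np.empty(len(merged))
    for k, (start, stop) in enumerate(merged):
        peak = start + int(np.argmax(dff.dff[start:stop]))
        times[k] = dff.t[peak]
        amps[k] = dff.dff[peak] - mu
    duration = dff.duration_s
    return TransientSet(
        event_times=times,
        event_amplitudes=amps,
        mu=mu,
        sigma=sigma,
        baseline_window=baseline_window,
        frequency=len(merged) / duration if duration > 0 else 0.0,
        threshold_multiplier=threshold_multiplier,
    )


def zscore_trace(dff: DffTrace) -> np.ndarray:
    """Z-score dF/F against the whole-session mean and SD.

    Raises
    ------
    ValueError
        If the session SD is zero.
    """
    sd = float(np.std(dff.dff))
    if sd == 0:
        raise ValueError("session SD is zero; cannot z-score")
    return (dff.dff - np.mean(dff.dff)) / sd


def peri_event_matrix(
    z: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    pre_s: float,
    post_s: float,
) -> PeriEventMatrix:
    """Extract trial-aligned windows of a (z-scored) trace around event onsets.

    One row per event with a complete [-pre_s, +post_s) window; the column at
    time offset 0 is the event-onset sample.  Events whose windows would
    extend past the trace bounds are dropped and counted.

    Raises
    ------
    ValueError
        If no event has a complete window.
    """
    z = np.asarray(z, dtype=float)
    event_times = np.atleast_1d(np.asarray(event_times, dtype=float))
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    rows, kept = [], []
    n_dropped = 0
    for et in event_times:
        idx = int(round(et * fs))
        if idx - n_pre < 0 or idx + n_post > len(z):
            n_dropped += 1
            continue
        rows.append(z[idx - n_pre : idx + n_post])
        kept.append(et)
    if not rows:
        raise ValueError("no event has a complete peri-event window")
    matrix = np.vstack(rows)
    time_axis = (np.arange(-n_pre, n_post)) / fs
    peak_idx = np.argmax(matrix, axis=1)
    return PeriEventMatrix(
        matrix=matrix,
        time_axis=time_axis,
        event_times=np.asarray(kept),
        window=(pre_s, post_s),
        peak_values=matrix[np.arange(len(rows)), peak_idx],
        peak_latencies=time_axis[peak_idx],
        n_dropped=n_dropped,
    )


def analyze_session(
    session: PhotometrySession,
    degree: int = 2,
    baseline_duration_s: float | None = None,
    seed: int | np.random.Generator = 0,
    robust_baseline: bool = True,
    threshold_multiplier: float = 3.0,
    merge_gap_s: float = 0.1,
    min_duration_samples: int = 5,
) -> TransientSet:
    """Full transient-detection pipeline for one session.

    Chains isosbestic correction, dF/F, random baseline selection and
    mu + 3*sigma detection with the module defaults (robust baseline
    statistics, see :func:`select_baseline`).
    """
    fit = fit_isosbestic(session, degree=degree)
    dff = compute_dff(session, fit)
    mu, sigma, window = select_baseline(
        dff, duration_s=baseline_duration_s, seed=seed, robust=robust_baseline
    )
    return detect_transients(
        dff,
        mu,
        sigma,
        threshold_multiplier=threshold_multiplier,
        merge_gap_s=merge_gap_s,
        min_duration_samples=min_duration_samples,
        baseline_window=window,
    )
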