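"""Acoustic startle response (ASR) and prepulse inhibition (PPI) quantification.

The startle response is measured from high-speed (200 fps) pose-estimation
keypoints: for each stimulus trial, each labelled body part's vibration
amplitude is its peak displacement from the pre-stimulus position within
200 ms of sound onset, and the trial amplitude is the mean over body parts.
Trials contaminated by spontaneous locomotion in the pre-stimulus baseline
are flagged invalid and excluded.  The PPI ratio is the mean amplitude of
valid prepulse+pulse trials divided by the mean amplitude of valid
pulse-only trials.

The protocol: a quiescence baseline of at least 20 min, a habituation phase
of 10 pulses 20 s apart, then a PPI phase of 20 trials (5 pulse-only at
105 dB, 15 prepulse+pulse with a 75 dB prepulse 500 ms before the pulse) in
randomized order.  Pulse and prepulse durations are 0.2 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrialSpec",
    "StartleSession",
    "StartleTrialResult",
    "build_trial_schedule",
    "startle_amplitude",
    "flag_invalid_trial",
    "analyze_session",
    "ppi_ratio",
]

PULSE_DB = 105.0
PREPULSE_DB = 75.0
PULSE_DURATION_S = 0.2
RESPONSE_WINDOW_S = 0.2
PREPULSE_LEAD_S = 0.5

TRIAL_TYPES = ("habituation_pulse", "pulse_only", "prepulse_pulse")


@dataclass(frozen=True)
class TrialSpec:
    """One stimulus trial: type, pulse onset, and optional prepulse onset."""

    trial_type: str
    pulse_onset_s: float
    prepulse_onset_s: float | None = None

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.trial_type == "prepulse_pulse" and self.prepulse_onset_s is None:
            raise ValueError("prepulse_pulse trial needs a prepulse onset")


@dataclass
class StartleSession:
    """Per-body-part keypoint positions at 200 fps plus the trial schedule.

    ``positions`` maps body-part name to an (n_frames, 2) array of x/y
    positions (mm or px — the PPI ratio is scale-invariant).
    """

    positions: dict
    fps: float
    schedule: list
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(p) for p in self.positions.values()}
        if len(lengths) > 1:
            raise ValueError("all body parts must have equal frame counts")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        n = self.n_frames
        for tr in self.schedule:
            if not 0 <= tr.pulse_onset_s * self.fps < n:
                raise ValueError(f"trial at {tr.pulse_onset_s} s outside recording")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.positions.values())))

    @property
    def body_parts(self) -> list:
        return list(self.positions)


@dataclass
class StartleTrialResult:
    """Measured startle amplitude for one trial."""

    trial_index: int
    trial_type: str
    amplitude: float
    valid: bool
    per_part_amplitudes: dict = field(default_factory=dict)


def build_trial_schedule(
    baseline_min: float = 20.0,
    n_habituation: int = 10,
    habituation_isi_s: float = 20.0,
    n_pulse_only: int = 5,
    n_prepulse: int = 15,
    ppi_iti_s: float = 20.0,
    prepulse_lead_s: float = PREPULSE_LEAD_S,
    seed: int | np.random.Generator = 0,
) -> list[TrialSpec]:
    """Build the full ASR/PPI trial schedule.

    Baseline (default 20 min) precedes 10 habituation pulses 20 s apart,
    then the PPI phase of ``n_pulse_only + n_prepulse`` trials in seeded
    random order; in prepulse trials the prepulse starts
    ``prepulse_lead_s`` (500 ms) before the pulse.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    schedule: list[TrialSpec] = []
    t = baseline_min * 60.0
    for _ in range(n_habituation):
        schedule.append(TrialSpec("habituation_pulse", t))
        t += habituation_isi_s
    types = ["pulse_only"] * n_pulse_only + ["prepulse_pulse"] * n_prepulse
    order = rng.permutation(len(types))
    for k in order:
        tt = types[k]
        if tt == "prepulse_pulse":
            schedule.append(TrialSpec(tt, t, prepulse_onset_s=t - prepulse_lead_s))
        else:
            schedule.append(TrialSpec(tt, t))
        t += ppi_iti_s
    return schedule


def _window_indices(session: StartleSession, start_s: float, stop_s: float) -> slice:
    return slice(int(round(start_s * session.fps)), int(round(stop_s * session.fps)))


def startle_amplitude(
    session: StartleSession,
    trial: TrialSpec,
    trial_index: int = 0,
    window_s: float = RESPONSE_WINDOW_S,
    pre_window_s: float = 0.1,
    method: str = "peak",
) -> StartleTrialResult:
    """Vibration amplitude of one trial.

    For each body part, the reference position is the mean over the
    ``pre_window_s`` immediately before sound onset; the part's amplitude is
    the peak (or RMS, ``method='rms'``) distance from that reference within
    [onset, onset + ``window_s``).  The trial amplitude averages the body
    parts.  Displacement occurring after the 200 ms window does not
    contribute.

    Raises
    ------
    ValueError
        If the response window runs past the end of the recording.
    """
    onset = trial.pulse_onset_s
    win = _window_indices(session, onset, onset + window_s)
    if win.stop > session.n_frames:
        raise ValueError("response window truncated by recording end")
    pre = _window_indices(session, max(0.0, onset - pre_window_s), onset)
    per_part = {}
    for part, pos in session.positions.items():
        ref = pos[pre].mean(axis=0)
        disp = np.hypot(pos[win, 0] - ref[0], pos[win, 1] - ref[1])
        per_part[part] = float(np.max(disp) if method == "peak" else np.sqrt(np.mean(disp**2)))
    amp = float(np.mean(list(per_part.values())))
    return StartleTrialResult(
        trial_index=trial_index,
        trial_type=trial.trial_type,
        amplitude=amp,
        valid=True,
        per_part_amplitudes=per_part,
    )


def flag_invalid_trial(
    session: StartleSession,
    trial: TrialSpec,
    baseline_window_s: float = 1.0,
    move_threshold: float = 50.0,
) -> bool:
    """True (valid) if the animal was quiescent before the stimulus.

    A trial is invalid when the mean body-part speed over the
    ``baseline_window_s`` preceding the (pre)pulse onset exceeds
    ``move_threshold`` (units/s) — the automated stand-in for the manual
    exclusion of trials contaminated by spontaneous movement.
    """
    stim_start = trial.prepulse_onset_s if trial.prepulse_onset_s is not None else trial.pulse_onset_s
    sl = _window_indices(session, max(0.0, stim_start - baseline_window_s), stim_start)
    speeds = []
    for pos in session.positions.values():
        seg = pos[sl]
        if len(seg) < 2:
            continue
        step = np.hypot(np.diff(seg[:, 0]), np.diff(seg[:, 1]))
        speeds.append(np.mean(step) * session.fps)
    return bool(np.mean(speeds) <= move_threshold) if speeds else True


def analyze_session(
    session: StartleSession,
    move_threshold: float = 50.0,
    method: str = "peak",
) -> list[StartleTrialResult]:
    """Measure every PPI-phase trial and apply the validity flag."""
    results = []
    for i, trial in enumerate(session.schedule):
        if trial.trial_type == "habituation_pulse":
            continue
        res = startle_amplitude(session, trial, trial_index=i, method=method)
        res.valid = flag_invalid_trial(session, trial, move_threshold=move_threshold)
        results.append(res)
    return results


def ppi_ratio(results: list[StartleTrialResult]) -> float:
    """PPI ratio: mean valid prepulse+pulse amplitude / mean valid pulse-only
    amplitude.

    Raises
    ------
    ValueError
        If either trial type has no valid trials, or the pulse-only mean is
        zero (the ratio is then undefined).
    """
    pp = [r.amplitude for r in results if r.valid and r.trial_type == "prepulse_pulse"]
    po = [r.amplitude for r in results if r.valid and r.trial_type == "pulse_only"]
    if not pp or not po:
        raise ValueError("need at least one valid trial of each type")
    po_mean = float(np.mean(po))
    if po_mean == 0:
        raise ValueError("pulse-only mean amplitude is zero; PPI ratio undefined")
    return float(np.mean(pp)) / po_mean
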