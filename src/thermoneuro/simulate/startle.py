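"""Synthetic high-speed keypoint recordings for the startle/PPI assay.

Each labelled body part rests at a fixed position with Gaussian tracking
jitter (sub-pixel scale relative to startle deflections); at every pulse
onset a half-sine displacement impulse of the trial's true amplitude is
added, confined to the 200 ms response window.  Trials can be scripted to
contain baseline locomotion so the invalid-trial flag is testable.
"""

from __future__ import annotations

import numpy as np

from ..startle import RESPONSE_WINDOW_S, StartleSession, TrialSpec, build_trial_schedule

__all__ = ["gen_startle_session"]

DEFAULT_BODY_PARTS = ("nose", "head", "shoulder", "tail_base")


def gen_startle_session(
    seed: int,
    true_amp_pulse: float = 5.0,
    true_amp_prepulse: float = 2.0,
    true_amp_habituation: float = 5.0,
    jitter_sd: float = 0.02,
    fps: float = 200.0,
    body_parts: tuple = DEFAULT_BODY_PARTS,
    schedule: list | None = None,
    baseline_min: float = 20.0,
    moving_baseline_trials: tuple = (),
    move_speed: float = 100.0,
    post_s: float = 5.0,
) -> tuple[StartleSession, dict]:
    """Generate a startle session plus ground truth.

    Amplitudes are in mm: pulse-only startle deflections of ~5 mm over
    ~0.02 mm keypoint jitter.  ``schedule`` defaults to the full protocol
    (``baseline_min`` baseline, 10 habituation pulses 20 s apart, then the
    randomized 5 pulse-only + 15 prepulse PPI phase).
    ``moving_baseline_trials`` lists schedule indices whose 1 s pre-stimulus
    baseline contains scripted walking at ``move_speed`` mm/s (those trials
    should be flagged invalid downstream).

    Returns
    -------
    session : StartleSession
    ground_truth : dict
        ``per_trial_amp`` (aligned with the schedule), ``expected_ppi``
        (prepulse/pulse true-amplitude ratio) and ``moving_trials``.
    """
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = build_trial_schedule(baseline_min=baseline_min, seed=rng)
    amp_of = {
        "habituation_pulse": true_amp_habituation,
        "pulse_only": true_amp_pulse,
        "prepulse_pulse": true_amp_prepulse,
    }
    duration_s = max(tr.pulse_onset_s for tr in schedule) + post_s
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps

    win = int(round(RESPONSE_WINDOW_S * fps))
    kernel = np.sin(np.pi * np.arange(win) / win)  # half-sine, peak 1 at 100 ms

    per_trial_amp = [amp_of[tr.trial_type] for tr in schedule]
    positions = {}
    for part in body_parts:
        rest = rng.uniform(-50.0, 50.0, size=2)
        pos = rest + rng.normal(0.0, jitter_sd, size=(n, 2))
        # startle impulses along a per-part unit direction
        theta = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(theta), np.sin(theta)])
        for tr, amp in zip(schedule, per_trial_amp):
            i0 = int(round(tr.pulse_onset_s * fps))
            seg = min(win, n - i0)
            pos[i0 : i0 + seg] += amp * kernel[:seg, None] * direction
        # scripted baseline locomotion for invalid trials
        for k in moving_baseline_trials:
            tr = schedule[k]
            start = tr.prepulse_onset_s if tr.prepulse_onset_s is not None else tr.pulse_onset_s
            j1 = int(round((start - 0.05) * fps))
            j0 = int(round((start - 1.05) * fps))
            drift = (np.arange(j1 - j0) / fps) * move_speed
            pos[j0:j1, 0] += drift
            pos[j1:, 0] += drift[-1]
        positions[part] = pos

    session = StartleSession(
        positions=positions,
        fps=fps,
        schedule=schedule,
        labels={"synthetic": True, "seed": seed},
    )
    ground_truth = {
        "per_trial_amp": per_trial_amp,
        "expected_ppi": true_amp_prepulse / true_amp_pulse if true_amp_pulse else float("nan"),
        "moving_trials": tuple(moving_baseline_trials),
    }
    return session, ground_truth
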