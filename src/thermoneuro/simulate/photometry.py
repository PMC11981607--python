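"""Synthetic two-channel fiber-photometry sessions with known transients.

The model emulates a 465 nm calcium signal and a 405 nm isosbestic control
sampled at 1017 Hz that share a single-exponential bleaching decay and a
slow multiplicative motion artifact (equal fractional gain on both
channels), while calcium transients — double-exponential kernels at Poisson
times — appear only in the signal channel.  Baseline noise is broadband
(white) Gaussian by default, as left by lock-in demodulation; setting
``noise_cutoff_hz`` instead low-passes it to model heavier acquisition
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ..photometry import PhotometrySession

__all__ = ["PhotometryGenParams", "gen_photometry", "transient_kernel"]


@dataclass
class PhotometryGenParams:
    """Parameters of the photometry generator.

    Attributes
    ----------
    duration_s : float
        Session length in seconds.
    fs : float
        Sampling rate, Hz.
    transient_rate : float
        Poisson rate of calcium transients, events/s.
    transient_amp : float
        Transient peak amplitude in multiples of the baseline noise SD.
    transient_tau_rise, transient_tau_decay : float
        Kernel time constants, seconds.  Defaults (10 ms rise, 100 ms decay)
        follow fast GCaMP8-family indicator kinetics.
    bleach_tau : float
        Shared photobleaching time constant, seconds.
    motion_artifact_sd : float
        SD of the shared slow multiplicative motion artifact as a fraction
        of the channel baseline.
    noise_sd : float
        Baseline noise SD in fluorescence units (per channel).
    noise_cutoff_hz : float or None
        Low-pass corner of the baseline noise; None (default) keeps the
        noise white over the acquisition band.
    baseline_465, baseline_405 : float
        Channel baselines in fluorescence units; their ratio is the channel
        gain.
    seed : int
        Required; all randomness derives from it.
    """

    duration_s: float
    seed: int
    fs: float = 1017.0
    transient_rate: float = 0.3
    transient_amp: float = 5.0
    transient_tau_rise: float = 0.010
    transient_tau_decay: float = 0.100
    bleach_tau: float = 600.0
    motion_artifact_sd: float = 0.002
    noise_sd: float = 0.5
    noise_cutoff_hz: float | None = None
    baseline_465: float = 100.0
    baseline_405: float = 80.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.transient_rate < 0:
            raise ValueError("transient_rate must be >= 0")
        if self.transient_tau_decay <= self.transient_tau_rise:
            raise ValueError("decay tau must exceed rise tau")


def transient_kernel(tau_rise: float, tau_decay: float, fs: float) -> np.ndarray:
    """Peak-normalized double-exponential kernel sampled at fs."""
    t = np.arange(0, 6 * tau_decay, 1.0 / fs)
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return k / k.max()


def _lowpassed_noise(
    rng: np.random.Generator, n: int, fs: float, cutoff_hz: float | None, sd: float
) -> np.ndarray:
    white = rng.standard_normal(n)
    if cutoff_hz is None or cutoff_hz >= fs / 2:
        filt = white
    else:
        sos = sps.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
        filt = sps.sosfiltfilt(sos, white)
    s = filt.std()
    return filt / s * sd if s > 0 else filt


def gen_photometry(
    params: PhotometryGenParams,
) -> tuple[PhotometrySession, list[dict]]:
    """Generate a photometry session and the list of injected transients.

    Returns
    -------
    session : PhotometrySession
    ground_truth : list of dict
        One entry per injected transient with ``time_s`` (kernel onset) and
        ``amplitude`` (peak height in fluorescence units,
        ``transient_amp * noise_sd``).
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs

    bleach = np.exp(-t / params.bleach_tau)

    # shared slow motion artifact: random walk, scaled to the requested
    # fractional SD, applied multiplicatively with equal gain to both channels
    if params.motion_artifact_sd > 0:
        walk = np.cumsum(rng.standard_normal(n))
        walk -= walk.mean()
        s = walk.std()
        motion = walk / s * params.motion_artifact_sd if s > 0 else walk
    else:
        motion = np.zeros(n)
    shared = bleach * (1.0 + motion)

    # Poisson transient times, signal channel only
    n_events = rng.poisson(params.transient_rate * params.duration_s)
    onsets = np.sort(rng.uniform(0.0, params.duration_s, size=n_events))
    amp = params.transient_amp * params.noise_sd
    transients = np.zeros(n)
    kernel = transient_kernel(params.transient_tau_rise, params.transient_tau_decay, params.fs)
    for onset in onsets:
        i = int(round(onset * params.fs))
        seg = min(len(kernel), n - i)
        if seg > 0:
            transients[i : i + seg] += amp * kernel[:seg]

    noise465 = _lowpassed_noise(rng, n, params.fs, params.noise_cutoff_hz, params.noise_sd)
    noise405 = _lowpassed_noise(rng, n, params.fs, params.noise_cutoff_hz, params.noise_sd)
    if params.noise_sd == 0:
        noise465 = np.zeros(n)
        noise405 = np.zeros(n)

    f465 = params.baseline_465 * shared + transients + noise465
    f405 = params.baseline_405 * shared + noise405

    session = PhotometrySession(
        t=t,
        f465=f465,
        f405=f405,
        fs=params.fs,
        labels={"synthetic": True, "seed": params.seed},
    )
    ground_truth = [{"time_s": float(o), "amplitude": amp} for o in onsets]
    return session, ground_truth
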