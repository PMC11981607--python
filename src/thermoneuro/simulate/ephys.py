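"""Synthetic patch-clamp sweeps with analytically known properties.

Current-clamp protocols use a leaky integrate-and-fire neuron solved
exactly (exponential relaxation toward V_inf = V_rest + I*R_m between
spikes, a stereotyped spike template pasted at each threshold crossing, a
3 ms refractory reset), so rheobase, F-I counts and passive properties all
have closed forms.  The threshold crossing is taken as reached when the
membrane voltage comes within 1e-6 mV of threshold, so a step exactly at
the analytic rheobase (V_th - V_rest)/R_m fires within a sufficiently long
step.  Voltage-clamp protocols produce miniature-PSC trains with Poisson
timing and Gaussian amplitudes; the LTP protocol produces a per-sweep
evoked-amplitude series with a specified post/pre step change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..ephys import EphysSweep

__all__ = ["EphysGenParams", "gen_ephys_sweeps", "analytic_rheobase_pa"]

_EPS_MV = 1e-6  # voltage tolerance for the asymptotic threshold approach


@dataclass
class EphysGenParams:
    """Ground-truth neuron and recording parameters.

    Units: mV, MOhm, ms, pA, Hz.  The analytic rheobase
    ``(v_threshold - v_rest) / r_m`` follows from the fields.
    """

    seed: int
    v_rest: float = -70.0
    v_threshold: float = -50.0
    r_m: float = 300.0
    tau_m: float = 20.0
    refractory_ms: float = 3.0
    spike_peak_mv: float = 20.0
    spike_sigma_ms: float = 0.3
    mini_rate: float = 2.0
    mini_amp_mean: float = 20.0
    mini_amp_sd: float = 2.0
    mini_noise_sd: float = 1.0
    fs: float = 10000.0
    noise_sd_mv: float = 0.0

    def __post_init__(self) -> None:
        if self.r_m <= 0 or self.tau_m <= 0:
            raise ValueError("r_m and tau_m must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.v_threshold <= self.v_rest:
            raise ValueError("v_threshold must exceed v_rest")


def analytic_rheobase_pa(params: EphysGenParams) -> float:
    """Closed-form rheobase (V_th - V_rest)/R_m in pA."""
    return (params.v_threshold - params.v_rest) / params.r_m * 1000.0


def _lif_sweep(
    params: EphysGenParams,
    i_pa: float,
    step_start_s: float,
    step_dur_s: float,
    total_s: float,
) -> tuple[np.ndarray, list[float]]:
    """Exactly solved LIF voltage trace for one current step; returns
    (v, spike_peak_times)."""
    fs = params.fs
    n = int(round(total_s * fs))
    t = np.arange(n) / fs
    v = np.full(n, params.v_rest)
    tau = params.tau_m / 1000.0
    v_inf = params.v_rest + i_pa * params.r_m / 1000.0
    refr = params.refractory_ms / 1000.0
    t_peak_in_template = 3 * params.spike_sigma_ms / 1000.0
    sigma = params.spike_sigma_ms / 1000.0

    step_end = step_start_s + step_dur_s
    spikes: list[float] = []
    seg_t0, v0 = step_start_s, params.v_rest

    def idx(x: float) -> int:
        return int(np.ceil(x * fs - 1e-9))

    def fill(a: float, b: float, v_start: float, target: float) -> None:
        sl = slice(idx(a), min(n, idx(b)))
        v[sl] = target + (v_start - target) * np.exp(-(t[sl] - a) / tau)

    while seg_t0 < step_end:
        fires = v_inf >= params.v_threshold - _EPS_MV
        if fires:
            gap = v_inf - v0
            drop = v_inf - params.v_threshold + _EPS_MV
            t_cross = seg_t0 + tau * np.log(gap / drop) if gap > drop else seg_t0
        else:
            t_cross = np.inf
        if not fires or t_cross >= step_end:
            fill(seg_t0, step_end, v0, v_inf)
            # decay back to rest after the step
            v_at_end = v_inf + (v0 - v_inf) * np.exp(-(step_end - seg_t0) / tau)
            fill(step_end, total_s, v_at_end, params.v_rest)
            break
        fill(seg_t0, t_cross, v0, v_inf)
        # paste the stereotyped spike template over the refractory window
        sl = slice(idx(t_cross), min(n, idx(t_cross + refr)))
        tt = t[sl] - t_cross
        v[sl] = params.v_threshold + (params.spike_peak_mv - params.v_threshold) * np.exp(
            -((tt - t_peak_in_template) ** 2) / (2 * sigma**2)
        )
        spikes.append(t_cross + t_peak_in_template)
        seg_t0, v0 = t_cross + refr, params.v_rest
    # if the loop exhausts after a spike close to the step end, the trace
    # simply stays at rest (its initialization) once the template ends

    return v, spikes


def _fi_protocol(params: EphysGenParams, rng: np.random.Generator) -> tuple[list[EphysSweep], dict]:
    step_start, step_dur, total = 0.1, 1.0, 1.2
    sweeps, spike_times = [], {}
    for i_pa in range(0, 101, 10):
        v, spikes = _lif_sweep(params, float(i_pa), step_start, step_dur, total)
        if params.noise_sd_mv > 0:
            v = v + rng.normal(0.0, params.noise_sd_mv, size=v.shape)
        n = len(v)
        sweeps.append(
            EphysSweep(
                t=np.arange(n) / params.fs,
                trace=v,
                command=float(i_pa),
                fs=params.fs,
                protocol="fi_steps",
                clamp="current",
                meta={"step_start_s": step_start, "step_dur_s": step_dur},
            )
        )
        spike_times[i_pa] = spikes
    rheo = analytic_rheobase_pa(params)
    truth = {
        "spike_times": spike_times,
        "spike_counts": {i: len(s) for i, s in spike_times.items()},
        "analytic_rheobase_pa": rheo,
        "grid_rheobase_pa": _grid_rheobase(rheo),
    }
    return sweeps, truth


def _grid_rheobase(rheo_pa: float) -> float | None:
    """Analytic rheobase rounded up to the 10 pA protocol grid (None if
    above the largest step)."""
    grid = 10.0 * np.ceil(rheo_pa / 10.0)
    return float(grid) if 0 < grid <= 100.0 else None


def _test_pulse_protocol(params: EphysGenParams, rng: np.random.Generator) -> tuple[EphysSweep, dict]:
    # hyperpolarizing current step sized to give a -5 mV steady-state
    # deflection from rest, mirroring the 50 ms / 5 mV protocol
    step_start, step_dur, total = 0.01, 0.05, 0.1
    i_pa = -5.0 / params.r_m * 1000.0
    fs = params.fs
    n = int(round(total * fs))
    t = np.arange(n) / fs
    tau = params.tau_m / 1000.0
    dv = i_pa * params.r_m / 1000.0
    v = np.full(n, params.v_rest)
    on = (t >= step_start) & (t < step_start + step_dur)
    v[on] = params.v_rest + dv * (1 - np.exp(-(t[on] - step_start) / tau))
    after = t >= step_start + step_dur
    v_end = params.v_rest + dv * (1 - np.exp(-step_dur / tau))
    v[after] = params.v_rest + (v_end - params.v_rest) * np.exp(
        -(t[after] - step_start - step_dur) / tau
    )
    if params.noise_sd_mv > 0:
        v = v + rng.normal(0.0, params.noise_sd_mv, size=n)
    sweep = EphysSweep(
        t=t,
        trace=v,
        command=i_pa,
        fs=fs,
        protocol="test_pulse",
        clamp="current",
        meta={"step_start_s": step_start, "step_dur_s": step_dur},
    )
    truth = {
        "r_m_mohm": params.r_m,
        "tau_m_ms": params.tau_m,
        "capacitance_pf": params.tau_m / params.r_m * 1000.0,
    }
    return sweep, truth


def _mini_protocol(
    params: EphysGenParams,
    rng: np.random.Generator,
    duration_s: float,
    polarity: str,
) -> tuple[EphysSweep, dict]:
    fs = params.fs
    n = int(round(duration_s * fs))
    sign = -1.0 if polarity == "mEPSC" else 1.0
    n_ev = rng.poisson(params.mini_rate * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s, size=n_ev))
    amps = np.abs(rng.normal(params.mini_amp_mean, params.mini_amp_sd, size=n_ev))
    trace = rng.normal(0.0, params.mini_noise_sd, size=n)
    # double-exponential PSC kernel: 1 ms rise, 8 ms decay
    kt = np.arange(0, 0.05, 1.0 / fs)
    kernel = np.exp(-kt / 0.008) - np.exp(-kt / 0.001)
    kernel /= kernel.max()
    for t_ev, amp in zip(times, amps):
        i = int(round(t_ev * fs))
        seg = min(len(kernel), n - i)
        if seg > 0:
            trace[i : i + seg] += sign * amp * kernel[:seg]
    sweep = EphysSweep(
        t=np.arange(n) / fs,
        trace=trace,
        command=-70.0 if polarity == "mEPSC" else 10.0,
        fs=fs,
        protocol="minis",
        clamp="voltage",
        meta={"polarity": polarity},
    )
    truth = {"event_times": times, "amplitudes": amps, "rate_hz": params.mini_rate}
    return sweep, truth


def _ltp_protocol(
    rng: np.random.Generator,
    post_over_pre: float,
    baseline_min: float,
    post_min: float,
    sweep_interval_s: float,
    base_amp_pa: float,
    noise_frac: float,
) -> tuple[dict, dict]:
    induction = baseline_min * 60.0
    times = np.arange(0.0, induction + post_min * 60.0, sweep_interval_s)
    amps = np.where(times < induction, base_amp_pa, base_amp_pa * post_over_pre)
    if noise_frac > 0:
        amps = amps * (1.0 + rng.normal(0.0, noise_frac, size=amps.shape))
    data = {"times_s": times, "amplitudes": amps, "induction_time_s": induction}
    truth = {"post_over_pre": post_over_pre, "expected_post_pct": 100.0 * post_over_pre}
    return data, truth


def gen_ephys_sweeps(
    params: EphysGenParams,
    protocol: str,
    duration_s: float = 60.0,
    polarity: str = "mEPSC",
    post_over_pre: float = 1.5,
    baseline_min: float = 10.0,
    post_min: float = 30.0,
    sweep_interval_s: float = 10.0,
    base_amp_pa: float = 100.0,
    noise_frac: float = 0.05,
):
    """Generate sweeps for one protocol with ground truth.

    ``protocol`` is one of:

    * ``'fi_steps'`` — 11 current-clamp sweeps, 0-100 pA in 10 pA steps;
      returns ``(list[EphysSweep], truth)`` with per-step spike times and the
      analytic/grid rheobase.
    * ``'test_pulse'`` — one 50 ms hyperpolarizing step sweep; truth has
      R_m, tau_m and capacitance.
    * ``'minis'`` — one continuous voltage-clamp trace of ``duration_s``
      with Poisson PSCs (``polarity`` 'mEPSC' or 'mIPSC'); truth has event
      times and amplitudes.
    * ``'ltp'`` — an evoked-amplitude series with a ``post_over_pre`` step
      after the induction marker; returns ``(dict, truth)``.

    Raises
    ------
    ValueError
        For an unknown protocol name.
    """
    rng = np.random.default_rng(params.seed)
    if protocol == "fi_steps":
        return _fi_protocol(params, rng)
    if protocol == "test_pulse":
        return _test_pulse_protocol(params, rng)
    if protocol == "minis":
        return _mini_protocol(params, rng, duration_s, polarity)
    if protocol == "ltp":
        return _ltp_protocol(
            rng, post_over_pre, baseline_min, post_min, sweep_interval_s,
            base_amp_pa, noise_frac,
        )
    raise ValueError(f"unknown protocol {protocol!r}")
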