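"""Spike, passive-property, mini, connectivity and LTP feature tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermoneuro.ephys import (
    EphysSweep,
    ap_half_width,
    ap_threshold,
    classify_connectivity,
    detect_minis,
    detect_spikes,
    fi_curve,
    ltp_normalize,
    passive_props,
    rheobase,
)
from thermoneuro.simulate import EphysGenParams, gen_ephys_sweeps

FS = 10_000.0


# -- spike detection ---------------------------------------------------------


def test_flat_resting_trace_has_no_spikes():
    v = np.full(int(FS), -70.0)
    assert len(detect_spikes(v, FS)) == 0


def test_lif_template_spikes_are_detected_at_pasted_times():
    p = EphysGenParams(seed=0)
    sweeps, truth = gen_ephys_sweeps(p, "fi_steps")
    sw = sweeps[7]  # 70 pA
    expected = truth["spike_times"][70]
    times = detect_spikes(sw.trace, sw.fs)
    assert len(times) == len(expected)
    assert np.allclose(times, expected, atol=2.0 / FS)


def test_spike_count_stable_under_doubled_sampling_rate():
    t = np.arange(int(0.5 * FS)) / FS
    v = np.full(len(t), -70.0)
    for s0 in (0.1, 0.25, 0.4):
        v += 90.0 * np.exp(-((t - s0) ** 2) / (2 * 0.0003**2))
    t2 = np.arange(2 * len(t)) / (2 * FS)
    v2 = np.interp(t2, t, v)
    assert len(detect_spikes(v, FS)) == len(detect_spikes(v2, 2 * FS)) == 3


# -- F-I and rheobase --------------------------------------------------------


def test_never_firing_neuron_has_no_rheobase():
    p = EphysGenParams(seed=0, r_m=150.0)  # rheobase 133 pA > 100 pA grid
    sweeps, truth = gen_ephys_sweeps(p, "fi_steps")
    assert truth["grid_rheobase_pa"] is None
    assert rheobase(fi_curve(sweeps)) is None


def test_rheobase_rounds_up_to_grid():
    # (V_th - V_rest)/R_m = 20 mV / 444.4 MOhm = 45 pA -> grid 50 pA
    p = EphysGenParams(seed=0, r_m=20.0 / 45.0 * 1000.0)
    sweeps, truth = gen_ephys_sweeps(p, "fi_steps")
    assert truth["analytic_rheobase_pa"] == pytest.approx(45.0)
    assert rheobase(fi_curve(sweeps)) == 50.0


def test_spike_counts_are_monotone_in_current_for_lif():
    sweeps, _ = gen_ephys_sweeps(EphysGenParams(seed=1), "fi_steps")
    fi = fi_curve(sweeps)
    counts = [fi[i] for i in sorted(fi)]
    assert all(b >= a for a, b in zip(counts, counts[1:]))


def test_fi_curve_reports_missing_steps():
    sweeps, _ = gen_ephys_sweeps(EphysGenParams(seed=1), "fi_steps")
    with pytest.raises(ValueError, match="50"):
        fi_curve([sw for sw in sweeps if sw.command != 50.0])


# -- AP threshold and half-width ---------------------------------------------


def synthetic_ap(upstroke_v_per_s=100.0, start_mv=-52.0, fs=FS):
    """Piecewise-linear spike: slow ramp, then a linear upstroke from
    start_mv at the given dV/dt, then symmetric downstroke."""
    slow = np.linspace(-70.0, start_mv, 400)  # ~4.5 V/s: below criterion
    dv = upstroke_v_per_s * 1000.0 / fs  # mV per sample
    up = np.arange(start_mv, 30.0, dv)
    down = up[::-1]
    v = np.concatenate([slow, up, down, np.full(200, -70.0)])
    return v, int(400 + len(up) - 1)


def test_threshold_read_at_slope_criterion_crossing():
    v, peak = synthetic_ap()
    thr = ap_threshold(v, FS, peak)
    dv_per_sample = 100.0 * 1000.0 / FS
    assert thr == pytest.approx(-52.0, abs=2 * dv_per_sample)


def test_subthreshold_trace_threshold_is_flagged_none():
    v = np.linspace(-70.0, -69.0, 1000)  # max slope ~ 0.01 V/s
    assert ap_threshold(v, FS, int(np.argmax(v))) is None


def test_halving_fs_doubles_worst_case_threshold_discretization():
    # error bound is (upstroke slope) * dt: one sample of voltage change
    slope = 100.0  # V/s
    for fs, factor in ((FS, 1.0), (FS / 2, 2.0)):
        bound = slope * 1000.0 / fs  # mV per sample
        v, peak = synthetic_ap(upstroke_v_per_s=slope, fs=fs)
        thr = ap_threshold(v, fs, peak)
        assert abs(thr - (-52.0)) <= 2 * bound
        assert bound == pytest.approx(factor * slope * 1000.0 / FS)


def test_triangular_spike_half_width_is_half_the_base():
    # symmetric triangle, 2 ms base, from threshold -50 to peak 30
    half_base = int(0.001 * FS)  # 1 ms rise
    up = np.linspace(-50.0, 30.0, half_base + 1)
    v = np.concatenate([np.full(100, -50.0), up, up[::-1][1:], np.full(100, -50.0)])
    peak = 100 + half_base
    hw = ap_half_width(v, FS, peak, threshold_mv=-50.0)
    assert hw == pytest.approx(1.0, rel=0.01)


def test_gaussian_spike_fwhm_matches_closed_form():
    sigma_ms = 0.3
    t = np.arange(int(0.02 * FS)) / FS * 1000.0  # ms
    center = 10.0
    v = -50.0 + 80.0 * np.exp(-((t - center) ** 2) / (2 * sigma_ms**2))
    peak = int(np.argmax(v))
    hw = ap_half_width(v, FS, peak, threshold_mv=-50.0)
    expected = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma_ms
    assert abs(hw - expected) <= 1000.0 / FS  # within one sample


def test_degenerate_peak_at_threshold_is_flagged():
    v = np.full(1000, -50.0)
    assert ap_half_width(v, FS, 500, threshold_mv=-50.0) is None


# -- passive properties ------------------------------------------------------


def test_ideal_rc_recovers_r_tau_capacitance():
    p = EphysGenParams(seed=0, r_m=200.0, tau_m=20.0)
    sweep, truth = gen_ephys_sweeps(p, "test_pulse")
    r, tau, cap = passive_props(sweep)
    assert r == pytest.approx(200.0, rel=0.01)
    assert tau == pytest.approx(20.0, rel=0.02)
    assert cap == pytest.approx(100.0, rel=0.03)


def test_zero_amplitude_step_raises():
    n = int(0.1 * FS)
    sweep = EphysSweep(t=np.arange(n) / FS, trace=np.full(n, -70.0),
                       command=0.0, fs=FS, protocol="test_pulse", clamp="current")
    with pytest.raises(ValueError):
        passive_props(sweep)


def test_noisy_rc_median_r_error_stays_small():
    errors = []
    for seed in range(20):
        p = EphysGenParams(seed=seed, r_m=200.0, tau_m=20.0, noise_sd_mv=0.2)
        sweep, _ = gen_ephys_sweeps(p, "test_pulse")
        r, _, _ = passive_props(sweep)
        errors.append(abs(r - 200.0) / 200.0)
    assert np.median(errors) < 0.05


# -- minis -------------------------------------------------------------------


def test_flat_trace_has_no_minis():
    v = np.zeros(int(10 * FS))
    assert detect_minis(v, FS, "mEPSC").n_events == 0


def test_mini_rate_and_amplitude_recovery_over_seeds():
    freq_err, amp_err = [], []
    for seed in range(20):
        sweep, truth = gen_ephys_sweeps(EphysGenParams(seed=seed), "minis",
                                        duration_s=60)
        m = detect_minis(sweep.trace, sweep.fs, "mEPSC")
        freq_err.append(m.frequency / 2.0 - 1.0)
        amp_err.append(np.mean(m.amplitudes) / 20.0 - 1.0)
    assert abs(np.mean(freq_err)) < 0.15
    assert abs(np.mean(amp_err)) < 0.10


def test_polarity_flip_on_same_trace_gives_disjoint_event_sets():
    sweep, _ = gen_ephys_sweeps(EphysGenParams(seed=5), "minis", duration_s=30)
    down = detect_minis(sweep.trace, sweep.fs, "mEPSC")
    up = detect_minis(sweep.trace, sweep.fs, "mIPSC")
    assert set(np.round(down.event_times, 4)).isdisjoint(np.round(up.event_times, 4))


def test_mini_count_strictly_decreasing_across_amplitude_spanning_thresholds():
    # deterministic trace with events of amplitude 10, 20, 30 pA
    n = int(3 * FS)
    v = np.zeros(n)
    kt = np.arange(0, 0.05, 1 / FS)
    kernel = np.exp(-kt / 0.008) - np.exp(-kt / 0.001)
    kernel /= kernel.max()
    for t0, amp in ((0.5, 10.0), (1.5, 20.0), (2.5, 30.0)):
        i = int(t0 * FS)
        v[i : i + len(kernel)] -= amp * kernel
    counts = [detect_minis(v, FS, "mEPSC", threshold_pa=th).n_events
              for th in (5.0, 15.0, 25.0)]
    assert counts == [3, 2, 1]


def test_mini_count_nonincreasing_in_threshold_on_generator_traces():
    sweep, _ = gen_ephys_sweeps(EphysGenParams(seed=2), "minis", duration_s=60)
    counts = [detect_minis(sweep.trace, sweep.fs, "mEPSC", threshold_pa=th).n_events
              for th in (8.0, 12.0, 16.0, 20.0)]
    assert all(b <= a for a, b in zip(counts, counts[1:]))


def test_mini_polarity_validation():
    with pytest.raises(ValueError):
        detect_minis(np.zeros(1000), FS, "upward")


# -- connectivity ------------------------------------------------------------


def test_all_silent_cohort_has_no_responding_percentages():
    call = classify_connectivity([(0.0, 0.0)] * 5)
    assert call.n_responding == 0
    assert call.percentages == {}


def test_single_dual_response_neuron_is_100_percent_both():
    call = classify_connectivity([(12.0, 30.0)])
    assert call.percentages["both"] == pytest.approx(100.0)


def test_missing_holding_condition_excludes_neuron():
    call = classify_connectivity([(None, 10.0), (5.0, 5.0)])
    assert call.n_excluded == 1
    assert call.counts["both"] == 1


# -- LTP normalization -------------------------------------------------------


def test_post_equal_to_baseline_reads_100_percent_everywhere():
    times = np.arange(0.0, 2400.0, 10.0)
    amps = np.full(len(times), 80.0)
    tc = ltp_normalize(amps, times, induction_time_s=600.0)
    assert np.allclose(tc.normalized_pct, 100.0)
    for pct in tc.post_marks_pct.values():
        assert pct == pytest.approx(100.0)


def test_baseline_mean_is_exactly_100_percent_by_construction():
    rng = np.random.default_rng(0)
    times = np.arange(0.0, 2400.0, 10.0)
    amps = 80.0 + rng.normal(0, 8, size=len(times))
    tc = ltp_normalize(amps, times, induction_time_s=600.0)
    assert np.mean(tc.normalized_pct[times < 600.0]) == pytest.approx(100.0)


@given(scale=st.floats(min_value=0.01, max_value=100.0))
def test_ltp_normalization_is_scale_invariant(scale):
    times = np.arange(0.0, 2400.0, 10.0)
    amps = np.where(times < 600.0, 100.0, 150.0)
    a = ltp_normalize(amps, times, induction_time_s=600.0)
    b = ltp_normalize(scale * amps, times, induction_time_s=600.0)
    assert np.allclose(a.normalized_pct, b.normalized_pct)
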