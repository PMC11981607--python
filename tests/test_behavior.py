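"""Unit and property tests for trajectory kinematics and event detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermoneuro.arenas import make_arena
from thermoneuro.behavior import (
    Trajectory,
    compute_speed,
    detect_fast_running,
    classify_center_pause_outcomes,
    detect_open_to_closed_transitions,
    preference_indices,
    pupil_timecourse,
    zone_occupancy,
    OccupancySummary,
)
from thermoneuro.simulate import TrajectoryGenParams, gen_trajectory

FPS = 30.0


def make_traj(x, y, fps=FPS, arena="epm"):
    n = len(x)
    return Trajectory(t=np.arange(n) / fps, x=np.asarray(x, float),
                      y=np.asarray(y, float), fps=fps, zones=make_arena(arena),
                      arena_name=arena)


# -- speed -------------------------------------------------------------------


def test_stationary_trajectory_has_zero_speed():
    traj = make_traj(np.zeros(200), np.full(200, 100.0))
    assert np.allclose(compute_speed(traj), 0.0)


def test_uniform_motion_speed_is_exact():
    t = np.arange(300) / FPS
    traj = make_traj(100.0 * t - 200.0, np.zeros(300), arena="open_field")
    speed = compute_speed(traj)
    assert np.allclose(speed, 100.0, atol=1e-6)


def test_speed_profile_consistent_when_fps_doubles():
    dur, f2 = 10.0, 60.0
    t1 = np.arange(int(dur * FPS)) / FPS
    t2 = np.arange(int(dur * f2)) / f2
    path_x = lambda t: 150.0 * np.sin(2 * np.pi * t / dur)
    tr1 = make_traj(path_x(t1), np.zeros(len(t1)), fps=FPS, arena="open_field")
    tr2 = make_traj(path_x(t2), np.zeros(len(t2)), fps=f2, arena="open_field")
    s1 = compute_speed(tr1)
    s2 = compute_speed(tr2)[::2][: len(s1)]
    interior = slice(10, len(s1) - 10)
    assert np.allclose(s1[interior], s2[interior], rtol=0.02, atol=2.0)


def test_speed_requires_at_least_two_frames():
    with pytest.raises(ValueError):
        compute_speed(make_traj([0.0], [100.0]))


# -- occupancy ---------------------------------------------------------------


def test_trajectory_in_closed_arm_has_zero_open_time_and_entries():
    traj = make_traj(np.zeros(600), np.full(600, 150.0))  # closed_arm_1
    occ = zone_occupancy(traj)
    assert occ.zone_time_s["open_arm_1"] == 0.0
    assert occ.zone_time_s["open_arm_2"] == 0.0
    assert occ.zone_entries["open_arm_1"] == 0


def test_scripted_four_open_arm_entries_are_counted():
    # alternate between closed arm (0, 150) and open arm (150, 0), 1 s dwells
    xs, ys = [], []
    for k in range(9):
        if k % 2 == 0:
            xs += [0.0] * 30
            ys += [150.0] * 30
        else:
            xs += [150.0] * 30
            ys += [0.0] * 30
    occ = zone_occupancy(make_traj(xs, ys))
    assert occ.zone_entries["open_arm_1"] == 4


def test_zone_times_sum_to_session_duration():
    traj, _ = gen_trajectory(TrajectoryGenParams(duration_s=45, seed=8))
    occ = zone_occupancy(traj)
    assert sum(occ.zone_time_s.values()) == pytest.approx(occ.duration_s)


# -- preference ratios -------------------------------------------------------


def occ_with(times: dict) -> OccupancySummary:
    return OccupancySummary(zone_time_s=times, zone_entries={}, total_distance_mm=0.0,
                            duration_s=sum(times.values()))


def test_equal_chamber_times_give_unit_preference():
    occ = occ_with({"left": 120.0, "right": 120.0})
    res = preference_indices("tct", occ, roles={"stranger": "left", "object": "right"})
    assert res.ratio == pytest.approx(1.0)


def test_sucrose_preference_arithmetic():
    res = preference_indices("spt", sucrose_ml=6.0, water_ml=2.0)
    assert res.ratio == pytest.approx(0.75)


def test_zero_denominator_is_flagged_not_infinite():
    occ = occ_with({"left": 100.0, "right": 0.0})
    res = preference_indices("tct", occ, roles={"stranger": "left", "object": "right"})
    assert not res.defined
    assert np.isnan(res.ratio)


# -- fast running ------------------------------------------------------------


def brute_force_bouts(speed, fps, threshold, min_dur_s, merge_gap_s):
    runs, start = [], None
    for i, v in enumerate(np.append(speed, -1.0)):
        if v > threshold and start is None:
            start = i
        elif v <= threshold and start is not None:
            runs.append((start, i))
            start = None
    merged = []
    for a, b in runs:
        if merged and (a - merged[-1][1]) / fps < merge_gap_s:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return [(a, b) for a, b in merged if (b - a) / fps >= min_dur_s]


def test_constant_walking_speed_yields_no_episodes():
    assert detect_fast_running(np.full(600, 100.0), FPS) == []


def test_two_scripted_bouts_separated_by_walking_yield_two_episodes():
    speed = np.full(900, 80.0)
    speed[100:130] = 600.0
    speed[280:310] = 600.0  # 5 s later
    events = detect_fast_running(speed, FPS)
    assert len(events) == 2
    assert all(e.peak_speed == 600.0 for e in events)
    oracle = brute_force_bouts(speed, FPS, 400.0, 0.25, 0.2)
    assert len(oracle) == 2


def test_speed_exactly_at_threshold_is_not_fast_running():
    speed = np.full(600, 400.0)
    assert detect_fast_running(speed, FPS) == []
    speed2 = np.full(600, 400.0 + 1e-9)
    assert len(detect_fast_running(speed2, FPS)) == 1


@given(seed=st.integers(min_value=0, max_value=10_000))
def test_fast_running_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    speed = np.abs(rng.normal(200, 180, size=400))
    events = detect_fast_running(speed, FPS)
    oracle = brute_force_bouts(speed, FPS, 400.0, 0.25, 0.2)
    assert len(events) == len(oracle)
    for e, (a, b) in zip(sorted(events, key=lambda e: e.onset_s), oracle):
        assert e.onset_s == pytest.approx(a / FPS)
        assert e.peak_speed == pytest.approx(np.max(speed[a:b]))


# -- centre pause outcomes ---------------------------------------------------


def test_path_never_entering_center_yields_no_pause_events():
    traj = make_traj(np.zeros(600), np.full(600, 150.0))
    speed = compute_speed(traj)
    assert classify_center_pause_outcomes(traj, speed) == []


def test_scripted_pause_then_sprint_to_closed_is_a_return_run():
    traj, _ = gen_trajectory(TrajectoryGenParams(
        duration_s=40, scripted_events=[("pause_then_return_run", 15.0)], seed=4))
    speed = compute_speed(traj)
    events = classify_center_pause_outcomes(traj, speed)
    assert [e.kind for e in events] == ["pause_then_return_run"]
    assert events[0].peak_speed > 400.0


def test_scripted_pause_then_slow_open_exit_is_exit_open():
    traj, _ = gen_trajectory(TrajectoryGenParams(
        duration_s=40, scripted_events=[("pause_then_exit_open", 15.0)], seed=4))
    speed = compute_speed(traj)
    events = classify_center_pause_outcomes(traj, speed)
    assert [e.kind for e in events] == ["pause_then_exit_open"]


# -- open-to-closed transitions ----------------------------------------------


def test_no_open_arm_visit_yields_no_transitions():
    traj = make_traj(np.zeros(600), np.full(600, 150.0))
    speed = compute_speed(traj)
    assert detect_open_to_closed_transitions(traj, speed) == []


def test_scripted_open_to_closed_dash_is_a_run_event():
    traj, truth = gen_trajectory(TrajectoryGenParams(
        duration_s=40, scripted_events=[("open_to_closed_run", 15.0)], seed=6))
    speed = compute_speed(traj)
    events = detect_open_to_closed_transitions(traj, speed)
    runs = [e for e in events if e.kind == "open_to_closed_run"]
    assert len(runs) == 1
    assert runs[0].peak_speed > 400.0


def test_closed_to_open_direction_is_not_emitted():
    # closed arm -> center -> open arm, slow walk, then stay
    xs = np.concatenate([np.zeros(90), np.linspace(0, 150, 120), np.full(90, 150.0)])
    ys = np.concatenate([np.full(90, 150.0), np.linspace(150, 0, 120), np.zeros(90)])
    traj = make_traj(xs, ys)
    speed = compute_speed(traj)
    assert detect_open_to_closed_transitions(traj, speed) == []


# -- pupil -------------------------------------------------------------------


def pupil_frame(n, scale=None, likelihood=None):
    base = {
        "pupil_left": (-1.0, 0.0), "pupil_right": (1.0, 0.0),
        "pupil_top": (0.0, 1.0), "pupil_bottom": (0.0, -1.0),
        "eyelid_top": (0.0, 2.0), "eyelid_bottom": (0.0, -2.0),
    }
    scale = np.ones(n) if scale is None else scale
    likelihood = np.ones(n) if likelihood is None else likelihood
    cols = {}
    for part, (x0, y0) in base.items():
        s = scale if part.startswith("pupil") else np.ones(n)
        cols[(part, "x")] = x0 * s
        cols[(part, "y")] = y0 * s
        cols[(part, "likelihood")] = likelihood
    return pd.DataFrame(cols)


def test_constant_keypoints_give_unit_normalized_size_everywhere():
    kp = pupil_frame(900)  # 30 s at 30 fps
    tc = pupil_timecourse(kp)
    assert np.allclose(tc.diameter_norm, 1.0)
    assert np.allclose([tc.samples["pre"], tc.samples["light"], tc.samples["post"]], 1.0)


def test_pupil_dilated_during_light_reads_1p5_at_light_sample():
    n = 900
    scale = np.ones(n)
    scale[300:600] = 1.5  # light window 10-20 s
    tc = pupil_timecourse(pupil_frame(n, scale=scale))
    assert tc.samples["light"] == pytest.approx(1.5)
    assert tc.samples["pre"] == pytest.approx(1.0)
    assert tc.samples["post"] == pytest.approx(1.0)


def test_long_low_likelihood_gap_raises_with_gap_description():
    n = 900
    like = np.ones(n)
    like[100:190] = 0.1  # 3 s gap at 30 fps
    with pytest.raises(ValueError, match="gap"):
        pupil_timecourse(pupil_frame(n, likelihood=like))


def test_short_low_likelihood_gap_is_interpolated():
    n = 900
    like = np.ones(n)
    like[100:110] = 0.1
    tc = pupil_timecourse(pupil_frame(n, likelihood=like))
    assert tc.n_interpolated > 0
    assert np.allclose(tc.diameter_norm, 1.0)
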