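"""Scripted synthetic trajectories inside the behavioral arenas.

The animal model is a waypoint walker: between scripted events it wanders at
walking speed inside a home region (the first closed arm in the elevated
plus maze, a central box elsewhere); each scripted event is realized as a
deterministic path segment (a sprint, a centre pause followed by an exit,
an arm transition) whose onset/offset and peak speed are logged as ground
truth.  Because scripted excursions can force additional real events on the
way back home (e.g. returning from an open arm necessarily produces an
open-to-closed transition), the ground truth lists every event realized in
the trajectory, scripted or induced.

Frame-wise keypoint jitter (Gaussian, ``jitter_mm``) is added at the end,
emulating tracking noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..arenas import make_arena
from ..behavior import RUN_SPEED_THRESHOLD_MM_S, BehaviorEvent, Trajectory

__all__ = ["TrajectoryGenParams", "gen_trajectory", "EVENT_KINDS"]

EVENT_KINDS = (
    "fast_run",
    "pause_then_return_run",
    "pause_then_return_walk",
    "pause_then_exit_open",
    "open_to_closed_run",
    "open_to_closed_walk",
    "open_arm_entry",
)

_EPM_ONLY = set(EVENT_KINDS) - {"fast_run"}


@dataclass
class TrajectoryGenParams:
    """Parameters of the trajectory generator.

    ``scripted_events`` is a list of ``(event_kind, time_s)`` pairs; event
    kinds other than ``fast_run`` require the EPM arena.  ``walk_speed`` and
    ``run_speed`` are commanded locomotion speeds (mm/s); the run speed must
    exceed the 400 mm/s running threshold for run-type events to be
    realizable.
    """

    arena: str = "epm"
    fps: float = 30.0
    duration_s: float = 120.0
    walk_speed: float = 80.0
    run_speed: float = 600.0
    scripted_events: list = field(default_factory=list)
    jitter_mm: float = 0.5
    pause_duration_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")
        for kind, t_ev in self.scripted_events:
            if kind not in EVENT_KINDS:
                raise ValueError(f"unknown scripted event kind {kind!r}")
            if not 0 <= t_ev <= self.duration_s:
                raise ValueError(f"scripted event at {t_ev} s outside [0, {self.duration_s}] s")
            if kind in _EPM_ONLY and self.arena != "epm":
                raise ValueError(f"event {kind!r} requires the epm arena, not {self.arena!r}")


class _PathBuilder:
    """Accumulates frames by dwelling and by straight moves at given speed."""

    def __init__(self, start: np.ndarray, fps: float):
        self.fps = fps
        self.frames: list[np.ndarray] = [np.asarray(start, dtype=float)]

    @property
    def pos(self) -> np.ndarray:
        return self.frames[-1]

    @property
    def n(self) -> int:
        return len(self.frames)

    def dwell(self, n_frames: int) -> None:
        self.frames.extend([self.pos.copy() for _ in range(n_frames)])

    def move_to(self, target, speed: float) -> tuple[int, int]:
        """Straight-line move at constant speed; returns (start, stop) frames."""
        target = np.asarray(target, dtype=float)
        start = self.n
        dist = float(np.linalg.norm(target - self.pos))
        n_steps = max(1, int(np.ceil(dist / (speed / self.fps))))
        origin = self.pos.copy()
        for k in range(1, n_steps + 1):
            self.frames.append(origin + (target - origin) * (k / n_steps))
        return start, self.n


def _first_frame_in(frames: np.ndarray, lo: int, poly) -> int:
    import shapely

    for i in range(lo, len(frames)):
        if shapely.intersects_xy(poly, frames[i, 0], frames[i, 1]):
            return i
    return len(frames) - 1


def _last_frame_in(frames: np.ndarray, lo: int, hi: int, poly) -> int:
    import shapely

    last = lo
    for i in range(lo, min(hi, len(frames))):
        if shapely.intersects_xy(poly, frames[i, 0], frames[i, 1]):
            last = i
    return last


def gen_trajectory(
    params: TrajectoryGenParams,
) -> tuple[Trajectory, list[BehaviorEvent]]:
    """Generate a trajectory realizing the scripted events.

    Returns the trajectory and the ground-truth event list (scripted events
    plus any transitions induced by returning home), each with onset/offset
    seconds and commanded peak speed.

    Raises
    ------
    ValueError
        For unknown arenas/event kinds, events outside the session, events
        incompatible with the arena geometry, or scripted events packed too
        closely to realize in order.
    """
    zones = make_arena(params.arena)
    rng = np.random.default_rng(params.seed)
    fps = params.fps
    n_total = int(round(params.duration_s * fps))

    if params.arena == "epm":
        home = np.array([0.0, 150.0])  # mid closed arm 1
        home_lo, home_hi = 60.0, 240.0
    else:
        home = np.array([0.0, 0.0])
        home_lo = home_hi = 0.0

    pb = _PathBuilder(home, fps)
    events: list[BehaviorEvent] = []

    def filler_until(frame: int) -> None:
        """Wander at walking speed inside the home region until `frame`."""
        while pb.n < frame:
            remaining = frame - pb.n
            if remaining * params.walk_speed / fps < 5.0:
                pb.dwell(remaining)
                break
            if params.arena == "epm":
                target = np.array([0.0, rng.uniform(home_lo, home_hi)])
            else:
                half = 100.0
                target = rng.uniform(-half, half, size=2)
            dist = np.linalg.norm(target - pb.pos)
            if dist / (params.walk_speed / fps) > remaining:
                # truncated move, then re-check
                frac = remaining * params.walk_speed / fps / dist
                target = pb.pos + (target - pb.pos) * frac
            pb.move_to(target, params.walk_speed)
            dwell = int(rng.integers(int(0.5 * fps), int(2.0 * fps)))
            pb.dwell(min(dwell, max(0, frame - pb.n)))

    def log(kind, onset_f, offset_f, peak, zs=()):
        events.append(
            BehaviorEvent(
                kind=kind,
                onset_s=onset_f / fps,
                offset_s=offset_f / fps,
                peak_speed=peak,
                zones=zs,
            )
        )

    def go_home_from_open() -> None:
        """Walk open arm -> centre -> closed arm; logs the induced transition."""
        frames_before = pb.n
        pb.move_to([0.0, 0.0], params.walk_speed)
        _, stop = pb.move_to([0.0, home_lo], params.walk_speed)
        arr = np.asarray(pb.frames)
        onset = _last_frame_in(arr, frames_before - 1, stop, zones["open_arm_1"])
        offset = _first_frame_in(arr, onset, zones["closed_arm_1"])
        log("open_to_closed_walk", onset, offset, params.walk_speed,
            ("open_arm_1", "closed_arm_1"))
        pb.move_to(home, params.walk_speed)

    for kind, t_ev in sorted(params.scripted_events, key=lambda e: e[1]):
        frame_ev = int(round(t_ev * fps))
        if frame_ev < pb.n:
            raise ValueError(
                f"scripted event {kind!r} at {t_ev} s overlaps the previous event"
            )
        filler_until(frame_ev)

        if kind == "fast_run":
            # long straight dash so the smoothed speed plateaus at run_speed
            if params.arena == "epm":
                pb.move_to([0.0, 235.0], params.walk_speed)
                a, b = pb.move_to([0.0, -150.0], params.run_speed)
            else:
                pb.move_to([-200.0, 0.0], params.walk_speed)
                a, b = pb.move_to([200.0, 0.0], params.run_speed)
            log("fast_running", a, b, params.run_speed)
            pb.dwell(int(1.0 * fps))

        elif kind.startswith("pause_then"):
            pb.move_to([0.0, 0.0], params.walk_speed)
            pb.dwell(int(round(params.pause_duration_s * fps)))
            exit_start = pb.n
            if kind == "pause_then_exit_open":
                _, arr_stop = pb.move_to([150.0, 0.0], params.walk_speed)
                arr = np.asarray(pb.frames)
                arrive = _first_frame_in(arr, exit_start, zones["open_arm_1"])
                log(kind, exit_start, arrive, params.walk_speed, ("center", "open_arm_1"))
                pb.dwell(int(1.0 * fps))
                go_home_from_open()
            else:
                # run/walk all the way home so the exit bout is long enough
                # for its smoothed speed to reach the commanded value
                speed = params.run_speed if kind.endswith("run") else params.walk_speed
                _, arr_stop = pb.move_to(home, speed)
                arr = np.asarray(pb.frames)
                arrive = _first_frame_in(arr, exit_start, zones["closed_arm_1"])
                log(kind, exit_start, arrive, speed, ("center", "closed_arm_1"))
                pb.dwell(int(0.5 * fps))

        elif kind.startswith("open_to_closed"):
            # walk out to the open arm first, then transition back
            pb.move_to([0.0, 0.0], params.walk_speed)
            pb.move_to([150.0, 0.0], params.walk_speed)
            pb.dwell(int(1.0 * fps))
            speed = params.run_speed if kind.endswith("run") else params.walk_speed
            frames_before = pb.n
            pb.move_to([0.0, 0.0], speed)
            _, stop = pb.move_to([0.0, home_lo], speed)
            arr = np.asarray(pb.frames)
            onset = _last_frame_in(arr, frames_before - 1, stop, zones["open_arm_1"])
            offset = _first_frame_in(arr, onset, zones["closed_arm_1"])
            log(kind, onset, offset, speed, ("open_arm_1", "closed_arm_1"))
            pb.move_to(home, params.walk_speed)

        elif kind == "open_arm_entry":
            pb.move_to([0.0, 0.0], params.walk_speed)
            frames_before = pb.n
            pb.move_to([150.0, 0.0], params.walk_speed)
            arr = np.asarray(pb.frames)
            enter = _first_frame_in(arr, frames_before, zones["open_arm_1"])
            log(kind, enter, pb.n - 1, params.walk_speed, ("open_arm_1",))
            pb.dwell(int(1.0 * fps))
            go_home_from_open()

    if pb.n > n_total:
        raise ValueError(
            "scripted events do not fit in duration_s "
            f"(needed {pb.n / fps:.1f} s, have {params.duration_s} s)"
        )
    filler_until(n_total)

    pos = np.asarray(pb.frames[:n_total])
    if params.jitter_mm > 0:
        pos = pos + rng.normal(0.0, params.jitter_mm, size=pos.shape)
    t = np.arange(n_total) / fps
    traj = Trajectory(
        t=t, x=pos[:, 0], y=pos[:, 1], fps=fps, zones=zones, arena_name=params.arena
    )
    return traj, events
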