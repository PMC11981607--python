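"""Behavioral measures and event detection from tracked positions and keypoints.

Covers the trajectory-derived readouts of the assays: zone occupancy and
entries, preference indices, speed, fast-running episodes (motion speed
strictly exceeding 400 mm/s), centre-pause outcome classification and
open-to-closed arm transitions in the elevated plus maze, and the normalized
pupil-size timecourse from eye keypoints.

Coordinates are millimetres with the origin at the arena centre; intervals
are half-open in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .arenas import CLOSED_ZONES, OPEN_ZONES

__all__ = [
    "Trajectory",
    "BehaviorEvent",
    "OccupancySummary",
    "PreferenceResult",
    "PupilTimecourse",
    "RUN_SPEED_THRESHOLD_MM_S",
    "compute_speed",
    "assign_zones",
    "zone_occupancy",
    "preference_indices",
    "detect_fast_running",
    "classify_center_pause_outcomes",
    "detect_open_to_closed_transitions",
    "pupil_timecourse",
]

#: Speed threshold (mm/s) separating running from walking and defining
#: fast-running episodes.  The comparison is strict (speed must exceed it).
RUN_SPEED_THRESHOLD_MM_S = 400.0


@dataclass
class Trajectory:
    """Timestamped 2-D positions plus named arena zone polygons."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float
    zones: dict  # zone name -> shapely Polygon
    arena_name: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("positions must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class BehaviorEvent:
    """A detected (or scripted) behavioral event."""

    kind: str
    onset_s: float
    offset_s: float
    peak_speed: float = 0.0
    zones: tuple = ()

    def __post_init__(self) -> None:
        if self.offset_s < self.onset_s:
            raise ValueError("offset_s must be >= onset_s")
        if self.peak_speed < 0:
            raise ValueError("peak_speed must be >= 0")


@dataclass
class OccupancySummary:
    """Per-zone occupancy times and entry counts plus total path length."""

    zone_time_s: dict
    zone_entries: dict
    total_distance_mm: float
    duration_s: float
    n_outside_warnings: int = 0


@dataclass
class PreferenceResult:
    """A preference ratio with its raw numerator/denominator.

    ``defined`` is False when the denominator is zero, in which case
    ``ratio`` is NaN rather than infinity.
    """

    assay: str
    ratio: float
    numerator: float
    denominator: float
    defined: bool = True


@dataclass
class PupilTimecourse:
    """Normalized pupil and eye size over a light on/off stimulation cycle."""

    t: np.ndarray
    diameter_norm: np.ndarray
    area_norm: np.ndarray
    eye_norm: np.ndarray
    samples: dict = field(default_factory=dict)  # {'pre','light','post'} -> diameter_norm
    n_interpolated: int = 0


# ---------------------------------------------------------------------------
# kinematics


def _adaptive_centered_mean(v: np.ndarray, half: int) -> np.ndarray:
    """Centered moving average whose window shrinks symmetrically at the edges.

    Exact (bias-free) for affine sequences at every index, unlike padding-based
    filters.
    """
    if half <= 0:
        return v.astype(float)
    n = len(v)
    csum = np.concatenate(([0.0], np.cumsum(v, dtype=float)))
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - h, idx + h + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth_positions(traj: Trajectory, smooth_window_s: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving-average smoothing of x and y."""
    half = int(round(smooth_window_s * traj.fps / 2.0))
    return (
        _adaptive_centered_mean(traj.x, half),
        _adaptive_centered_mean(traj.y, half),
    )


def compute_speed(traj: Trajectory, smooth_window_s: float = 0.2) -> np.ndarray:
    """Instantaneous speed in mm/s after position smoothing.

    Positions are smoothed with a centered moving average of the given
    duration, then differentiated with central finite differences (one-sided
    at the endpoints).  Output length equals the frame count.

    Raises
    ------
    ValueError
        If the trajectory has fewer than two frames.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to compute speed")
    xs, ys = smooth_positions(traj, smooth_window_s)
    dt = 1.0 / traj.fps
    return np.hypot(np.gradient(xs, dt), np.gradient(ys, dt))


def path_length(traj: Trajectory, smooth_window_s: float = 0.2) -> float:
    """Total distance (mm) along the smoothed path polyline."""
    xs, ys = smooth_positions(traj, smooth_window_s)
    return float(np.sum(np.hypot(np.diff(xs), np.diff(ys))))


# ---------------------------------------------------------------------------
# zones


def assign_zones(traj: Trajectory) -> tuple[np.ndarray, list, int]:
    """Assign every frame to a zone by point-in-polygon.

    Returns ``(zone_index, zone_names, n_outside)`` where ``zone_index[i]``
    indexes into ``zone_names``.  A point covered by several zones (shared
    boundary) goes to the first zone in insertion order; a point outside all
    zones goes to the nearest zone and is counted in ``n_outside``.
    """
    names = list(traj.zones)
    n = traj.n_frames
    zone_idx = np.full(n, -1, dtype=int)
    for j, name in enumerate(names):
        unassigned = zone_idx < 0
        if not unassigned.any():
            break
        hit = shapely.intersects_xy(traj.zones[name], traj.x[unassigned], traj.y[unassigned])
        sel = np.flatnonzero(unassigned)[hit]
        zone_idx[sel] = j
    outside = np.flatnonzero(zone_idx < 0)
    for i in outside:
        p = shapely.points(traj.x[i], traj.y[i])
        dists = [traj.zones[name].distance(p) for name in names]
        zone_idx[i] = int(np.argmin(dists))
    return zone_idx, names, len(outside)


def _runs(seq: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encode an int sequence as (value, start, stop) half-open."""
    out = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            out.append((int(seq[start]), start, i))
            start = i
    return out


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _debounced_runs(zone_idx: np.ndarray, min_dwell: int) -> list[tuple[int, int, int]]:
    """Zone visit sequence after dropping dwells shorter than min_dwell frames."""
    runs = [r for r in _runs(zone_idx) if r[2] - r[1] >= min_dwell]
    merged: list[tuple[int, int, int]] = []
    for r in runs:
        if merged and merged[-1][0] == r[0]:
            merged[-1] = (r[0], merged[-1][1], r[2])
        else:
            merged.append(r)
    return merged


def zone_occupancy(
    traj: Trajectory,
    min_dwell_frames: int = 3,
    smooth_window_s: float = 0.2,
) -> OccupancySummary:
    """Per-zone occupancy time, entry counts, and total distance travelled.

    Occupancy time is frame count divided by fps, so zone times sum to the
    session duration.  An entry is a transition into a zone whose dwell lasts
    at least ``min_dwell_frames`` (debouncing boundary jitter); the starting
    zone is not counted as an entry.
    """
    zone_idx, names, n_outside = assign_zones(traj)
    counts = np.bincount(zone_idx, minlength=len(names))
    zone_time = {name: counts[j] / traj.fps for j, name in enumerate(names)}

    entries = dict.fromkeys(names, 0)
    visits = _debounced_runs(zone_idx, min_dwell_frames)
    for prev, cur in zip(visits, visits[1:]):
        entries[names[cur[0]]] += 1

    return OccupancySummary(
        zone_time_s=zone_time,
        zone_entries=entries,
        total_distance_mm=path_length(traj, smooth_window_s),
        duration_s=traj.duration_s,
        n_outside_warnings=n_outside,
    )


def preference_indices(
    assay: str,
    occ: OccupancySummary | None = None,
    roles: dict | None = None,
    sucrose_ml: float | None = None,
    water_ml: float | None = None,
) -> PreferenceResult:
    """Preference ratio for the three-chamber (tct), female-encounter (fet)
    or sucrose-preference (spt) assay.

    * ``tct``: time(stranger zone) / time(object zone)
    * ``fet``: time(female zone) / time(male zone)
    * ``spt``: sucrose_ml / (sucrose_ml + water_ml)

    For tct/fet, ``roles`` maps role names (``stranger``/``object`` or
    ``female``/``male``) to zone names in ``occ``.  A zero denominator yields
    ``defined=False`` and a NaN ratio, never infinity.
    """
    if assay == "spt":
        if sucrose_ml is None or water_ml is None:
            raise ValueError("spt requires sucrose_ml and water_ml")
        num, den = sucrose_ml, sucrose_ml + water_ml
    elif assay in ("tct", "fet"):
        if occ is None or roles is None:
            raise ValueError(f"{assay} requires an OccupancySummary and roles mapping")
        top, bottom = ("stranger", "object") if assay == "tct" else ("female", "male")
        num = occ.zone_time_s[roles[top]]
        den = occ.zone_time_s[roles[bottom]]
    else:
        raise ValueError(f"unknown assay {assay!r}")
    if den == 0:
        return PreferenceResult(assay, float("nan"), num, den, defined=False)
    return PreferenceResult(assay, num / den, num, den)


# ---------------------------------------------------------------------------
# event detectors


def detect_fast_running(
    speed: np.ndarray,
    fps: float,
    threshold_mm_s: float = RUN_SPEED_THRESHOLD_MM_S,
    min_dur_s: float = 0.25,
    merge_gap_s: float = 0.2,
) -> list[BehaviorEvent]:
    """Fast-running episodes: maximal runs of frames with speed strictly
    exceeding ``threshold_mm_s``, merged across gaps shorter than
    ``merge_gap_s`` and kept if lasting at least ``min_dur_s``.
    """
    if threshold_mm_s <= 0:
        raise ValueError("threshold must be > 0")
    speed = np.asarray(speed, dtype=float)
    above = speed > threshold_mm_s  # strict
    runs = _bool_runs(above)
    gap = int(round(merge_gap_s * fps))
    merged: list[tuple[int, int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    min_frames = max(1, int(round(min_dur_s * fps)))
    events = []
    for a, b in merged:
        if b - a < min_frames:
            continue
        events.append(
            BehaviorEvent(
                kind="fast_running",
                onset_s=a / fps,
                offset_s=b / fps,
                peak_speed=float(np.max(speed[a:b])),
            )
        )
    return events


def _require_epm(zones: dict) -> None:
    missing = [z for z in OPEN_ZONES + CLOSED_ZONES + ("center",) if z not in zones]
    if missing:
        raise ValueError(f"EPM arena required; missing zones {missing}")


def _locomotion_class(peak_speed: float) -> str:
    return "run" if peak_speed >= RUN_SPEED_THRESHOLD_MM_S else "walk"


def classify_center_pause_outcomes(
    traj: Trajectory,
    speed: np.ndarray,
    pause_speed_mm_s: float = 20.0,
    pause_min_s: float = 0.5,
    onset_radius_mm: float = 5.0,
    class_pad_s: float = 0.2,
) -> list[BehaviorEvent]:
    """Classify centre-zone pauses in the EPM by where the animal goes next.

    A pause is a dwell in the centre zone with speed below
    ``pause_speed_mm_s`` lasting at least ``pause_min_s``.  The outcome is
    labelled by the first arm entered after the pause and by the locomotion
    class of the exit bout (peak speed at or above the run threshold = run):

    * ``pause_then_return_run`` / ``pause_then_return_walk`` — back to a
      closed arm,
    * ``pause_then_exit_open`` — out to an open arm.

    Events are timestamped at exit onset so peri-event signal alignment is
    at the moment the decision is acted on.  Because position smoothing
    makes the speed trace rise a few frames before true movement, exit onset
    is refined to the first frame whose raw position leaves an
    ``onset_radius_mm`` circle around the pause centroid.  The run/walk
    label uses the peak speed from exit onset to ``class_pad_s`` beyond arm
    arrival (the exit bout continues into the arm).

    Raises
    ------
    ValueError
        If the trajectory's zones are not an EPM layout.
    """
    _require_epm(traj.zones)
    zone_idx, names, _ = assign_zones(traj)
    center_j = names.index("center")
    open_j = {names.index(z) for z in OPEN_ZONES}
    closed_j = {names.index(z) for z in CLOSED_ZONES}
    arm_j = open_j | closed_j
    speed = np.asarray(speed)
    pad = int(round(class_pad_s * traj.fps))

    pause_mask = (zone_idx == center_j) & (speed < pause_speed_mm_s)
    min_frames = max(1, int(round(pause_min_s * traj.fps)))
    events: list[BehaviorEvent] = []
    scan_from = 0
    for a, b in _bool_runs(pause_mask):
        if b - a < min_frames or a < scan_from:
            continue
        # first arm frame after the pause
        after = zone_idx[b:]
        arm_hits = np.flatnonzero(np.isin(after, list(arm_j)))
        if arm_hits.size == 0:
            continue
        arrive = b + int(arm_hits[0])
        dest = zone_idx[arrive]
        # refine exit onset: first raw position leaving the pause centroid
        cx, cy = np.mean(traj.x[a:b]), np.mean(traj.y[a:b])
        moved = np.hypot(traj.x[a:arrive + 1] - cx, traj.y[a:arrive + 1] - cy) > onset_radius_mm
        onset = a + int(np.argmax(moved)) if moved.any() else b
        bout_peak = float(np.max(speed[onset : min(arrive + 1 + pad, len(speed))]))
        if dest in closed_j:
            kind = f"pause_then_return_{_locomotion_class(bout_peak)}"
        else:
            kind = "pause_then_exit_open"
        events.append(
            BehaviorEvent(
                kind=kind,
                onset_s=onset / traj.fps,
                offset_s=arrive / traj.fps,
                peak_speed=bout_peak,
                zones=("center", names[dest]),
            )
        )
        scan_from = arrive
    return events


def detect_open_to_closed_transitions(
    traj: Trajectory,
    speed: np.ndarray,
    min_dwell_frames: int = 3,
) -> list[BehaviorEvent]:
    """Open-arm to closed-arm transitions in the EPM, labelled run/walk.

    A transition is a debounced open-arm visit followed — possibly through the
    centre — by a closed-arm visit with no intervening open-arm re-entry.
    Onset is the last open-arm frame (arm exit), offset the first closed-arm
    frame; the event is labelled by the peak speed of that bout.  Transitions
    in the closed-to-open direction are not emitted.
    """
    _require_epm(traj.zones)
    zone_idx, names, _ = assign_zones(traj)
    open_j = {names.index(z) for z in OPEN_ZONES}
    closed_j = {names.index(z) for z in CLOSED_ZONES}

    visits = _debounced_runs(zone_idx, min_dwell_frames)
    events: list[BehaviorEvent] = []
    for i, (zj, a, b) in enumerate(visits):
        if zj not in open_j:
            continue
        for nz, na, nb in visits[i + 1 :]:
            if nz in open_j:
                break  # re-entered an open arm first
            if nz in closed_j:
                onset = b - 1  # last open-arm frame
                offset = na
                bout_peak = float(np.max(speed[onset : offset + 1]))
                events.append(
                    BehaviorEvent(
                        kind=f"open_to_closed_{_locomotion_class(bout_peak)}",
                        onset_s=onset / traj.fps,
                        offset_s=offset / traj.fps,
                        peak_speed=bout_peak,
                        zones=(names[zj], names[nz]),
                    )
                )
                break
    return events


# ---------------------------------------------------------------------------
# pupil


_PUPIL_PAIRS = (("pupil_left", "pupil_right"), ("pupil_top", "pupil_bottom"))
_EYELID_PAIR = ("eyelid_top", "eyelid_bottom")


def _interp_low_likelihood(
    series: np.ndarray, good: np.ndarray, fps: float, max_gap_s: float
) -> np.ndarray:
    """Linearly interpolate samples flagged bad; error on gaps beyond limit."""
    if good.all():
        return series
    for a, b in _bool_runs(~good):
        if (b - a) / fps > max_gap_s:
            raise ValueError(
                f"low-likelihood gap of {(b - a) / fps:.2f} s at "
                f"[{a / fps:.2f}, {b / fps:.2f}) s exceeds {max_gap_s} s limit"
            )
    idx = np.arange(len(series))
    out = series.copy()
    out[~good] = np.interp(idx[~good], idx[good], series[good])
    return out


def pupil_timecourse(
    keypoints: pd.DataFrame,
    fps: float = 30.0,
    light_on_s: float = 10.0,
    light_off_s: float = 20.0,
    sample_times_s: tuple[float, float, float] = (5.0, 15.0, 25.0),
    likelihood_min: float = 0.9,
    max_gap_s: float = 1.0,
) -> PupilTimecourse:
    """Normalized pupil and eye size over a light off/on/off cycle.

    ``keypoints`` has MultiIndex columns ``(bodypart, {'x','y','likelihood'})``
    with pupil boundary points (pupil_left/right/top/bottom) and eyelid points
    (eyelid_top/bottom) at 30 fps.  Pupil diameter is the mean distance of the
    two opposing point pairs; area is the ellipse pi/4 * d1 * d2 (the size
    metric is reported both ways).  All series are normalized to their mean
    over the pre-light period, and the normalized diameter is sampled at the
    pre/light/post timepoints (defaults 5, 15, 25 s).

    Low-likelihood samples are linearly interpolated when the gap is at most
    ``max_gap_s``; longer gaps raise an error naming the gap.
    """
    n = len(keypoints)
    t = np.arange(n) / fps
    parts = [p for pair in _PUPIL_PAIRS for p in pair] + list(_EYELID_PAIR)
    missing = [p for p in parts if p not in keypoints.columns.get_level_values(0)]
    if missing:
        raise ValueError(f"missing keypoints {missing}")

    coords: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    n_interp = 0
    for p in parts:
        like = keypoints[(p, "likelihood")].to_numpy(dtype=float)
        good = like >= likelihood_min
        n_interp += int((~good).sum())
        x = _interp_low_likelihood(keypoints[(p, "x")].to_numpy(dtype=float), good, fps, max_gap_s)
        y = _interp_low_likelihood(keypoints[(p, "y")].to_numpy(dtype=float), good, fps, max_gap_s)
        coords[p] = (x, y)

    def dist(a: str, b: str) -> np.ndarray:
        return np.hypot(coords[a][0] - coords[b][0], coords[a][1] - coords[b][1])

    d1 = dist(*_PUPIL_PAIRS[0])
    d2 = dist(*_PUPIL_PAIRS[1])
    diameter = 0.5 * (d1 + d2)
    area = np.pi / 4.0 * d1 * d2
    eye = dist(*_EYELID_PAIR)

    pre = t < light_on_s
    if not pre.any():
        raise ValueError("no pre-light frames to normalize against")

    def norm(v: np.ndarray) -> np.ndarray:
        ref = float(np.mean(v[pre]))
        if ref == 0:
            raise ValueError("zero pre-period mean; cannot normalize")
        return v / ref

    diameter_n, area_n, eye_n = norm(diameter), norm(area), norm(eye)
    labels = ("pre", "light", "post")
    samples = {}
    for lab, ts in zip(labels, sample_times_s):
        i = int(round(ts * fps))
        if not 0 <= i < n:
            raise ValueError(f"sample time {ts} s outside recording")
        samples[lab] = float(diameter_n[i])
    return PupilTimecourse(
        t=t,
        diameter_norm=diameter_n,
        area_norm=area_n,
        eye_norm=eye_n,
        samples=samples,
        n_interpolated=n_interp,
    )
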