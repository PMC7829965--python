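"""Trajectory kinematics: movement segmentation and summary statistics.

A calibrated centroid trajectory is reduced to per-step displacements, a
moving/immobile segmentation, and five summary statistics:

* traveled distance — cumulative displacement over moving steps,
* effective velocity — distance divided by time spent moving,
* mean acceleration — mean positive step-to-step speed increment,
* stops — immobile runs flanked by movement on both sides,
* distance/stop — distance divided by the stop count.

All distances are centimetres, times seconds. The immobility threshold
``epsilon_cm`` is a free parameter of every analysis and is carried in the
outputs; there is no hidden default inside the computations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "MovementSegmentation",
    "KinematicSummary",
    "StraightSegment",
    "TrajectoryError",
    "segment_movement",
    "traveled_distance",
    "effective_velocity",
    "mean_acceleration",
    "count_stops",
    "distance_per_stop",
    "summarize",
    "bin_by_minute",
    "straight_walk_segments",
    "turning_events",
]

#: Default immobility threshold (cm per step); sub-body-scale centroid jitter.
DEFAULT_EPSILON_CM = 0.3

_DT_TOL_S = 1e-6


class TrajectoryError(ValueError):
    """Raised for structurally invalid trajectories."""


def _seq_sum(values) -> float:
    """Strict left-to-right float accumulation (reproducible step order)."""
    total = 0.0
    for v in values:
        total += float(v)
    return total


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped 2-D centroid path in arena coordinates (cm).

    Timestamps must be strictly increasing with a uniform step (tolerance
    1e-6 s) and at least two frames are required.
    """

    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    subject_id: str = ""
    group_label: str = ""
    test_stage: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        x = np.asarray(self.x_cm, dtype=float)
        y = np.asarray(self.y_cm, dtype=float)
        if not (t.ndim == x.ndim == y.ndim == 1):
            raise TrajectoryError("t_s, x_cm, y_cm must be 1-D")
        if not (len(t) == len(x) == len(y)):
            raise TrajectoryError("t_s, x_cm, y_cm must have equal length")
        if len(t) < 2:
            raise TrajectoryError("trajectory needs at least 2 frames")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise TrajectoryError("coordinates and timestamps must be finite")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise TrajectoryError("timestamps must be strictly increasing")
        if np.max(steps) - np.min(steps) > _DT_TOL_S:
            raise TrajectoryError("timestamps must be uniformly spaced")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "x_cm", x)
        object.__setattr__(self, "y_cm", y)

    @property
    def n_frames(self) -> int:
        return len(self.t_s)

    @property
    def dt_s(self) -> float:
        return float(self.t_s[1] - self.t_s[0])

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    def points(self) -> np.ndarray:
        """Return an (n, 2) array of (x, y) positions."""
        return np.column_stack([self.x_cm, self.y_cm])

    def reversed(self) -> "Trajectory":
        """Time-reversed copy (same timestamps, reversed path)."""
        return Trajectory(
            t_s=self.t_s.copy(),
            x_cm=self.x_cm[::-1].copy(),
            y_cm=self.y_cm[::-1].copy(),
            subject_id=self.subject_id,
            group_label=self.group_label,
            test_stage=self.test_stage,
        )

    def scaled(self, c: float) -> "Trajectory":
        """Copy with all coordinates multiplied by ``c``."""
        return Trajectory(
            t_s=self.t_s.copy(),
            x_cm=self.x_cm * c,
            y_cm=self.y_cm * c,
            subject_id=self.subject_id,
            group_label=self.group_label,
            test_stage=self.test_stage,
        )

    def frame_slice(self, start: int, stop: int) -> "Trajectory":
        """Sub-trajectory over frames [start, stop)."""
        return Trajectory(
            t_s=self.t_s[start:stop].copy(),
            x_cm=self.x_cm[start:stop].copy(),
            y_cm=self.y_cm[start:stop].copy(),
            subject_id=self.subject_id,
            group_label=self.group_label,
            test_stage=self.test_stage,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "t_s": self.t_s,
                "x_cm": self.x_cm,
                "y_cm": self.y_cm,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, subject_id: str = "", group_label: str = "",
                 test_stage: str = "") -> "Trajectory":
        df = pd.read_csv(path)
        required = {"t_s", "x_cm", "y_cm"}
        if not required.issubset(df.columns):
            raise TrajectoryError(
                f"trajectory CSV must have columns {sorted(required)}; got {list(df.columns)}"
            )
        return cls(
            t_s=df["t_s"].to_numpy(float),
            x_cm=df["x_cm"].to_numpy(float),
            y_cm=df["y_cm"].to_numpy(float),
            subject_id=subject_id,
            group_label=group_label,
            test_stage=test_stage,
        )


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) index pairs."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


@dataclass(frozen=True)
class MovementSegmentation:
    """Per-step moving/immobile labelling of a trajectory.

    ``step_displacement_cm[i]`` is the Euclidean displacement between frames
    ``i`` and ``i+1``; a step is moving iff its displacement strictly exceeds
    ``epsilon_cm``. Bouts are maximal runs of moving steps; stop events are
    maximal immobile runs flanked by bouts on both sides.
    """

    step_displacement_cm: np.ndarray
    moving: np.ndarray
    epsilon_cm: float
    dt_s: float
    bouts: tuple[tuple[int, int], ...]
    stop_events: tuple[tuple[int, int], ...]

    @property
    def n_steps(self) -> int:
        return len(self.step_displacement_cm)

    @property
    def n_moving_steps(self) -> int:
        return int(np.count_nonzero(self.moving))

    @property
    def moving_time_s(self) -> float:
        return self.n_moving_steps * self.dt_s


def segment_movement(traj: Trajectory, epsilon_cm: float = DEFAULT_EPSILON_CM) -> MovementSegmentation:
    """Split a trajectory into moving/immobile steps, bouts and stop events."""
    if epsilon_cm < 0:
        raise ValueError("epsilon_cm must be >= 0")
    if traj.n_frames < 2:
        raise TrajectoryError("trajectory needs at least 2 frames")
    dx = np.diff(traj.x_cm)
    dy = np.diff(traj.y_cm)
    disp = np.sqrt(dx * dx + dy * dy)
    moving = disp > epsilon_cm
    bouts = _bool_runs(moving)
    stop_events: list[tuple[int, int]] = []
    for (s0, e0), (s1, _e1) in zip(bouts, bouts[1:]):
        stop_events.append((e0 + 1, s1 - 1))
    return MovementSegmentation(
        step_displacement_cm=disp,
        moving=moving,
        epsilon_cm=float(epsilon_cm),
        dt_s=traj.dt_s,
        bouts=tuple(bouts),
        stop_events=tuple(stop_events),
    )


def traveled_distance(seg: MovementSegmentation, include_jitter: bool = False) -> float:
    """Cumulative displacement; by default only moving steps contribute."""
    if include_jitter:
        return _seq_sum(seg.step_displacement_cm)
    return _seq_sum(seg.step_displacement_cm[seg.moving])


def effective_velocity(seg: MovementSegmentation, dt_s: float | None = None) -> float:
    """Distance over time actually spent moving; NaN when never moving."""
    dt = seg.dt_s if dt_s is None else float(dt_s)
    if dt <= 0:
        raise ValueError("dt_s must be > 0")
    n_moving = seg.n_moving_steps
    if n_moving == 0:
        return math.nan
    return traveled_distance(seg) / (n_moving * dt)


def mean_acceleration(
    seg: MovementSegmentation,
    dt_s: float | None = None,
    positive_only_denominator: bool = True,
) -> float:
    """Mean positive step-to-step speed increment over moving step pairs.

    Speed deltas are taken only across consecutive step pairs that are both
    moving (never across a stop). With the default reading, the mean runs
    over the positive deltas only; the alternative averages ``max(dv, 0)``
    over all consecutive moving pairs. NaN when fewer than two consecutive
    moving steps exist; 0.0 when pairs exist but no delta is positive.
    """
    dt = seg.dt_s if dt_s is None else float(dt_s)
    if dt <= 0:
        raise ValueError("dt_s must be > 0")
    disp = seg.step_displacement_cm
    moving = seg.moving
    pos_sum = 0.0
    n_pos = 0
    n_pairs = 0
    for i in range(len(disp) - 1):
        if moving[i] and moving[i + 1]:
            n_pairs += 1
            dv = (disp[i + 1] - disp[i]) / dt
            if dv > 0:
                pos_sum += dv
                n_pos += 1
    if n_pairs == 0:
        return math.nan
    if positive_only_denominator:
        if n_pos == 0:
            return 0.0
        return (pos_sum / n_pos) / dt
    return (pos_sum / n_pairs) / dt


def count_stops(seg: MovementSegmentation) -> int:
    """Number of immobile runs flanked by movement on both sides."""
    return len(seg.stop_events)


def distance_per_stop(total_distance_cm: float, stops: int) -> float:
    """Distance divided by stop count; NaN when there are no stops."""
    if stops == 0:
        return math.nan
    return total_distance_cm / stops


@dataclass(frozen=True)
class KinematicSummary:
    """The five kinematic statistics over one frame subset."""

    traveled_distance_cm: float
    effective_velocity_cm_s: float
    mean_acceleration_cm_s2: float
    stops: int
    distance_per_stop_cm: float
    moving_time_s: float
    n_steps: int
    n_moving_steps: int
    epsilon_cm: float
    degenerate: bool

    def as_dict(self) -> dict:
        return {
            "distance_cm": self.traveled_distance_cm,
            "eff_vel_cm_s": self.effective_velocity_cm_s,
            "mean_acc_cm_s2": self.mean_acceleration_cm_s2,
            "stops": self.stops,
            "dist_per_stop_cm": self.distance_per_stop_cm,
            "moving_time_s": self.moving_time_s,
            "n_steps": self.n_steps,
            "n_moving_steps": self.n_moving_steps,
            "epsilon_cm": self.epsilon_cm,
            "degenerate": self.degenerate,
        }


#: Canonical statistic names in summary/report tables.
STATISTICS = ("distance_cm", "eff_vel_cm_s", "mean_acc_cm_s2", "stops", "dist_per_stop_cm")


def summarize_segmentation(
    seg: MovementSegmentation,
    include_jitter: bool = False,
    positive_only_denominator: bool = True,
) -> KinematicSummary:
    """All five statistics from one segmentation pass."""
    dist = traveled_distance(seg, include_jitter=include_jitter)
    stops = count_stops(seg)
    degenerate = seg.n_moving_steps == 0
    return KinematicSummary(
        traveled_distance_cm=dist,
        effective_velocity_cm_s=effective_velocity(seg),
        mean_acceleration_cm_s2=mean_acceleration(
            seg, positive_only_denominator=positive_only_denominator
        ),
        stops=stops,
        distance_per_stop_cm=distance_per_stop(dist, stops),
        moving_time_s=seg.moving_time_s,
        n_steps=seg.n_steps,
        n_moving_steps=seg.n_moving_steps,
        epsilon_cm=seg.epsilon_cm,
        degenerate=degenerate,
    )


def summarize(
    traj: Trajectory,
    epsilon_cm: float = DEFAULT_EPSILON_CM,
    include_jitter: bool = False,
    positive_only_denominator: bool = True,
) -> KinematicSummary:
    """Segment ``traj`` and compute the five statistics."""
    seg = segment_movement(traj, epsilon_cm)
    return summarize_segmentation(
        seg,
        include_jitter=include_jitter,
        positive_only_denominator=positive_only_denominator,
    )


_EMPTY_BIN = dict(
    traveled_distance_cm=0.0,
    effective_velocity_cm_s=math.nan,
    mean_acceleration_cm_s2=math.nan,
    stops=0,
    distance_per_stop_cm=math.nan,
    moving_time_s=0.0,
    n_steps=0,
    n_moving_steps=0,
    degenerate=True,
)


def bin_by_minute(
    traj: Trajectory,
    epsilon_cm: float = DEFAULT_EPSILON_CM,
    bin_s: float = 60.0,
    **summary_kwargs,
) -> list[KinematicSummary]:
    """Summaries over half-open windows [k*bin_s, (k+1)*bin_s) of session time.

    Each bin is segmented independently, so a stop spanning a bin boundary is
    counted in neither bin, and per-bin distances can differ from the whole
    session by at most one boundary step per boundary. A trailing remainder
    of fewer than two frames (e.g. the single frame at exactly t = k*bin_s
    closing a session) carries no step and is dropped.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    rel = traj.t_s - traj.t_s[0]
    idx = np.floor(rel / bin_s + 1e-12).astype(int)
    summaries: list[KinematicSummary] = []
    for k in range(idx.max() + 1):
        sel = np.flatnonzero(idx == k)
        if len(sel) >= 2:
            sub = traj.frame_slice(sel[0], sel[-1] + 1)
            summaries.append(summarize(sub, epsilon_cm, **summary_kwargs))
        elif k < idx.max():
            summaries.append(KinematicSummary(epsilon_cm=epsilon_cm, **_EMPTY_BIN))
    return summaries


@dataclass(frozen=True)
class StraightSegment:
    """A maximal run of moving steps walked in a near-straight line."""

    start_frame: int
    end_frame: int
    path_length_cm: float
    duration_s: float
    straightness: float
    walking_velocity_cm_s: float


def straight_walk_segments(
    traj: Trajectory,
    min_steps: int = 3,
    straightness_min: float = 0.95,
    epsilon_cm: float = DEFAULT_EPSILON_CM,
) -> list[StraightSegment]:
    """Detect near-straight walking segments of at least ``min_steps`` steps.

    Within each movement bout, every step window of length >= ``min_steps``
    whose straightness (net displacement / path length) reaches
    ``straightness_min`` qualifies; only windows not contained in a larger
    qualifying window are reported.
    """
    if min_steps < 2:
        raise ValueError("min_steps must be >= 2")
    if not (0 < straightness_min <= 1):
        raise ValueError("straightness_min must be in (0, 1]")
    seg = segment_movement(traj, epsilon_cm)
    disp = seg.step_displacement_cm
    x, y = traj.x_cm, traj.y_cm
    dt = traj.dt_s
    out: list[StraightSegment] = []
    for b0, b1 in seg.bouts:  # inclusive step indices
        length = b1 - b0 + 1
        if length < min_steps:
            continue
        # prefix path length over steps of this bout
        prefix = np.concatenate([[0.0], np.cumsum(disp[b0 : b1 + 1])])

        def straightness(i: int, j: int) -> float:
            # window covers steps i..j (bout-local), frames b0+i .. b0+j+1
            path = prefix[j + 1] - prefix[i]
            if path == 0:
                return 0.0
            f0, f1 = b0 + i, b0 + j + 1
            net = math.hypot(x[f1] - x[f0], y[f1] - y[f0])
            return min(net / path, 1.0)

        jmax = {}
        for i in range(length - min_steps + 1):
            best = -1
            for j in range(i + min_steps - 1, length):
                if straightness(i, j) >= straightness_min:
                    best = j
            if best >= 0:
                jmax[i] = best
        running = -1
        for i in sorted(jmax):
            j = jmax[i]
            if j > running:
                path = prefix[j + 1] - prefix[i]
                n = j - i + 1
                out.append(
                    StraightSegment(
                        start_frame=b0 + i,
                        end_frame=b0 + j + 1,
                        path_length_cm=float(path),
                        duration_s=n * dt,
                        straightness=straightness(i, j),
                        walking_velocity_cm_s=float(path) / (n * dt),
                    )
                )
            running = max(running, j)
    return out


def turning_events(
    traj: Trajectory,
    window_s: float = 3.0,
    epsilon_cm: float = DEFAULT_EPSILON_CM,
    tolerance_deg: float = 15.0,
    arena=None,
) -> tuple[int, int] | dict:
    """Count returns (~180 deg turns) and circlings (~360 deg turns).

    Heading is taken per moving step; signed heading changes are accumulated
    over a sliding time window. Accumulated turning of at least
    ``360 - tolerance_deg`` with consistent sign counts as a circling (and
    consumes its steps); an accumulation ending in ``[180 - tolerance_deg,
    360 - tolerance_deg)`` counts as a return. This automates what the
    original protocol scored visually; thresholds are heuristic.

    Returns ``(returns, circlings)``, or a per-role dict (plus a ``"total"``
    entry) when ``arena`` is given.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    seg = segment_movement(traj, epsilon_cm)
    dt = traj.dt_s
    moving_steps = np.flatnonzero(seg.moving)
    returns = 0
    circlings = 0
    per_role: dict[str, list[int]] = {}

    def _role_at(frame: int) -> str:
        from .arenas import assign_zone  # local import; avoids module cycle

        if arena is None:
            return "total"
        zid = assign_zone((traj.x_cm[frame], traj.y_cm[frame]), arena)
        if zid is None:
            return "unassigned"
        return arena.zone_by_id(zid).role

    def _record(kind: int, frame: int) -> None:
        nonlocal returns, circlings
        if kind == 0:
            returns += 1
        else:
            circlings += 1
        if arena is not None:
            per_role.setdefault(_role_at(frame), [0, 0])[kind] += 1

    headings = {}
    for i in moving_steps:
        headings[i] = math.degrees(
            math.atan2(traj.y_cm[i + 1] - traj.y_cm[i], traj.x_cm[i + 1] - traj.x_cm[i])
        )
    circle_thr = 360.0 - tolerance_deg
    return_thr = 180.0 - tolerance_deg
    acc: list[tuple[float, float]] = []  # (time, signed heading change)
    cum = 0.0
    prev_step = None
    for i in moving_steps:
        if prev_step is not None:
            d = headings[i] - headings[prev_step]
            d = (d + 180.0) % 360.0 - 180.0
            t = traj.t_s[i]
            # evict turning older than the window
            while acc and t - acc[0][0] > window_s:
                cum -= acc.pop(0)[1]
            if cum != 0 and d != 0 and (d > 0) != (cum > 0) and abs(d) > tolerance_deg:
                if abs(cum) >= return_thr:
                    _record(0, i)
                acc = []
                cum = 0.0
            acc.append((t, d))
            cum += d
            if abs(cum) >= circle_thr:
                _record(1, i)
                acc = []
                cum = 0.0
        prev_step = i
    if abs(cum) >= return_thr:
        _record(0, int(moving_steps[-1]) if len(moving_steps) else 0)
    if arena is not None:
        out = {role: (r, c) for role, (r, c) in per_role.items()}
        out["total"] = (returns, circlings)
        return out
    return returns, circlings
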