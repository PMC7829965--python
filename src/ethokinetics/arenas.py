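"""Arena geometries, zone assignment, occupancy and per-zone kinematics.

Three behavioral-test geometries are built in: a square open field with a
3x3 quadrant grid, a three-chamber social apparatus, and an elevated plus
maze. Zones are axis-aligned rectangles in arena coordinates (cm, origin
top-left, y downward). Rectangles are half-open ``[x0, x1) x [y0, y1)``
except along the outer arena boundary, which is inclusive, so the arena is
partitioned without double counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .kinematics import (
    KinematicSummary,
    MovementSegmentation,
    Trajectory,
    _seq_sum,
    distance_per_stop,
    segment_movement,
    DEFAULT_EPSILON_CM,
)

__all__ = [
    "Zone",
    "ArenaSpec",
    "ZoneOccupancy",
    "SocialRatioReport",
    "ArenaConfigError",
    "ZONE_ROLES",
    "make_open_field",
    "make_three_chamber",
    "make_epm",
    "assign_zone",
    "zone_occupancy",
    "per_zone_kinematics",
    "social_preference",
    "social_ratio_report",
]

ZONE_ROLES = frozenset(
    {
        "corner",
        "center",
        "chamber_social",
        "chamber_center",
        "chamber_empty",
        "arm_open",
        "arm_closed",
        "hub",
        "other",
    }
)

UNASSIGNED = None


class ArenaConfigError(ValueError):
    """Raised for inconsistent arena configurations."""


@dataclass(frozen=True)
class Zone:
    zone_id: str
    rect: tuple[float, float, float, float]  # x0, y0, x1, y1 (cm)
    role: str

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rect
        if not (x1 > x0 and y1 > y0):
            raise ArenaConfigError(f"zone {self.zone_id}: degenerate rectangle {self.rect}")
        if self.role not in ZONE_ROLES:
            raise ArenaConfigError(f"zone {self.zone_id}: unknown role {self.role!r}")


@dataclass(frozen=True)
class ArenaSpec:
    """Named rectangular zones within rectangular arena bounds."""

    name: str
    bounds_cm: tuple[float, float]  # width, height
    zones: tuple[Zone, ...]
    social_side: str | None = None

    def __post_init__(self) -> None:
        w, h = self.bounds_cm
        ids = [z.zone_id for z in self.zones]
        if len(set(ids)) != len(ids):
            raise ArenaConfigError("zone ids must be unique")
        for z in self.zones:
            x0, y0, x1, y1 = z.rect
            if x0 < -1e-9 or y0 < -1e-9 or x1 > w + 1e-9 or y1 > h + 1e-9:
                raise ArenaConfigError(f"zone {z.zone_id} exceeds arena bounds")
        object.__setattr__(self, "zones", tuple(self.zones))

    def zone_by_id(self, zone_id: str) -> Zone:
        for z in self.zones:
            if z.zone_id == zone_id:
                return z
        raise KeyError(zone_id)

    def roles(self) -> set[str]:
        return {z.role for z in self.zones}

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "bounds_cm": list(self.bounds_cm),
            "social_side": self.social_side,
            "zones": [
                {"id": z.zone_id, "rect": list(z.rect), "role": z.role} for z in self.zones
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaSpec":
        zones = tuple(
            Zone(z["id"], tuple(float(v) for v in z["rect"]), z["role"]) for z in d["zones"]
        )
        return cls(
            name=d["name"],
            bounds_cm=tuple(float(v) for v in d["bounds_cm"]),
            zones=zones,
            social_side=d.get("social_side"),
        )

    @classmethod
    def from_yaml(cls, path) -> "ArenaSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_open_field(side_cm: float = 60.0, quadrant_cm: float = 20.0) -> ArenaSpec:
    """Square open field partitioned into a 3x3 grid of quadrants.

    The four grid corners are ``corner`` zones, the middle cell is the
    ``center`` zone and the four edge cells are ``other``.
    """
    if abs(3 * quadrant_cm - side_cm) > 1e-9:
        raise ArenaConfigError(
            f"open field needs side == 3 * quadrant; got side={side_cm}, quadrant={quadrant_cm}"
        )
    q = quadrant_cm
    names = [
        ["corner_nw", "edge_n", "corner_ne"],
        ["edge_w", "center", "edge_e"],
        ["corner_sw", "edge_s", "corner_se"],
    ]
    zones = []
    for r in range(3):
        for c in range(3):
            nm = names[r][c]
            role = "corner" if nm.startswith("corner") else ("center" if nm == "center" else "other")
            zones.append(Zone(nm, (c * q, r * q, (c + 1) * q, (r + 1) * q), role))
    return ArenaSpec(name="open_field", bounds_cm=(side_cm, side_cm), zones=tuple(zones))


def make_three_chamber(
    chamber_w: float = 30.0,
    chamber_h: float = 22.0,
    door: float = 10.0,
    social_side: str = "left",
    door_depth_cm: float = 0.0,
) -> ArenaSpec:
    """Three abutting chambers; the social chamber sits on ``social_side``.

    With ``door_depth_cm > 0`` strips of that depth around the two internal
    walls (door width tall, vertically centred) are carved out as extra
    zones assigned to the center chamber, so doorway frames do not inflate
    the lateral-chamber statistics.
    """
    if social_side not in ("left", "right"):
        raise ArenaConfigError("social_side must be 'left' or 'right'")
    if door > chamber_h:
        raise ArenaConfigError("door height cannot exceed chamber height")
    w, h = chamber_w, chamber_h
    left_role = "chamber_social" if social_side == "left" else "chamber_empty"
    right_role = "chamber_empty" if social_side == "left" else "chamber_social"
    zones: list[Zone] = []
    if door_depth_cm > 0:
        y0 = (h - door) / 2.0
        y1 = y0 + door
        zones.append(Zone("door_left", (w - door_depth_cm, y0, w + door_depth_cm, y1), "chamber_center"))
        zones.append(Zone("door_right", (2 * w - door_depth_cm, y0, 2 * w + door_depth_cm, y1), "chamber_center"))
    zones += [
        Zone("chamber_left", (0.0, 0.0, w, h), left_role),
        Zone("chamber_center", (w, 0.0, 2 * w, h), "chamber_center"),
        Zone("chamber_right", (2 * w, 0.0, 3 * w, h), right_role),
    ]
    return ArenaSpec(
        name="three_chamber",
        bounds_cm=(3 * w, h),
        zones=tuple(zones),
        social_side=social_side,
    )


def make_epm(arm_l: float = 40.0, arm_w: float = 10.0) -> ArenaSpec:
    """Elevated plus maze: open arms horizontal, closed arms vertical."""
    if arm_l <= 0 or arm_w <= 0:
        raise ArenaConfigError("arm dimensions must be positive")
    size = 2 * arm_l + arm_w
    a, b = arm_l, arm_l + arm_w  # hub spans [a, b) on both axes
    zones = (
        Zone("arm_open_w", (0.0, a, a, b), "arm_open"),
        Zone("arm_open_e", (b, a, size, b), "arm_open"),
        Zone("arm_closed_n", (a, 0.0, b, a), "arm_closed"),
        Zone("arm_closed_s", (a, b, b, size), "arm_closed"),
        Zone("hub", (a, a, b, b), "hub"),
    )
    return ArenaSpec(name="epm", bounds_cm=(size, size), zones=zones)


def _contains(point, rect, bounds) -> bool:
    x, y = point
    x0, y0, x1, y1 = rect
    w, h = bounds
    in_x = (x0 <= x < x1) or (x == x1 == w)
    in_y = (y0 <= y < y1) or (y == y1 == h)
    return in_x and in_y


def assign_zone(point: tuple[float, float], arena: ArenaSpec) -> str | None:
    """Zone id containing ``point`` (first declared zone wins), else None."""
    for z in arena.zones:
        if _contains(point, z.rect, arena.bounds_cm):
            return z.zone_id
    return UNASSIGNED


def assign_zones(traj: Trajectory, arena: ArenaSpec) -> list[str | None]:
    """Per-frame zone ids for a trajectory."""
    return [assign_zone((x, y), arena) for x, y in zip(traj.x_cm, traj.y_cm)]


@dataclass(frozen=True)
class ZoneOccupancy:
    """Per-zone frame counts, dwell times and session-time percentages."""

    frames: dict
    seconds: dict
    percent: dict
    unassigned_frames: int
    role_percent: dict
    total_frames: int
    dt_s: float

    @property
    def unassigned_percent(self) -> float:
        return 100.0 * self.unassigned_frames / self.total_frames


def zone_occupancy(traj: Trajectory, arena: ArenaSpec) -> ZoneOccupancy:
    """Occupancy of each zone, plus pooled role-level percentages."""
    labels = assign_zones(traj, arena)
    n = traj.n_frames
    dt = traj.dt_s
    frames = {z.zone_id: 0 for z in arena.zones}
    unassigned = 0
    for lab in labels:
        if lab is None:
            unassigned += 1
        else:
            frames[lab] += 1
    seconds = {k: v * dt for k, v in frames.items()}
    percent = {k: 100.0 * v / n for k, v in frames.items()}
    role_frames: dict[str, int] = {}
    for z in arena.zones:
        role_frames[z.role] = role_frames.get(z.role, 0) + frames[z.zone_id]
    role_percent = {k: 100.0 * v / n for k, v in role_frames.items()}
    return ZoneOccupancy(
        frames=frames,
        seconds=seconds,
        percent=percent,
        unassigned_frames=unassigned,
        role_percent=role_percent,
        total_frames=n,
        dt_s=dt,
    )


def _summary_from_parts(
    disp: np.ndarray,
    moving: np.ndarray,
    sel: np.ndarray,
    stops: int,
    dt: float,
    epsilon_cm: float,
    positive_only_denominator: bool = True,
) -> KinematicSummary:
    """Five statistics over the step subset ``sel`` of one segmentation."""
    sel_moving = sel & moving
    n_moving = int(np.count_nonzero(sel_moving))
    dist = _seq_sum(disp[sel_moving])
    eff_vel = dist / (n_moving * dt) if n_moving else math.nan
    pos_sum = 0.0
    n_pos = 0
    n_pairs = 0
    idx = np.flatnonzero(sel_moving)
    for a, b in zip(idx, idx[1:]):
        if b == a + 1:  # consecutive moving steps inside the subset
            n_pairs += 1
            dv = (disp[b] - disp[a]) / dt
            if dv > 0:
                pos_sum += dv
                n_pos += 1
    if n_pairs == 0:
        acc = math.nan
    elif positive_only_denominator:
        acc = (pos_sum / n_pos) / dt if n_pos else 0.0
    else:
        acc = (pos_sum / n_pairs) / dt
    return KinematicSummary(
        traveled_distance_cm=dist,
        effective_velocity_cm_s=eff_vel,
        mean_acceleration_cm_s2=acc,
        stops=stops,
        distance_per_stop_cm=distance_per_stop(dist, stops),
        moving_time_s=n_moving * dt,
        n_steps=int(np.count_nonzero(sel)),
        n_moving_steps=n_moving,
        epsilon_cm=epsilon_cm,
        degenerate=n_moving == 0,
    )


def per_zone_kinematics(
    traj: Trajectory,
    arena: ArenaSpec,
    epsilon_cm: float = DEFAULT_EPSILON_CM,
    role_grouping: dict | None = None,
) -> dict[str, KinematicSummary]:
    """Kinematic summaries per zone role (or per pooled role group).

    Each step is assigned the zone role of its earlier frame. Stop events
    count toward a group only when the moving steps flanking the immobile
    run both belong to that group; boundary-spanning stops are attributed
    to no group.
    """
    seg = segment_movement(traj, epsilon_cm)
    labels = assign_zones(traj, arena)
    role_of_zone = {z.zone_id: z.role for z in arena.zones}

    def group_of(frame_label) -> str | None:
        if frame_label is None:
            return None
        role = role_of_zone[frame_label]
        if role_grouping is None:
            return role
        return role_grouping.get(role)

    step_group = [group_of(labels[i]) for i in range(traj.n_frames - 1)]
    groups = sorted({g for g in step_group if g is not None})
    # stop attribution: flanking moving steps must share the group
    stops_per_group = {g: 0 for g in groups}
    for s, e in seg.stop_events:
        g_before = step_group[s - 1]
        g_after = step_group[e + 1]
        if g_before is not None and g_before == g_after:
            stops_per_group[g_before] += 1
    out: dict[str, KinematicSummary] = {}
    arr = np.array([g if g is not None else "" for g in step_group])
    for g in groups:
        sel = arr == g
        out[g] = _summary_from_parts(
            seg.step_displacement_cm, seg.moving, sel, stops_per_group[g], seg.dt_s, epsilon_cm
        )
    return out


def social_preference(traj: Trajectory, arena: ArenaSpec) -> float:
    """Percent of session time spent in the social chamber."""
    if "chamber_social" not in arena.roles():
        raise ArenaConfigError("arena has no chamber_social zone")
    occ = zone_occupancy(traj, arena)
    return occ.role_percent.get("chamber_social", 0.0)


#: Pooling used for social-stage analyses: social chamber vs center + empty.
SOCIAL_GROUPING = {
    "chamber_social": "social",
    "chamber_center": "non_social",
    "chamber_empty": "non_social",
}


@dataclass(frozen=True)
class SocialRatioReport:
    """Social vs non-social values and their ratio, per statistic."""

    social: dict
    non_social: dict
    ratio: dict


def social_ratio_report(per_zone: dict[str, KinematicSummary]) -> SocialRatioReport:
    """Ratios social/non-social for the five statistics.

    ``per_zone`` must contain ``social`` and ``non_social`` summaries (as
    produced with :data:`SOCIAL_GROUPING`); a degenerate side yields NaN
    ratios.
    """
    for key in ("social", "non_social"):
        if key not in per_zone:
            raise ArenaConfigError(f"per-zone summaries missing {key!r}")
    soc = per_zone["social"].as_dict()
    non = per_zone["non_social"].as_dict()
    degenerate = per_zone["social"].degenerate or per_zone["non_social"].degenerate
    social = {}
    non_social = {}
    ratio = {}
    from .kinematics import STATISTICS

    for stat in STATISTICS:
        sv, nv = float(soc[stat]), float(non[stat])
        social[stat] = sv
        non_social[stat] = nv
        if degenerate or not nv > 0 or math.isnan(sv):
            ratio[stat] = math.nan
        else:
            ratio[stat] = sv / nv
    return SocialRatioReport(social=social, non_social=non_social, ratio=ratio)
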