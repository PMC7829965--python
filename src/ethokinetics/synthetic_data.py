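"""Synthetic trajectories, cohorts and video frame stacks with ground truth.

The generator alternates immobile gaps and movement bouts: gap lengths and
bout lengths are exponential (per-step hazards ``bout_rate_hz`` and
``1 / mean_bout_s``), within a bout speed ramps up toward a cruise speed,
and heading follows a correlated random walk with specular reflection at
the walls. Zone attraction uses a Metropolis-style rule on zone-boundary
crossings: a step into a lower-weight zone role is rejected (the heading
reverses) with probability ``1 - w_new / w_current``, so stationary
occupancy is proportional to zone weight times area. While the animal is
inside the social chamber, optional multiplicative modulation factors
apply to acceleration/jerkiness, the bout-ending (stop) hazard, and the
cruise speed.

All randomness is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .arenas import ArenaSpec, make_open_field, make_three_chamber
from .kinematics import Trajectory

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulationError",
    "simulate_trajectory",
    "make_cohort",
    "render_frames",
    "control_like_config",
    "vpa_like_config",
]


class SimulationError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    arena: ArenaSpec
    duration_s: float = 300.0
    dt_s: float = 1.0 / 30.0
    bout_rate_hz: float = 2.0          # bout initiations per second of immobility
    mean_bout_s: float = 1.0           # mean bout duration
    ramp_accel_cm_s2: float = 60.0     # within-bout speed ramp
    ramp_decel_cm_s2: float | None = None  # None: bouts stop instantly
    cruise_speed_cm_s: float = 15.0
    min_speed_cm_s: float = 5.0        # speed floor at bout start
    heading_kappa: float = 4.0         # von Mises concentration of turning noise
    speed_noise_cv: float = 0.0        # per-step multiplicative speed variability
    bout_rate_half_life_s: float | None = None  # activity decay (habituation)
    zone_bias: dict = field(default_factory=dict)   # role -> attraction weight
    social_modulation: dict = field(default_factory=dict)  # accel/stop_rate/speed
    start_xy: tuple[float, float] | None = None
    phenotype: str = "generic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_s <= 0 or self.duration_s <= 0:
            raise SimulationError("dt_s and duration_s must be positive")
        if self.bout_rate_hz < 0 or self.mean_bout_s <= 0:
            raise SimulationError("bout_rate_hz must be >= 0 and mean_bout_s > 0")
        if self.cruise_speed_cm_s <= 0 or self.min_speed_cm_s <= 0:
            raise SimulationError("speeds must be positive")
        if any(w < 0 for w in self.zone_bias.values()):
            raise SimulationError("zone_bias weights must be >= 0")
        if self.bout_rate_half_life_s is not None and self.bout_rate_half_life_s <= 0:
            raise SimulationError("bout_rate_half_life_s must be > 0")
        w, h = self.arena.bounds_cm
        if self.cruise_speed_cm_s * self.dt_s >= min(w, h):
            raise SimulationError("arena too small for a single step at cruise speed")


@dataclass(frozen=True)
class GroundTruth:
    """Generative bookkeeping emitted alongside each trajectory."""

    positions: np.ndarray          # (n_frames, 2) cm
    moving_step: np.ndarray        # (n_frames - 1,) bool
    speed_cm_s: np.ndarray         # (n_frames - 1,) commanded speed per step
    zone_role: list                # per-frame role (or None)
    bout_schedule: tuple           # ((start_step, end_step), ...) inclusive
    per_bout_peak_speed: tuple
    n_bouts: int
    n_stops: int                   # immobile gaps strictly between bouts
    phenotype: str


def _role_lookup(arena: ArenaSpec):
    zones = [(z.rect, z.role) for z in arena.zones]
    w, h = arena.bounds_cm

    def role(x: float, y: float):
        for (x0, y0, x1, y1), r in zones:
            if (x0 <= x < x1 or (x == x1 == w)) and (y0 <= y < y1 or (y == y1 == h)):
                return r
        return None

    return role


def _bounce(x: float, y: float, heading: float, step: float, w: float, h: float):
    """Advance by ``step`` with specular wall reflection of the heading.

    The heading (not the endpoint) is mirrored, so the net displacement of
    every moving step is exactly ``step``; one reflection per axis suffices
    because a step is shorter than either arena span.
    """
    dx = step * math.cos(heading)
    dy = step * math.sin(heading)
    if x + dx < 0.0 or x + dx > w:
        dx = -dx
        heading = math.pi - heading
    if y + dy < 0.0 or y + dy > h:
        dy = -dy
        heading = -heading
    return x + dx, y + dy, heading


def simulate_trajectory(cfg: SimulationConfig) -> tuple[Trajectory, GroundTruth]:
    """Simulate one session; deterministic for a given config (incl. seed)."""
    rng = np.random.default_rng(cfg.seed)
    n_steps = int(round(cfg.duration_s / cfg.dt_s))
    if n_steps < 1:
        raise SimulationError("duration shorter than one frame interval")
    n_frames = n_steps + 1
    w, h = cfg.arena.bounds_cm
    role_at = _role_lookup(cfg.arena)
    mod = {"accel": 1.0, "stop_rate": 1.0, "speed": 1.0}
    mod.update(cfg.social_modulation)

    # pre-drawn random streams (one block each; fixed consumption order)
    u_start = rng.random(n_steps)
    u_stop = rng.random(n_steps)
    turn = rng.vonmises(0.0, cfg.heading_kappa, n_steps)
    u_cross = rng.random(n_steps)
    if cfg.speed_noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + cfg.speed_noise_cv**2))
        speed_noise = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, n_steps))
    else:
        speed_noise = np.ones(n_steps)
    # emitted speed never drops below this, so moving steps stay above any
    # immobility threshold smaller than min_speed * 0.6 * dt
    v_floor = cfg.min_speed_cm_s * 0.6

    pos = np.empty((n_frames, 2))
    if cfg.start_xy is None:
        pos[0] = (w / 2.0, h / 2.0)
    else:
        pos[0] = cfg.start_xy
    moving = np.zeros(n_steps, dtype=bool)
    speeds = np.zeros(n_steps)
    zone_role: list = [role_at(pos[0, 0], pos[0, 1])]
    bouts: list[tuple[int, int]] = []
    peaks: list[float] = []

    x, y = float(pos[0, 0]), float(pos[0, 1])
    heading = 0.0
    v = 0.0
    in_bout = False
    bout_start = 0
    peak = 0.0
    dt = cfg.dt_s
    p_start = 1.0 - math.exp(-cfg.bout_rate_hz * dt) if cfg.bout_rate_hz > 0 else 0.0
    base_stop_hazard = 1.0 / cfg.mean_bout_s

    cooldown = False  # a bout end implies >= 1 immobile frame
    for i in range(n_steps):
        role = zone_role[-1]
        social = role == "chamber_social"
        if not in_bout:
            if cfg.bout_rate_half_life_s is not None:
                rate = cfg.bout_rate_hz * 2.0 ** (-(i * dt) / cfg.bout_rate_half_life_s)
                p_start = 1.0 - math.exp(-rate * dt)
            if cooldown:
                cooldown = False
            elif p_start > 0.0 and u_start[i] < p_start:
                in_bout = True
                bout_start = i
                peak = 0.0
                v = cfg.min_speed_cm_s * (mod["speed"] if social else 1.0)
                heading = float(rng.uniform(-math.pi, math.pi))
        if in_bout:
            accel = cfg.ramp_accel_cm_s2 * (mod["accel"] if social else 1.0)
            cruise = cfg.cruise_speed_cm_s * (mod["speed"] if social else 1.0)
            v = min(v + accel * dt, cruise)
            # the accel factor also scales the per-step speed deviations, so
            # social modulation damps jerkiness without changing mean speed
            dev = (speed_noise[i] - 1.0) * (mod["accel"] if social else 1.0)
            v_step = max(v * (1.0 + dev), v_floor)
            peak = max(peak, v_step)
            heading += turn[i]
            nx, ny, nheading = _bounce(x, y, heading, v_step * dt, w, h)
            if cfg.zone_bias:
                w_cur = cfg.zone_bias.get(role, 1.0)
                w_new = cfg.zone_bias.get(role_at(nx, ny), 1.0)
                if w_new < w_cur and u_cross[i] >= w_new / w_cur:
                    # crossing rejected: reverse heading, retrace the step
                    heading += math.pi
                    nx, ny, nheading = _bounce(x, y, heading, v_step * dt, w, h)
            x, y, heading = nx, ny, nheading
            moving[i] = True
            speeds[i] = v_step
            stop_hazard = base_stop_hazard * (mod["stop_rate"] if social else 1.0)
            if u_stop[i] < 1.0 - math.exp(-stop_hazard * dt):
                in_bout = False
                cooldown = True
                bouts.append((bout_start, i))
                peaks.append(peak)
                v = 0.0
        pos[i + 1] = (x, y)
        zone_role.append(role_at(x, y))
    if in_bout:
        bouts.append((bout_start, n_steps - 1))
        peaks.append(peak)

    t = np.arange(n_frames) * dt
    traj = Trajectory(t_s=t, x_cm=pos[:, 0].copy(), y_cm=pos[:, 1].copy(),
                      test_stage=cfg.arena.name)
    truth = GroundTruth(
        positions=pos,
        moving_step=moving,
        speed_cm_s=speeds,
        zone_role=zone_role,
        bout_schedule=tuple(bouts),
        per_bout_peak_speed=tuple(peaks),
        n_bouts=len(bouts),
        n_stops=max(0, len(bouts) - 1),
        phenotype=cfg.phenotype,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# phenotype presets
#
# Preset magnitudes are tuning constants chosen so simulated summaries land
# in a plausible band (accelerations of order 1e2 cm/s^2), not measured
# facts. The control-like phenotype modulates its kinematics inside the
# social chamber (softer acceleration, more frequent stopping); the
# vpa-like phenotype applies no social modulation but moves with steeper
# ramps and shorter, more frequent bouts, keeping overall distance and
# effective velocity unchanged by construction.


def _base_config(arena: ArenaSpec | None = None, **overrides) -> SimulationConfig:
    if arena is None:
        arena = make_open_field()
    defaults = dict(
        duration_s=300.0,
        dt_s=0.1,
        bout_rate_hz=2.0,
        mean_bout_s=1.0,
        ramp_accel_cm_s2=60.0,
        cruise_speed_cm_s=15.0,
        min_speed_cm_s=5.0,
        heading_kappa=8.0,
        speed_noise_cv=0.25,
    )
    if "chamber_social" in arena.roles():
        # weight 2 vs 1+1 for center/empty -> ~50% social-chamber occupancy
        defaults["zone_bias"] = {"chamber_social": 2.0}
    defaults.update(overrides)
    return SimulationConfig(arena=arena, **defaults)


def control_like_config(arena: ArenaSpec | None = None, **overrides) -> SimulationConfig:
    cfg = _base_config(arena, **overrides)
    return replace(
        cfg,
        social_modulation={"accel": 0.65, "stop_rate": 1.9, "speed": 1.0},
        phenotype="control_like",
    )


def vpa_like_config(arena: ArenaSpec | None = None, **overrides) -> SimulationConfig:
    cfg = _base_config(arena, **overrides)
    return replace(
        cfg,
        ramp_accel_cm_s2=cfg.ramp_accel_cm_s2 * 1.7,
        speed_noise_cv=cfg.speed_noise_cv * 1.7,  # jerkier speed profile
        mean_bout_s=cfg.mean_bout_s * 0.4,
        bout_rate_hz=cfg.bout_rate_hz * 2.46,  # keeps traveled distance neutral
        social_modulation={},
        phenotype="vpa_like",
    )


@dataclass(frozen=True)
class CohortSubject:
    subject_id: str
    group: str
    seed: int
    trajectory: Trajectory
    truth: GroundTruth


def make_cohort(
    control_cfg: SimulationConfig,
    treated_cfg: SimulationConfig,
    n_per_group: int,
    base_seed: int = 0,
) -> list[CohortSubject]:
    """Simulate a two-group cohort; subject seeds are base_seed + index."""
    if n_per_group < 1:
        raise SimulationError("n_per_group must be >= 1")
    subjects: list[CohortSubject] = []
    idx = 0
    for group, cfg in (("control", control_cfg), ("treated", treated_cfg)):
        for j in range(n_per_group):
            seed = base_seed + idx
            sid = f"{group}_{j:02d}"
            traj, truth = simulate_trajectory(replace(cfg, seed=seed))
            traj = Trajectory(
                t_s=traj.t_s, x_cm=traj.x_cm, y_cm=traj.y_cm,
                subject_id=sid, group_label=group, test_stage=cfg.arena.name,
            )
            subjects.append(CohortSubject(sid, group, seed, traj, truth))
            idx += 1
    return subjects


# ---------------------------------------------------------------------------
# frame rendering


def render_frames(
    traj: Trajectory,
    cal,
    blob_radius_px: float = 5.0,
    blob_intensity: int = 30,
    background_intensity: int = 200,
    noise_sd: float = 0.0,
    frame_shape: tuple[int, int] = (128, 128),
    seed: int = 0,
):
    """Render a trajectory as a grayscale frame stack with a dark disc.

    Returns ``(FrameStack, path_px)`` where ``path_px`` is the (n, 2) array
    of true disc centres in pixel coordinates. The blob must be darker than
    the background by at least ``3 * noise_sd``.
    """
    from .tracking import Calibration, FrameStack  # late import: module cycle

    if not isinstance(cal, Calibration):
        raise SimulationError("cal must be a Calibration")
    if background_intensity - blob_intensity < 3 * noise_sd:
        raise SimulationError("blob must be darker than background by >= 3 * noise_sd")
    H, W = frame_shape
    cx = traj.x_cm * cal.px_per_cm_x + cal.origin_px[0]
    cy = traj.y_cm * cal.px_per_cm_y + cal.origin_px[1]
    r = blob_radius_px
    if (cx.min() < r or cx.max() > W - 1 - r or cy.min() < r or cy.max() > H - 1 - r):
        raise SimulationError("blob leaves the frame; enlarge frame_shape or shrink path")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:H, 0:W]
    frames = np.empty((traj.n_frames, H, W), dtype=np.uint8)
    for i in range(traj.n_frames):
        img = np.full((H, W), float(background_intensity))
        disc = (xx - cx[i]) ** 2 + (yy - cy[i]) ** 2 <= r * r
        img[disc] = blob_intensity
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, size=(H, W))
        frames[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    stack = FrameStack(frames=frames, frame_interval_s=traj.dt_s,
                       source_id=f"render:{traj.subject_id or 'synthetic'}")
    return stack, np.column_stack([cx, cy])
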