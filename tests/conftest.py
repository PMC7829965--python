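"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive every quantity with plain Python
loops (no numpy reductions, no calls into the package's computation paths)
so they stay independent of the code they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ethokinetics.kinematics import Trajectory


def make_walk(seed: int, n_steps: int = 500, dt: float = 0.1,
              p_move: float = 0.7, step_scale: float = 1.0) -> Trajectory:
    """Random walk with genuine immobile runs (steps of exactly zero)."""
    rng = np.random.default_rng(seed)
    moving = rng.random(n_steps) < p_move
    angles = rng.uniform(-math.pi, math.pi, n_steps)
    lengths = rng.exponential(step_scale, n_steps) + 0.5  # clear of epsilon
    dx = np.where(moving, lengths * np.cos(angles), 0.0)
    dy = np.where(moving, lengths * np.sin(angles), 0.0)
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])
    t = np.arange(n_steps + 1) * dt
    return Trajectory(t_s=t, x_cm=x, y_cm=y, subject_id=f"walk{seed}")


def traj_from_displacements(disps, dt: float = 0.1) -> Trajectory:
    """Trajectory along the x axis with the given per-step displacements."""
    x = [0.0]
    for d in disps:
        x.append(x[-1] + d)
    t = np.arange(len(x)) * dt
    return Trajectory(t_s=np.array(t, float), x_cm=np.array(x, float),
                      y_cm=np.zeros(len(x)))


def oracle_five_stats(traj: Trajectory, epsilon_cm: float) -> dict:
    """Naive-loop recomputation of the five kinematic statistics."""
    dt = float(traj.t_s[1] - traj.t_s[0])
    n = len(traj.x_cm)
    disp = []
    for i in range(n - 1):
        dx = float(traj.x_cm[i + 1]) - float(traj.x_cm[i])
        dy = float(traj.y_cm[i + 1]) - float(traj.y_cm[i])
        disp.append(math.sqrt(dx * dx + dy * dy))
    moving = [d > epsilon_cm for d in disp]

    distance = 0.0
    n_moving = 0
    for d, m in zip(disp, moving):
        if m:
            distance += d
            n_moving += 1
    eff_vel = distance / (n_moving * dt) if n_moving else math.nan

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
        acc = math.nan
    elif n_pos == 0:
        acc = 0.0
    else:
        acc = (pos_sum / n_pos) / dt

    stops = oracle_count_stops(moving)
    dps = distance / stops if stops else math.nan
    return {
        "distance": distance,
        "eff_vel": eff_vel,
        "acc": acc,
        "stops": stops,
        "dist_per_stop": dps,
        "n_moving": n_moving,
        "moving": moving,
    }


def oracle_count_stops(moving) -> int:
    """Maximal immobile runs with movement on both sides (regex-style scan)."""
    s = "".join("m" if m else "i" for m in moving)
    import re

    return len(re.findall(r"(?<=m)i+(?=m)", s))


@pytest.fixture(scope="session")
def random_walks():
    return [make_walk(seed) for seed in range(20)]
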