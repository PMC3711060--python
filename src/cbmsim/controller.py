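"""High-level (cortical-like) controller: trajectory generation and crude
inverse dynamics.

The controller is purely algorithmic. It plans smooth hand paths with a
minimum-jerk (quintic) profile, converts them to joint space through the
closed-form two-link inverse kinematics (elbow-positive branch, fixed for
reproducibility) and the kinematic Jacobian, and emits feedforward torque
commands from the nominal arm model. It knows nothing about the rotation
bias or other perturbations: corrections are the cerebellar models' job.

Replanning consumes forward-model state predictions: a fresh quintic is
issued from the predicted hand state to the target over the remaining
movement duration. When the prediction sits exactly on the current plan,
the replanned suffix coincides with the old one (the quintic Hermite
interpolant of a quintic is the quintic itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arm import (
    DT,
    ArmParams,
    TorquePair,
    coriolis,
    hand_jacobian,
    inverse_kinematics_angles,
    mass_matrix,
)


def minimum_jerk(start, target, D: float, t):
    """Minimum-jerk position/velocity/acceleration at time ``t``.

    Fifth-order profile x(t) = x0 + dx * (10 s^3 - 15 s^4 + 6 s^5) with
    s = t/D, applied per Cartesian coordinate. ``t`` may be scalar or an
    array; values must lie in [0, D].
    """
    if D <= 0:
        raise ValueError("duration must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -1e-12) or np.any(t_arr > D + 1e-12):
        raise ValueError(f"t={t} outside [0, {D}]")
    s = np.clip(t_arr / D, 0.0, 1.0)
    start = np.asarray(start, float)
    target = np.asarray(target, float)
    dx = target - start
    shape = (10 * s ** 3 - 15 * s ** 4 + 6 * s ** 5)
    dshape = (30 * s ** 2 - 60 * s ** 3 + 30 * s ** 4) / D
    ddshape = (60 * s - 180 * s ** 2 + 120 * s ** 3) / D ** 2
    if t_arr.ndim == 0:
        return start + dx * shape, dx * dshape, dx * ddshape
    pos = start[None, :] + dx[None, :] * shape[:, None]
    vel = dx[None, :] * dshape[:, None]
    acc = dx[None, :] * ddshape[:, None]
    return pos, vel, acc


def quintic_hermite(p0, v0, a0, p1, v1, a1, T: float, t):
    """General quintic with full position/velocity/acceleration boundary
    conditions at both ends; used for mid-movement replanning."""
    if T <= 0:
        raise ValueError("duration must be positive")
    p0, v0, a0 = (np.asarray(z, float) for z in (p0, v0, a0))
    p1, v1, a1 = (np.asarray(z, float) for z in (p1, v1, a1))
    s = np.clip(np.asarray(t, float) / T, 0.0, 1.0)
    # Hermite basis on the unit interval, scaled by T for derivatives
    c0 = p0
    c1 = v0 * T
    c2 = 0.5 * a0 * T ** 2
    c3 = 10 * (p1 - p0) - (6 * v0 + 4 * v1) * T - (1.5 * a0 - 0.5 * a1) * T ** 2
    c4 = -15 * (p1 - p0) + (8 * v0 + 7 * v1) * T + (1.5 * a0 - a1) * T ** 2
    c5 = 6 * (p1 - p0) - (3 * v0 + 3 * v1) * T - (0.5 * a0 - 0.5 * a1) * T ** 2
    coeffs = [c0, c1, c2, c3, c4, c5]
    s_col = s[..., None] if np.ndim(s) else s
    pos = sum(c * np.power(s_col, k) for k, c in enumerate(coeffs))
    vel = sum(k * c * np.power(s_col, k - 1) for k, c in enumerate(coeffs) if k >= 1) / T
    acc = sum(k * (k - 1) * c * np.power(s_col, k - 2) for k, c in enumerate(coeffs) if k >= 2) / T ** 2
    return pos, vel, acc


def inverse_kinematics(x: float, y: float, p: ArmParams) -> tuple[float, float]:
    """Joint angles reaching (x, y); elbow-positive solution."""
    return inverse_kinematics_angles(x, y, p)


def jacobian_dot(theta, dtheta, p: ArmParams) -> np.ndarray:
    ts, te = theta
    ws, we = dtheta
    s1, c1 = math.sin(ts), math.cos(ts)
    s12, c12 = math.sin(ts + te), math.cos(ts + te)
    w12 = ws + we
    return np.array([
        [-p.L1 * c1 * ws - p.L2 * c12 * w12, -p.L2 * c12 * w12],
        [-p.L1 * s1 * ws - p.L2 * s12 * w12, -p.L2 * s12 * w12],
    ])


def joint_profiles(pos: np.ndarray, vel: np.ndarray, acc: np.ndarray,
                   p: ArmParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map a Cartesian kinematic profile to joint space (vectorized).

    Positions go through the closed-form inverse kinematics
    (elbow-positive branch); velocities and accelerations through the
    analytic Jacobian (no finite differences): dtheta = J^-1 v,
    ddtheta = J^-1 (a - Jdot dtheta).
    """
    x, y = pos[:, 0], pos[:, 1]
    r2 = x * x + y * y
    r = np.sqrt(r2)
    lo, hi = abs(p.L1 - p.L2), p.L1 + p.L2
    if np.any(r > hi + 1e-12) or np.any(r < lo - 1e-12):
        from .arm import UnreachableTargetError
        raise UnreachableTargetError("trajectory leaves the reachable annulus")
    cos_e = np.clip((r2 - p.L1 ** 2 - p.L2 ** 2) / (2.0 * p.L1 * p.L2), -1.0, 1.0)
    te = np.arccos(cos_e)
    k1 = p.L1 + p.L2 * cos_e
    k2 = p.L2 * np.sin(te)
    ts = np.arctan2(y, x) - np.arctan2(k2, k1)

    s1, c1 = np.sin(ts), np.cos(ts)
    s12, c12 = np.sin(ts + te), np.cos(ts + te)
    j00 = -p.L1 * s1 - p.L2 * s12
    j01 = -p.L2 * s12
    j10 = p.L1 * c1 + p.L2 * c12
    j11 = p.L2 * c12
    det = j00 * j11 - j01 * j10
    vx, vy = vel[:, 0], vel[:, 1]
    ws = (j11 * vx - j01 * vy) / det
    we = (-j10 * vx + j00 * vy) / det

    w12 = ws + we
    jd00 = -p.L1 * c1 * ws - p.L2 * c12 * w12
    jd01 = -p.L2 * c12 * w12
    jd10 = -p.L1 * s1 * ws - p.L2 * s12 * w12
    jd11 = -p.L2 * s12 * w12
    rx = acc[:, 0] - (jd00 * ws + jd01 * we)
    ry = acc[:, 1] - (jd10 * ws + jd11 * we)
    as_ = (j11 * rx - j01 * ry) / det
    ae = (-j10 * rx + j00 * ry) / det

    theta = np.stack([ts, te], axis=1)
    dtheta = np.stack([ws, we], axis=1)
    ddtheta = np.stack([as_, ae], axis=1)
    return theta, dtheta, ddtheta


def inverse_dynamics(theta, dtheta, ddtheta, p: ArmParams) -> TorquePair:
    """Computed-torque feedforward law on the nominal (unbiased) model."""
    M = mass_matrix(theta[1], p)
    C = coriolis(theta[1], dtheta[0], dtheta[1], p)
    B = np.array([p.b1 * dtheta[0], p.b2 * dtheta[1]])
    tau = M @ np.asarray(ddtheta, float) + C + B
    return TorquePair(float(tau[0]), float(tau[1]))


def inverse_dynamics_profile(theta: np.ndarray, dtheta: np.ndarray,
                             ddtheta: np.ndarray, p: ArmParams) -> np.ndarray:
    """Vectorized computed-torque law over a whole desired profile."""
    te = theta[:, 1]
    c = np.cos(te)
    a11 = (p.I1 + p.I2 + p.m1 * p.lc1 ** 2
           + p.m2 * (p.L1 ** 2 + p.lc2 ** 2 + 2.0 * p.L1 * p.lc2 * c))
    a12 = p.I2 + p.m2 * (p.lc2 ** 2 + p.L1 * p.lc2 * c)
    a22 = p.I2 + p.m2 * p.lc2 ** 2
    h = p.m2 * p.L1 * p.lc2 * np.sin(te)
    ws, we = dtheta[:, 0], dtheta[:, 1]
    tau_s = (a11 * ddtheta[:, 0] + a12 * ddtheta[:, 1]
             - h * we * (2.0 * ws + we) + p.b1 * ws)
    tau_e = (a12 * ddtheta[:, 0] + a22 * ddtheta[:, 1]
             + h * ws ** 2 + p.b2 * we)
    return np.stack([tau_s, tau_e], axis=1)


@dataclass
class TrajectoryPlan:
    """Desired kinematics of one reach, sampled at the global step.

    Arrays span the whole movement window (D/dt steps); replanning
    overwrites the suffix from the replanning instant onward. ``x`` is
    the task-space (unrotated) desired hand path; joint-space desireds
    are derived via IK/Jacobian and cached here.
    """

    start: np.ndarray
    target: np.ndarray
    duration: float
    dt: float
    x: np.ndarray          # (N, 2) desired hand position
    v: np.ndarray          # (N, 2) desired hand velocity
    a: np.ndarray          # (N, 2) desired hand acceleration
    theta: np.ndarray      # (N, 2) desired joint angles
    dtheta: np.ndarray     # (N, 2)
    ddtheta: np.ndarray    # (N, 2)

    @property
    def n_steps(self) -> int:
        return self.x.shape[0]

    def copy(self) -> "TrajectoryPlan":
        return TrajectoryPlan(
            self.start.copy(), self.target.copy(), self.duration, self.dt,
            self.x.copy(), self.v.copy(), self.a.copy(),
            self.theta.copy(), self.dtheta.copy(), self.ddtheta.copy())


def make_plan(start, target, duration: float, p: ArmParams,
              dt: float = DT) -> TrajectoryPlan:
    """Plan a minimum-jerk reach from rest at ``start`` to rest at ``target``."""
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    pos, vel, acc = minimum_jerk(start, target, duration, t)
    theta, dtheta, ddtheta = joint_profiles(pos, vel, acc, p)
    return TrajectoryPlan(np.asarray(start, float), np.asarray(target, float),
                          duration, dt, pos, vel, acc, theta, dtheta, ddtheta)


def replan(plan: TrajectoryPlan, predicted_pos, predicted_vel,
           index: int, target, p: ArmParams,
           min_remaining_steps: int = 10) -> TrajectoryPlan:
    """Re-issue the desired trajectory from a forward-model prediction.

    A quintic with boundary conditions (predicted position, predicted
    velocity, current planned acceleration) at the replanning instant and
    (target, 0, 0) at the end of the movement replaces the plan suffix.
    If fewer than ``min_remaining_steps`` steps remain, the current plan
    is kept unchanged.
    """
    n = plan.n_steps
    remaining = n - index
    if remaining < min_remaining_steps:
        return plan
    T = remaining * plan.dt
    t = np.arange(remaining) * plan.dt
    pos, vel, acc = quintic_hermite(
        np.asarray(predicted_pos, float), np.asarray(predicted_vel, float),
        plan.a[index], np.asarray(target, float), np.zeros(2), np.zeros(2),
        T, t)
    theta, dtheta, ddtheta = joint_profiles(pos, vel, acc, p)
    new = plan.copy()
    new.x[index:] = pos
    new.v[index:] = vel
    new.a[index:] = acc
    new.theta[index:] = theta
    new.dtheta[index:] = dtheta
    new.ddtheta[index:] = ddtheta
    return new
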