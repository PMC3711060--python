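"""Planar two-link arm plant (shoulder + elbow).

The arm moves in the horizontal plane, so gravity plays no role; the
dynamics are the standard rigid-body equations of a planar double
pendulum with viscous joint friction,

    M(theta) theta'' + C(theta, theta') + B theta' = tau,

integrated with a semi-implicit Euler scheme at the global 1 ms step.
Angles follow the convention used throughout the package: the shoulder
angle is measured from the world +x axis, the elbow angle relative to
the upper-arm axis, radians everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: global simulation step (s)
DT = 1e-3


@dataclass
class ArmParams:
    """Physical parameters of the two-link arm.

    Link inertias default to uniform-rod values (m L^2 / 12 about the
    centre of mass, located at mid-link). Magnitudes are human-forearm
    scale.
    """

    L1: float = 0.30            # upper-arm length (m)
    L2: float = 0.30            # forearm length (m)
    m1: float = 1.4             # upper-arm mass (kg)
    m2: float = 1.0             # forearm mass (kg)
    I1: float | None = None     # inertia about COM (kg m^2); None -> rod
    I2: float | None = None
    b1: float = 0.05            # viscous friction, shoulder (N m s / rad)
    b2: float = 0.05            # viscous friction, elbow (N m s / rad)
    shoulder_limits: tuple[float, float] = (-math.pi, math.pi)
    elbow_limits: tuple[float, float] = (0.0, math.pi)
    tau_max: float = 20.0       # actuator bound (N m), clamped silently

    def __post_init__(self) -> None:
        if min(self.L1, self.L2, self.m1, self.m2) <= 0:
            raise ValueError("link lengths and masses must be strictly positive")
        if self.I1 is None:
            self.I1 = self.m1 * self.L1 ** 2 / 12.0
        if self.I2 is None:
            self.I2 = self.m2 * self.L2 ** 2 / 12.0
        if self.I1 <= 0 or self.I2 <= 0:
            raise ValueError("inertias must be strictly positive")
        if self.b1 < 0 or self.b2 < 0:
            raise ValueError("friction must be non-negative")

    @property
    def lc1(self) -> float:
        return self.L1 / 2.0

    @property
    def lc2(self) -> float:
        return self.L2 / 2.0


@dataclass
class ArmState:
    """Joint angles (rad) and angular velocities (rad/s)."""

    theta_s: float = 0.0
    theta_e: float = 0.0
    omega_s: float = 0.0
    omega_e: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.theta_s, self.theta_e, self.omega_s, self.omega_e])

    def copy(self) -> "ArmState":
        return replace(self)


@dataclass
class TorquePair:
    """Shoulder and elbow torques (N m)."""

    tau_s: float = 0.0
    tau_e: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.tau_s, self.tau_e])


class ArmDiagnosticError(RuntimeError):
    """Non-finite command or state reached the plant."""


def mass_matrix(theta_e: float, p: ArmParams) -> np.ndarray:
    c = math.cos(theta_e)
    a11 = (p.I1 + p.I2 + p.m1 * p.lc1 ** 2
           + p.m2 * (p.L1 ** 2 + p.lc2 ** 2 + 2.0 * p.L1 * p.lc2 * c))
    a12 = p.I2 + p.m2 * (p.lc2 ** 2 + p.L1 * p.lc2 * c)
    a22 = p.I2 + p.m2 * p.lc2 ** 2
    return np.array([[a11, a12], [a12, a22]])


def coriolis(theta_e: float, omega_s: float, omega_e: float, p: ArmParams) -> np.ndarray:
    h = p.m2 * p.L1 * p.lc2 * math.sin(theta_e)
    return np.array([-h * omega_e * (2.0 * omega_s + omega_e), h * omega_s ** 2])


def acceleration(state: ArmState, tau: np.ndarray, p: ArmParams) -> np.ndarray:
    """Joint accelerations for given state and (already clamped) torques."""
    M = mass_matrix(state.theta_e, p)
    C = coriolis(state.theta_e, state.omega_s, state.omega_e, p)
    B = np.array([p.b1 * state.omega_s, p.b2 * state.omega_e])
    return np.linalg.solve(M, tau - C - B)


def forward_kinematics(state: ArmState | tuple, p: ArmParams) -> tuple[float, float]:
    """Hand (end-point) position in metres, shoulder at the origin."""
    if isinstance(state, ArmState):
        ts, te = state.theta_s, state.theta_e
    else:
        ts, te = state
    x = p.L1 * math.cos(ts) + p.L2 * math.cos(ts + te)
    y = p.L1 * math.sin(ts) + p.L2 * math.sin(ts + te)
    return (x, y)


def hand_jacobian(theta_s: float, theta_e: float, p: ArmParams) -> np.ndarray:
    s1, c1 = math.sin(theta_s), math.cos(theta_s)
    s12, c12 = math.sin(theta_s + theta_e), math.cos(theta_s + theta_e)
    return np.array([
        [-p.L1 * s1 - p.L2 * s12, -p.L2 * s12],
        [p.L1 * c1 + p.L2 * c12, p.L2 * c12],
    ])


def hand_velocity(state: ArmState, p: ArmParams) -> np.ndarray:
    J = hand_jacobian(state.theta_s, state.theta_e, p)
    return J @ np.array([state.omega_s, state.omega_e])


class UnreachableTargetError(ValueError):
    """Requested hand position is outside the arm's annulus."""


def inverse_kinematics_angles(x: float, y: float, p: ArmParams) -> tuple[float, float]:
    """Elbow-positive (counter-clockwise) two-link inverse kinematics."""
    r2 = x * x + y * y
    r = math.sqrt(r2)
    lo, hi = abs(p.L1 - p.L2), p.L1 + p.L2
    if r > hi + 1e-12 or r < lo - 1e-12:
        raise UnreachableTargetError(
            f"hand position ({x:.3f}, {y:.3f}) at radius {r:.3f} outside [{lo:.3f}, {hi:.3f}]"
        )
    cos_e = (r2 - p.L1 ** 2 - p.L2 ** 2) / (2.0 * p.L1 * p.L2)
    cos_e = min(1.0, max(-1.0, cos_e))
    theta_e = math.acos(cos_e)          # elbow-positive branch
    k1 = p.L1 + p.L2 * cos_e
    k2 = p.L2 * math.sin(theta_e)
    theta_s = math.atan2(y, x) - math.atan2(k2, k1)
    return (theta_s, theta_e)


def clamp_torque(torque: TorquePair | np.ndarray, p: ArmParams) -> np.ndarray:
    tau = torque.as_array() if isinstance(torque, TorquePair) else np.asarray(torque, float)
    if not np.all(np.isfinite(tau)):
        raise ArmDiagnosticError(f"non-finite torque command: {tau}")
    return np.clip(tau, -p.tau_max, p.tau_max)


def step_dynamics(state: ArmState, torque: TorquePair | np.ndarray,
                  p: ArmParams, dt: float = DT) -> ArmState:
    """Advance the rigid-body dynamics one step (explicit midpoint).

    Second-order accurate, so the 1 ms step tracks a fine-step
    integration of the same equations to well under 1e-4 rad over a
    reach. Deterministic: identical inputs give bit-identical outputs.
    Joint limits clamp the angle and zero the offending velocity.
    """
    tau = clamp_torque(torque, p)
    om0 = np.array([state.omega_s, state.omega_e])
    th0 = np.array([state.theta_s, state.theta_e])
    a1 = acceleration(state, tau, p)
    mid = ArmState(th0[0] + 0.5 * dt * om0[0], th0[1] + 0.5 * dt * om0[1],
                   om0[0] + 0.5 * dt * a1[0], om0[1] + 0.5 * dt * a1[1])
    a2 = acceleration(mid, tau, p)
    omega = om0 + a2 * dt
    theta = th0 + (om0 + 0.5 * dt * a1) * dt

    limits = (p.shoulder_limits, p.elbow_limits)
    for j, (lo, hi) in enumerate(limits):
        if theta[j] < lo:
            theta[j] = lo
            omega[j] = max(omega[j], 0.0)
        elif theta[j] > hi:
            theta[j] = hi
            omega[j] = min(omega[j], 0.0)
    return ArmState(theta[0], theta[1], omega[0], omega[1])


def reset_arm(state: ArmState, start_position: tuple[float, float],
              p: ArmParams) -> ArmState:
    """Place the hand at the start position S with zero joint velocities.

    Used during the 0.3 s inter-trajectory refractory window. Raises
    :class:`UnreachableTargetError` if S lies outside the workspace.
    """
    ts, te = inverse_kinematics_angles(start_position[0], start_position[1], p)
    return ArmState(ts, te, 0.0, 0.0)


def kinetic_energy(state: ArmState, p: ArmParams) -> float:
    omega = np.array([state.omega_s, state.omega_e])
    return 0.5 * float(omega @ mass_matrix(state.theta_e, p) @ omega)
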