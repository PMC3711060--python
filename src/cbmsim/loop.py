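"""The closed sensorimotor loop: one 1 s trajectory at a time.

Timing contract (all delays in integer steps of the global 1 ms clock,
delta = 50 ms at defaults):

* the controller emits at step t the command for plan index t + delta
  (it knows its own actuation delay), which reaches the plant at t +
  delta, so at time u the plant executes plan index u; the first delta
  of commands is issued during the tail of the preceding refractory
  window, priming the efferent pipeline;
* sensed feedback at step t reports the actual state at t - delta;
* a forward predictor queried at step t predicts the state at plan
  index t + delta from the efference copy emitted at t; its teaching
  target for that prediction becomes available 2 delta later, hence the
  prediction delay line of length 2 delta and an end-to-end
  command-to-sensed-consequence latency of exactly 2 delta.

The rotation bias is injected in the trajectory generator: the desired
Cartesian profile is rotated anticlockwise about the start position S
before inverse kinematics, while every other consumer of "desired"
(corrector context, teaching, metrics) keeps the unrotated plan. Each
trajectory runs 0.7 s of movement followed by a 0.3 s refractory window
during which the arm is repositioned at S and the cerebellar nets return
to baseline (weights untouched).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .arm import (DT, ArmParams, ArmState, clamp_torque, forward_kinematics,
                  hand_jacobian, reset_arm)
from .controller import (TrajectoryPlan, inverse_dynamics_profile,
                         joint_profiles, make_plan, replan)
from .models import (OFFLINE, ONLINE, ForwardPredictor, InverseCorrector,
                     TeachingConfig, make_encoder)
from .network import MicrocomplexBank, MicrocomplexConfig, build_microcomplex
from .synthetic import rotate_about

SCHEMES = ("FM", "IM", "CM")


class DelayLine:
    """Strict FIFO of fixed latency: an item pushed at step k is returned
    at step k + n; before warm-up the configured neutral value (or the
    preload contents) comes out."""

    def __init__(self, n_steps: int, neutral, preload: list | None = None):
        if n_steps < 0:
            raise ValueError("delay must be non-negative")
        self.n = n_steps
        if preload is not None:
            if len(preload) != n_steps:
                raise ValueError("preload must fill the line exactly")
            self._buf = list(preload)
        else:
            self._buf = [neutral] * n_steps

    def push_pop(self, item):
        if self.n == 0:
            return item
        self._buf.append(item)
        return self._buf.pop(0)


@dataclass
class ModeConfig:
    """Which model families run/learn, the phase, and the bias in force."""

    scheme: str = "CM"
    phase: str = ONLINE
    bias_deg: float = 0.0
    learning: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.phase not in (ONLINE, OFFLINE):
            raise ValueError("phase must be online or offline")

    @property
    def forward_active(self) -> bool:
        return self.scheme in ("FM", "CM")

    @property
    def inverse_active(self) -> bool:
        return self.scheme in ("IM", "CM")

    @property
    def replan_enabled(self) -> bool:
        # trajectory recalculation is impossible without forward predictions
        return self.forward_active and self.phase == ONLINE


@dataclass
class LoopConfig:
    """Timing and gain constants of the closed loop."""

    dt: float = DT
    delay_s: float = 0.050          # central<->peripheral transmission delay
    movement_s: float = 0.700
    reset_s: float = 0.300
    replan_period_s: float = 0.010
    replan_start_s: float = 0.060   # let decoder rate filters warm up first
    torque_gain: float = 2.5        # corrective torque at full DCN rate (N m)
    tau_act_s: float = 0.080        # first-order smoothing of the correction
    dcn_max_rate_hz: float = 100.0
    confidence_threshold: float = 2.0
    decoder_min_rate_hz: float = 2.0
    replan_min_offset_m: float = 0.015  # ignore predicted deviations below this
    replan_blend: float = 0.4       # fraction of the predicted offset acted on
    #: a predictor's output is released only while its running (EMA)
    #: prediction error is small relative to the running deviation
    #: magnitude — inaccurate predictions would make trajectory planning
    #: catastrophic
    accuracy_ratio: float = 0.75
    accuracy_dev_floor: float = 0.02  # minimum deviation signal (span units)
    accuracy_ema_decay: float = 0.997
    decode_lag_s: float = 0.020     # mean lag of the 20 ms decode window
    trace_mean_lag_s: float = 0.025  # mean age of a fresh eligibility trace

    # Timing alignment, derived from the loop's own lags. The corrector
    # reads its context this far ahead of the plan index its (delayed,
    # smoothed) output will act on; the plasticity lag re-centres CF
    # credit on the PF activity that caused the error being taught.
    @property
    def inv_context_lead_s(self) -> float:
        return self.delay_s + self.tau_act_s + self.decode_lag_s

    @property
    def inv_plasticity_lag_s(self) -> float:
        return self.inv_context_lead_s + self.trace_mean_lag_s

    @property
    def fwd_plasticity_lag_s(self) -> float:
        return self.delay_s + self.decode_lag_s + 0.012

    @property
    def n_inv_lead(self) -> int:
        return int(round(self.inv_context_lead_s / self.dt))

    @property
    def n_move(self) -> int:
        return int(round(self.movement_s / self.dt))

    @property
    def n_reset(self) -> int:
        return int(round(self.reset_s / self.dt))

    @property
    def n_delay(self) -> int:
        return int(round(self.delay_s / self.dt))


@dataclass
class TaskRanges:
    """Physical ranges spanned by the task, used to lay out encoders."""

    theta: np.ndarray        # (2, 2) per-joint [lo, hi] (rad)
    dtheta: np.ndarray       # (2, 2) (rad/s)
    torque: np.ndarray       # (2, 2) final command range (N m)
    dev_pos: np.ndarray      # (2,) symmetric deviation bound per joint (rad)
    dev_vel: np.ndarray      # (2,) (rad/s)
    #: desired joint states visited by the task (N, 4) — the manifold the
    #: corrector encoders tile
    inv_samples: np.ndarray | None = None
    #: (torque, desired pos, desired vel) triples per joint (N, 3)
    fwd_samples: tuple | None = None


def derive_task_ranges(params: ArmParams, centre, radius: float,
                       duration: float = 0.7,
                       biases=(0.0, 15.0, 30.0, 45.0, 60.0),
                       torque_margin: float = 0.8,
                       pad: float = 1.25) -> TaskRanges:
    """Sweep the task geometry (8 targets x bias schedule) and record the
    joint-state, torque and plan-deviation envelopes, padded."""
    centre = np.asarray(centre, float)
    th_all, dth_all, tau_all = [], [], []
    dev_p = np.zeros(2)
    dev_v = np.zeros(2)
    inv_samples = []
    fwd_samples = ([], [])
    sub = 10  # subsampling stride for manifold samples
    for k in range(8):
        ang = k * math.pi / 4.0
        target = centre + radius * np.array([math.cos(ang), math.sin(ang)])
        plan = make_plan(centre, target, duration, params)
        inv_samples.append(np.concatenate([plan.theta[::sub],
                                           plan.dtheta[::sub]], axis=1))
        for b in biases:
            xb = rotate_about(plan.x, b, centre)
            vb = rotate_about(plan.v, b, (0.0, 0.0))
            ab = rotate_about(plan.a, b, (0.0, 0.0))
            th, dth, ddth = joint_profiles(xb, vb, ab, params)
            tau = inverse_dynamics_profile(th, dth, ddth, params)
            th_all.append(th)
            dth_all.append(dth)
            tau_all.append(tau)
            dev_p = np.maximum(dev_p, np.abs(th - plan.theta).max(axis=0))
            dev_v = np.maximum(dev_v, np.abs(dth - plan.dtheta).max(axis=0))
            for joint in (0, 1):
                # commanded torque (biased) against the unrotated desired
                # state, with offsets spanning the corrective range
                for off in (-0.5, 0.0, 0.5):
                    fwd_samples[joint].append(np.column_stack([
                        tau[::sub, joint] + off,
                        plan.theta[::sub, 0], plan.theta[::sub, 1],
                        plan.dtheta[::sub, 0], plan.dtheta[::sub, 1]]))
    th_all = np.concatenate(th_all)
    dth_all = np.concatenate(dth_all)
    tau_all = np.concatenate(tau_all)

    def _box(arr, extra=0.0):
        lo = arr.min(axis=0)
        hi = arr.max(axis=0)
        mid = 0.5 * (lo + hi)
        half = np.maximum(0.5 * (hi - lo) * pad + extra, 1e-3)
        return np.stack([mid - half, mid + half], axis=1)

    return TaskRanges(
        theta=_box(th_all),
        dtheta=_box(dth_all),
        torque=_box(tau_all, extra=torque_margin),
        dev_pos=np.maximum(dev_p * pad, 1e-3),
        dev_vel=np.maximum(dev_v * pad, 1e-3),
        inv_samples=np.concatenate(inv_samples),
        fwd_samples=(np.concatenate(fwd_samples[0]),
                     np.concatenate(fwd_samples[1])),
    )


# ---------------------------------------------------------------------------
# the eight microcomplexes of one subject

#: forward predictor order in the bank
FWD_ORDER = ("shoulder_angle", "shoulder_velocity", "elbow_angle", "elbow_velocity")
#: inverse corrector order in the bank: (joint, sign)
INV_ORDER = ((0, +1), (0, -1), (1, +1), (1, -1))


class ModelSet:
    """Four forward predictors + four inverse correctors of one subject,
    each a microcomplex, batched into two banks for execution."""

    def __init__(self, net_cfg: MicrocomplexConfig, ranges: TaskRanges,
                 seed: int, loop_cfg: LoopConfig | None = None,
                 teaching: TeachingConfig | None = None):
        self.cfg = net_cfg
        self.loop_cfg = loop_cfg or LoopConfig()
        self.ranges = ranges
        self.teaching = teaching or TeachingConfig()
        ss = np.random.SeedSequence(seed)
        seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(10)]

        # forward units carry a local (place) code on their DCN axis and
        # use a denser nucleus so the decoded value resolves finely
        # forward nets carry a local (place) code along their DCN axis;
        # value resolution scales with the PC/DCN density, so they use a
        # denser sheet than the rate-decoded inverse units, a sharper
        # eligibility trace (the context sweeps during the reach, and a
        # long trace blurs credit across it) and a denser CF teaching
        # rate with a correspondingly smaller LTD step
        fwd_cfg = replace(net_cfg, pc_dcn_profile="kernel",
                          n_pc=2 * net_cfg.n_pc, n_dcn=4 * net_cfg.n_dcn,
                          w_mfgc=0.40, w_max=0.028,
                          alpha_ltd=0.0008, cf_max_hz=25.0, trace_tau_ms=25.0,
                          plasticity_lag_ms=self.loop_cfg.fwd_plasticity_lag_s * 1000.0)
        inv_cfg = replace(net_cfg,
                          plasticity_lag_ms=self.loop_cfg.inv_plasticity_lag_s * 1000.0)
        self.forward: list[ForwardPredictor] = []
        fwd_nets = []
        for i, q in enumerate(FWD_ORDER):
            joint = 0 if q.startswith("shoulder") else 1
            is_vel = q.endswith("velocity")
            bound = float(ranges.dev_vel[joint] if is_vel else ranges.dev_pos[joint])
            dev_range = (-bound, bound)
            pv_pc = np.linspace(-bound, bound, fwd_cfg.n_pc)
            pv_dcn = np.linspace(-bound, bound, fwd_cfg.n_dcn)
            enc = make_encoder(net_cfg.n_mf, [ranges.torque[joint],
                                              ranges.theta[0], ranges.theta[1],
                                              ranges.dtheta[0], ranges.dtheta[1]],
                               sigma_scale=1.0,
                               samples=None if ranges.fwd_samples is None
                               else ranges.fwd_samples[joint])
            net = build_microcomplex(fwd_cfg, seeds[i], preferred_values=pv_pc)
            fwd_nets.append(net)
            self.forward.append(ForwardPredictor(
                quantity=q, encoder=enc, preferred_values=pv_pc,
                dcn_preferred=pv_dcn, deviation_range=dev_range,
                confidence_threshold=self.loop_cfg.confidence_threshold,
                joint=joint, is_velocity=is_vel, teaching=self.teaching))

        # all four correctors share one context: the full desired joint
        # state (both angles, both velocities) sent down by the controller
        inv_enc = make_encoder(net_cfg.n_mf, [ranges.theta[0], ranges.theta[1],
                                              ranges.dtheta[0], ranges.dtheta[1]],
                               sigma_scale=1.0, samples=ranges.inv_samples)
        self.inverse: list[InverseCorrector] = []
        inv_nets = []
        for i, (joint, sign) in enumerate(INV_ORDER):
            enc = inv_enc
            # agonist/antagonist twins share their wiring seed, so the net
            # correction starts at exactly zero and arises purely from
            # differential plasticity between the two units
            net = build_microcomplex(inv_cfg, seeds[4 + 2 * joint])
            inv_nets.append(net)
            self.inverse.append(InverseCorrector(
                joint=joint, sign=sign, encoder=enc,
                torque_gain=self.loop_cfg.torque_gain,
                max_rate_hz=self.loop_cfg.dcn_max_rate_hz,
                n_io=net_cfg.n_pc, teaching=self.teaching))

        self.fwd_bank = MicrocomplexBank(fwd_nets, seeds[8])
        self.inv_bank = MicrocomplexBank(inv_nets, seeds[9])

        # running accuracy monitor of each predictor: deviation-weighted
        # EMAs of the prediction error and deviation magnitude (span
        # units); weighting by the deviation keeps the near-zero samples,
        # where the decode noise floor dominates, from masking accuracy
        # on the deviations that actually matter. Starts pessimistic.
        self.pred_err_ema = np.ones(4)
        self.dev_mag_ema = np.zeros(4)
        self._wsum_ema = np.full(4, 1e-3)
        #: temporally smoothed raw predictions consumed by replanning and
        #: offline teaching (tau ~40 ms)
        self.pred_smooth = np.zeros(4)
        self._pred_smooth_decay = math.exp(-self.loop_cfg.dt / 0.040)

        # cached vectorized-decode constants
        self._pv_dcn = np.stack([f.dcn_preferred for f in self.forward])
        self._dev_lo = np.array([f.deviation_range[0] for f in self.forward])
        self._dev_span = np.array([f.deviation_range[1] - f.deviation_range[0]
                                   for f in self.forward])
        self._dev_bound = 0.5 * self._dev_span
        self._zpref = np.tile(np.linspace(0.0, 1.0, fwd_cfg.n_pc), (4, 1))
        self._inv_sign = np.array([s for _, s in INV_ORDER], float)

    # -- readouts ----------------------------------------------------------

    def predictions(self):
        """Decoded deviation and gate per forward quantity (length 4)."""
        raw = self.fwd_bank.dcn_rate
        # light spatial smoothing cleans single-cell raggedness from the
        # local-code profile before the population-vector readout
        r = raw.copy()
        r[:, 1:-1] = 0.25 * raw[:, :-2] + 0.5 * raw[:, 1:-1] + 0.25 * raw[:, 2:]
        r[:, 0] = (2.0 * raw[:, 0] + raw[:, 1]) / 3.0
        r[:, -1] = (2.0 * raw[:, -1] + raw[:, -2]) / 3.0
        mean = r.mean(axis=1)
        mx = r.max(axis=1)
        mn = r.min(axis=1)
        ok = mean > mn
        conf = np.where(ok, (mx - mn) / np.maximum(mean - mn, 1e-12), 0.0)
        excess = np.maximum(r - mean[:, None], 0.0)
        tot = excess.sum(axis=1)
        lc = self.loop_cfg
        wd = self.dev_mag_ema / self._wsum_ema
        we = self.pred_err_ema / self._wsum_ema
        accurate = (wd > lc.accuracy_dev_floor) & (we < lc.accuracy_ratio * wd)
        conf_gates = (ok & (mx >= lc.decoder_min_rate_hz)
                      & (conf >= lc.confidence_threshold) & (tot > 0))
        self._conf_gates = conf_gates
        gates = conf_gates & accurate
        vals = np.where(tot > 0,
                        (excess * self._pv_dcn).sum(axis=1) / np.maximum(tot, 1e-12),
                        0.0)
        self._raw_vals = vals
        self.pred_smooth *= self._pred_smooth_decay
        self.pred_smooth += (1.0 - self._pred_smooth_decay) * vals
        devs = np.where(gates, self.pred_smooth, 0.0)
        return devs, gates, conf

    def corrective_torque(self) -> np.ndarray:
        """Net corrective torque per joint (agonist + antagonist)."""
        rates = self.inv_bank.dcn_rate.mean(axis=1)
        contrib = (self._inv_sign * self.loop_cfg.torque_gain
                   * rates / self.loop_cfg.dcn_max_rate_hz)
        return np.array([contrib[0] + contrib[1], contrib[2] + contrib[3]])

    def reset_to_baseline(self) -> None:
        self.fwd_bank.reset_to_baseline()
        self.inv_bank.reset_to_baseline()
        self.pred_smooth[:] = 0.0

    def checksums(self) -> tuple[float, float]:
        return self.fwd_bank.checksum(), self.inv_bank.checksum()


# ---------------------------------------------------------------------------
# trajectory execution

@dataclass
class TrajectoryRecord:
    """Full time series of one 1 s trajectory (0.7 s move + 0.3 s reset)."""

    target: np.ndarray
    target_id: int
    bias_deg: float
    scheme: str
    phase: str
    seed: int
    dt: float
    n_move: int
    hand_path: np.ndarray        # (n_total, 2) actual hand positions
    hand_vel: np.ndarray         # (n_total, 2)
    desired_path: np.ndarray     # (n_total, 2) unrotated desired
    actual_theta: np.ndarray | None = None
    desired_theta: np.ndarray | None = None
    predicted_dev: np.ndarray | None = None
    torque_cmd: np.ndarray | None = None
    torque_corr: np.ndarray | None = None
    torque_final: np.ndarray | None = None
    gates: np.ndarray | None = None
    replan_count: int = 0

    @property
    def movement_path(self) -> np.ndarray:
        return self.hand_path[: self.n_move]

    @property
    def movement_vel(self) -> np.ndarray:
        return self.hand_vel[: self.n_move]

    @property
    def endpoint(self) -> np.ndarray:
        return self.hand_path[self.n_move - 1]


class _PlanBundle:
    """A plan plus everything derived from it that the loop consumes:
    biased joint profiles, crude torques, and MF context rate profiles."""

    def __init__(self, plan: TrajectoryPlan, bias_deg: float, centre,
                 params: ArmParams, ms: ModelSet):
        self.plan = plan
        self.bias_deg = bias_deg
        self.centre = np.asarray(centre, float)
        self.params = params
        self.ms = ms
        n = plan.n_steps
        self.theta_b = np.empty((n, 2))
        self.dtheta_b = np.empty((n, 2))
        self.tau_crude = np.empty((n, 2))
        self.inv_ctx = np.empty((n, ms.cfg.n_mf))
        self.fwd_d2_state = [np.empty((n, ms.cfg.n_mf)), np.empty((n, ms.cfg.n_mf))]
        self._derive(0)

    def _derive(self, start: int) -> None:
        plan, params = self.plan, self.params
        if self.bias_deg != 0.0:
            xb = rotate_about(plan.x[start:], self.bias_deg, self.centre)
            vb = rotate_about(plan.v[start:], self.bias_deg, (0.0, 0.0))
            ab = rotate_about(plan.a[start:], self.bias_deg, (0.0, 0.0))
            th, dth, ddth = joint_profiles(xb, vb, ab, params)
        else:
            th = plan.theta[start:]
            dth = plan.dtheta[start:]
            ddth = plan.ddtheta[start:]
        self.theta_b[start:] = th
        self.dtheta_b[start:] = dth
        self.tau_crude[start:] = inverse_dynamics_profile(th, dth, ddth, params)
        ms = self.ms
        # corrector MF context (shared): full desired state along the plan
        enc = ms.inverse[0].encoder
        lo, hi = enc.ranges[:, 0], enc.ranges[:, 1]
        vals = np.concatenate([plan.theta[start:], plan.dtheta[start:]], axis=1)
        z = (np.clip(vals, lo, hi) - lo) / (hi - lo)
        d2 = ((z[:, None, :] - enc.centres[None, :, :]) ** 2).sum(axis=2)
        self.inv_ctx[start:] = enc.max_rate_hz * np.exp(-0.5 * d2 / enc.sigma ** 2)
        for joint in (0, 1):
            # state part of the forward-predictor context (torque added per step)
            fenc = ms.forward[2 * joint].encoder
            flo, fhi = fenc.ranges[:, 0], fenc.ranges[:, 1]
            zs = (np.clip(vals, flo[1:], fhi[1:]) - flo[1:]) / (fhi[1:] - flo[1:])
            self.fwd_d2_state[joint][start:] = (
                (zs[:, None, :] - fenc.centres[None, :, 1:]) ** 2).sum(axis=2)

    def replan_from(self, pred_pos, pred_vel, index: int, target,
                    min_remaining: int) -> bool:
        from .arm import UnreachableTargetError
        old = self.plan
        try:
            new = replan(old, pred_pos, pred_vel, index, target,
                         self.params, min_remaining)
            if new is old:
                return False
            self.plan = new
            self._derive(index)
        except UnreachableTargetError:
            # a wild prediction produced a plan leaving the workspace;
            # keep the current plan
            self.plan = old
            self._derive(index)
            return False
        return True


def apply_bias(points: np.ndarray, bias_deg: float, centre) -> np.ndarray:
    """Rotate a desired hand trajectory anticlockwise about S — the bias
    injection point of the rotation-adaptation task."""
    if bias_deg == 0.0:
        return np.asarray(points, float)
    return rotate_about(points, bias_deg, centre)


def _accel(ts, te, ws, we, tau_s, tau_e, p: ArmParams):
    c = math.cos(te)
    bb = p.m2 * p.L1 * p.lc2
    a11 = (p.I1 + p.I2 + p.m1 * p.lc1 ** 2
           + p.m2 * (p.L1 ** 2 + p.lc2 ** 2) + 2.0 * bb * c)
    a12 = p.I2 + p.m2 * p.lc2 ** 2 + bb * c
    a22 = p.I2 + p.m2 * p.lc2 ** 2
    h = bb * math.sin(te)
    rhs_s = tau_s + h * we * (2.0 * ws + we) - p.b1 * ws
    rhs_e = tau_e - h * ws * ws - p.b2 * we
    det = a11 * a22 - a12 * a12
    return ((a22 * rhs_s - a12 * rhs_e) / det,
            (a11 * rhs_e - a12 * rhs_s) / det)


def _step_arm(ts, te, ws, we, tau_s, tau_e, p: ArmParams, dt: float):
    """Scalar explicit-midpoint step (same scheme as arm.step_dynamics)."""
    a1s, a1e = _accel(ts, te, ws, we, tau_s, tau_e, p)
    a2s, a2e = _accel(ts + 0.5 * dt * ws, te + 0.5 * dt * we,
                      ws + 0.5 * dt * a1s, we + 0.5 * dt * a1e,
                      tau_s, tau_e, p)
    ts += (ws + 0.5 * dt * a1s) * dt
    te += (we + 0.5 * dt * a1e) * dt
    ws += a2s * dt
    we += a2e * dt
    lo, hi = p.shoulder_limits
    if ts < lo:
        ts, ws = lo, max(ws, 0.0)
    elif ts > hi:
        ts, ws = hi, min(ws, 0.0)
    lo, hi = p.elbow_limits
    if te < lo:
        te, we = lo, max(we, 0.0)
    elif te > hi:
        te, we = hi, min(we, 0.0)
    return ts, te, ws, we


def run_trajectory(arm_state: ArmState, params: ArmParams, ms: ModelSet,
                   mode: ModeConfig, target, centre,
                   plan: TrajectoryPlan | None = None,
                   cfg: LoopConfig | None = None,
                   record_full: bool = False,
                   seed: int = 0) -> tuple[TrajectoryRecord, ArmState]:
    """Run one 0.7 s + 0.3 s trajectory under the given scheme and phase.

    Returns the record and the arm state after the reset window (hand at
    S, zero velocity). During the offline phase no plant is simulated and
    no sensed feedback exists; the forward predictions stand in for the
    executed state and the record's "hand path" is the predicted one.
    """
    cfg = cfg or ms.loop_cfg
    centre = np.asarray(centre, float)
    target = np.asarray(target, float)
    n_move, n_delay = cfg.n_move, cfg.n_delay
    n_total = n_move + cfg.n_reset
    offline = mode.phase == OFFLINE
    teach = ms.teaching
    dt = cfg.dt

    if plan is None:
        plan = make_plan(centre, target, cfg.movement_s, params)
    bundle = _PlanBundle(plan.copy(), 0.0 if offline else mode.bias_deg,
                         centre, params, ms)

    # the controller issues the first delta of commands during the tail of
    # the preceding refractory window, priming the efferent pipeline
    motor_delay = DelayLine(n_delay, None,
                            preload=[(bundle.tau_crude[i, 0], bundle.tau_crude[i, 1])
                                     for i in range(n_delay)])
    sense_delay = DelayLine(n_delay, arm_state.as_array())
    pred_delay = DelayLine(2 * n_delay,
                           (np.zeros(4), np.zeros(4, bool), np.zeros(4)))

    hand_path = np.empty((n_total, 2))
    hand_vel = np.zeros((n_total, 2))
    desired_path = np.empty((n_total, 2))
    if record_full:
        rec_theta = np.zeros((n_total, 4))
        rec_des_theta = np.zeros((n_total, 4))
        rec_dev = np.zeros((n_total, 4))
        rec_tau = np.zeros((n_total, 2))
        rec_corr = np.zeros((n_total, 2))
        rec_final = np.zeros((n_total, 2))
        rec_gates = np.zeros((n_total, 4), bool)

    replan_every = max(1, int(round(cfg.replan_period_s / dt)))
    replan_start = int(round(cfg.replan_start_s / dt))
    act_decay = math.exp(-dt / cfg.tau_act_s) if cfg.tau_act_s > 0 else 0.0
    corr_s = corr_e = 0.0
    replan_count = 0
    ts, te = arm_state.theta_s, arm_state.theta_e
    ws, we = arm_state.omega_s, arm_state.omega_e
    tau_max = params.tau_max
    p = params
    L1, L2 = p.L1, p.L2

    mf_inv = np.empty((4, ms.cfg.n_mf))
    mf_fwd = np.empty((4, ms.cfg.n_mf))
    devs = np.zeros(4)
    gates = np.zeros(4, bool)
    raw_vals = np.zeros(4)
    sensed = None
    pred_delay_item = (np.zeros(4), np.zeros(4, bool), np.zeros(4))

    # forward-encoder torque-axis constants per joint
    fenc0 = ms.forward[0].encoder
    fenc1 = ms.forward[2].encoder
    ftau_lo = (fenc0.ranges[0, 0], fenc1.ranges[0, 0])
    ftau_span = (fenc0.ranges[0, 1] - fenc0.ranges[0, 0],
                 fenc1.ranges[0, 1] - fenc1.ranges[0, 0])
    fc_tau = (fenc0.centres[:, 0], fenc1.centres[:, 0])
    f_gain = (-0.5 / fenc0.sigma ** 2, -0.5 / fenc1.sigma ** 2)
    f_max = (fenc0.max_rate_hz, fenc1.max_rate_hz)

    n_inv_lead = cfg.n_inv_lead
    for t in range(n_move):
        i_cmd = t + n_delay
        if i_cmd >= n_move:
            i_cmd = n_move - 1

        # --- crude command + cerebellar correction -----------------------
        tau_s_cmd, tau_e_cmd = bundle.tau_crude[i_cmd]
        if mode.inverse_active:
            i_ctx = t + n_inv_lead
            if i_ctx >= n_move:
                i_ctx = n_move - 1
            ctx = bundle.inv_ctx[i_ctx]
            mf_inv[0] = ctx
            mf_inv[1] = ctx
            mf_inv[2] = ctx
            mf_inv[3] = ctx
            cf_inv = None
            if mode.learning:
                cf_inv = _inverse_teaching(ms, mode, bundle, t, n_delay,
                                           sensed, devs, gates)
            ms.inv_bank.step(mf_inv, cf_inv, plastic=mode.learning)
            raw = ms.corrective_torque()
            corr_s = act_decay * corr_s + (1.0 - act_decay) * raw[0]
            corr_e = act_decay * corr_e + (1.0 - act_decay) * raw[1]
        tau_s_fin = tau_s_cmd + corr_s
        tau_e_fin = tau_e_cmd + corr_e
        if not (math.isfinite(tau_s_fin) and math.isfinite(tau_e_fin)):
            raise RuntimeError(
                f"non-finite torque command at step {t}: ({tau_s_fin}, {tau_e_fin})")
        tau_s_fin = min(max(tau_s_fin, -tau_max), tau_max)
        tau_e_fin = min(max(tau_e_fin, -tau_max), tau_max)

        # --- plant (online) ----------------------------------------------
        if not offline:
            tau_app = motor_delay.push_pop((tau_s_fin, tau_e_fin))
            ts, te, ws, we = _step_arm(ts, te, ws, we, tau_app[0], tau_app[1],
                                       p, dt)
            sensed = sense_delay.push_pop(np.array([ts, te, ws, we]))

        # --- forward predictors ------------------------------------------
        if mode.forward_active:
            # position and velocity predictors of a joint share their context
            for joint, tau_j in ((0, tau_s_fin), (1, tau_e_fin)):
                z = (min(max(tau_j, ftau_lo[joint]),
                         ftau_lo[joint] + ftau_span[joint])
                     - ftau_lo[joint]) / ftau_span[joint]
                d2 = bundle.fwd_d2_state[joint][i_cmd] + (fc_tau[joint] - z) ** 2
                rates = f_max[joint] * np.exp(f_gain[joint] * d2)
                mf_fwd[2 * joint] = rates
                mf_fwd[2 * joint + 1] = rates
            cf_fwd = None
            if not offline and mode.learning and t >= n_delay:
                cf_fwd = _forward_teaching(ms, bundle, t, n_delay, sensed,
                                           pred_delay_item)
            ms.fwd_bank.step(mf_fwd, cf_fwd, plastic=mode.learning and not offline)
            devs, gates, _ = ms.predictions()
            raw_vals = ms._raw_vals
        pred_delay_item = pred_delay.push_pop((devs, gates, raw_vals))

        # --- replanning ----------------------------------------------------
        if (mode.replan_enabled and t >= replan_start and t % replan_every == 0
                and gates[0] and gates[2]):
            th_s = bundle.plan.theta[i_cmd, 0] + devs[0]
            th_e = bundle.plan.theta[i_cmd, 1] + devs[2]
            x_hat = np.array(forward_kinematics((th_s, th_e), p))
            dx = x_hat - bundle.plan.x[i_cmd]
            # act only on predicted offsets above the decode resolution,
            # move partway toward them, and keep the plan's own velocity
            # boundary (decoded velocity predictions are too coarse to
            # anchor a quintic)
            if dx[0]*dx[0] + dx[1]*dx[1] >= cfg.replan_min_offset_m ** 2:
                x_new = bundle.plan.x[i_cmd] + cfg.replan_blend * dx
                v_new = bundle.plan.v[i_cmd]
                if bundle.replan_from(x_new, v_new, i_cmd, target, replan_every):
                    replan_count += 1

        # --- record --------------------------------------------------------
        desired_path[t] = bundle.plan.x[t]
        if offline:
            th_s = bundle.plan.theta[t, 0] + devs[0]
            th_e = bundle.plan.theta[t, 1] + devs[2]
            hand_path[t, 0] = L1 * math.cos(th_s) + L2 * math.cos(th_s + th_e)
            hand_path[t, 1] = L1 * math.sin(th_s) + L2 * math.sin(th_s + th_e)
        else:
            c1 = math.cos(ts)
            s1 = math.sin(ts)
            c12 = math.cos(ts + te)
            s12 = math.sin(ts + te)
            hand_path[t, 0] = L1 * c1 + L2 * c12
            hand_path[t, 1] = L1 * s1 + L2 * s12
            w12 = ws + we
            hand_vel[t, 0] = -L1 * s1 * ws - L2 * s12 * w12
            hand_vel[t, 1] = L1 * c1 * ws + L2 * c12 * w12
        if record_full:
            if not offline:
                rec_theta[t] = (ts, te, ws, we)
            rec_des_theta[t, 0:2] = bundle.plan.theta[t]
            rec_des_theta[t, 2:4] = bundle.plan.dtheta[t]
            rec_dev[t] = devs
            rec_tau[t] = (tau_s_cmd, tau_e_cmd)
            rec_corr[t] = (corr_s, corr_e)
            rec_final[t] = (tau_s_fin, tau_e_fin)
            rec_gates[t] = gates

    # --- teaching flush: the sensed consequences of the last delta of the
    # movement arrive during the early refractory window; keep teaching
    # (with no new context drive) so the end of the reach is credited too
    if mode.learning and not offline:
        zero_mf = np.zeros((4, ms.cfg.n_mf))
        final_state = np.array([ts, te, ws, we])
        for t in range(n_move, n_move + n_delay):
            sensed = sense_delay.push_pop(final_state)
            if mode.inverse_active:
                cf_inv = _inverse_teaching(ms, mode, bundle, t, n_delay,
                                           sensed, devs, gates)
                ms.inv_bank.step(zero_mf, cf_inv, plastic=True)
            if mode.forward_active:
                pred_delay_item = pred_delay.push_pop(
                    (np.zeros(4), np.zeros(4, bool), np.zeros(4)))
                cf_fwd = _forward_teaching(ms, bundle, t, n_delay, sensed,
                                           pred_delay_item)
                ms.fwd_bank.step(zero_mf, cf_fwd, plastic=True)

    # --- 0.3 s refractory window: reposition and settle -------------------
    state = reset_arm(ArmState(ts, te, ws, we), centre, params)
    ms.reset_to_baseline()
    hand_path[n_move:] = forward_kinematics(state, params)
    hand_vel[n_move:] = 0.0
    desired_path[n_move:] = bundle.plan.x[-1]

    rec = TrajectoryRecord(
        target=target, target_id=-1, bias_deg=mode.bias_deg,
        scheme=mode.scheme, phase=mode.phase, seed=seed, dt=dt,
        n_move=n_move, hand_path=hand_path, hand_vel=hand_vel,
        desired_path=desired_path, replan_count=replan_count)
    if record_full:
        rec.actual_theta = rec_theta
        rec.desired_theta = rec_des_theta
        rec.predicted_dev = rec_dev
        rec.torque_cmd = rec_tau
        rec.torque_corr = rec_corr
        rec.torque_final = rec_final
        rec.gates = rec_gates
    return rec, state


def _inverse_teaching(ms: ModelSet, mode: ModeConfig, bundle: _PlanBundle,
                      t: int, n_delay: int, sensed, devs, gates):
    """CF rates (4, n_io) for the corrector bank at step t, or None.

    Online: the sensorimotor error between the desired state at the
    matching (delayed) plan index and the delayed sensed state. Offline:
    the error between desired and *predicted* state; emitted only for
    joints whose forward gates (position and velocity) are open.
    """
    teach = ms.teaching
    if mode.phase == ONLINE:
        if sensed is None or t < n_delay:
            return None
        i_ref = t - n_delay
        th_d = bundle.plan.theta[i_ref]
        dth_d = bundle.plan.dtheta[i_ref]
        e0 = (teach.k_p * (th_d[0] - sensed[0])
              + teach.k_v * (dth_d[0] - sensed[2]))
        e1 = (teach.k_p * (th_d[1] - sensed[1])
              + teach.k_v * (dth_d[1] - sensed[3]))
        e = (e0, e1)
    else:
        # offline: teaching information is available whenever the forward
        # profile is confidently peaked (the accuracy monitor is a
        # sensory-comparison quantity and does not exist offline)
        cg = getattr(ms, "_conf_gates", None)
        pv = ms.pred_smooth
        if cg is None:
            return None
        e = [None, None]
        for joint in (0, 1):
            if cg[2 * joint] and cg[2 * joint + 1]:
                # desired - predicted = -deviation
                e[joint] = -(teach.k_p * pv[2 * joint]
                             + teach.k_v * pv[2 * joint + 1])
        if e[0] is None and e[1] is None:
            return None
    n_io = ms.cfg.n_pc
    rates = np.full((4, n_io), teach.cf_baseline_hz)
    span = teach.cf_max_hz - teach.cf_baseline_hz
    inv_scale = 1.0 / teach.error_scale
    for i, (joint, sign) in enumerate(INV_ORDER):
        ej = e[joint]
        if ej is None:
            continue
        d = sign * ej * inv_scale
        if d > teach.deadband:
            # this unit's CF above baseline: LTD grows its output
            rates[i] += span * min((d - teach.deadband) / (1.0 - teach.deadband), 1.0)
        elif -d > teach.deadband:
            # the opposite unit is being taught; this unit's IO is
            # suppressed below baseline, so its output relaxes
            rates[i] -= teach.recovery_hz * min((-d - teach.deadband)
                                                / (1.0 - teach.deadband), 1.0)
    return rates


def _forward_teaching(ms: ModelSet, bundle: _PlanBundle, t: int, n_delay: int,
                      sensed, delayed_pred):
    """CF rates (4, n_io) for the forward bank at step t (online only).

    The supervised target is the deviation of the delayed sensed state
    from the plan at the matching index; the prediction made 2 delta ago
    for that index sets the error magnitude.
    """
    teach = ms.teaching
    i_ref = t - n_delay
    th_d = bundle.plan.theta[i_ref]
    dth_d = bundle.plan.dtheta[i_ref]
    actual_dev = np.array([
        sensed[0] - th_d[0], sensed[2] - dth_d[0],
        sensed[1] - th_d[1], sensed[3] - dth_d[1],
    ])
    devs_then, gates_then, raw_then = delayed_pred
    lo = ms._dev_lo
    span = ms._dev_span
    tgt = np.clip(actual_dev, lo, lo + span)
    # update the running accuracy monitor from the raw (ungated) decode,
    # weighting samples by the deviation magnitude
    lam = ms.loop_cfg.accuracy_ema_decay
    w = np.abs(tgt) / span
    ms.pred_err_ema *= lam
    ms.pred_err_ema += (1.0 - lam) * w * np.abs(tgt - raw_then) / span
    ms.dev_mag_ema *= lam
    ms.dev_mag_ema += (1.0 - lam) * w * w
    ms._wsum_ema *= lam
    ms._wsum_ema += (1.0 - lam) * w
    # error magnitude scored against the raw decode, so teaching relaxes
    # to baseline as the stored profile approaches the target even while
    # the output gate is still closed
    err = np.minimum(np.abs(tgt - raw_then) / (teach.fwd_error_scale * span), 1.0)
    err = np.maximum(err - teach.deadband, 0.0) / (1.0 - teach.deadband)
    z_t = (tgt - lo) / span
    prof = np.exp(-0.5 * ((ms._zpref - z_t[:, None]) / teach.teach_sigma) ** 2)
    # carve at the target value, relax elsewhere: IO cells far from the
    # target are suppressed below baseline so stale dips get erased
    return (teach.cf_baseline_hz
            + (teach.cf_max_hz - teach.cf_baseline_hz) * err[:, None] * prof
            - teach.recovery_hz * err[:, None] * (1.0 - prof))


# ---------------------------------------------------------------------------
# offline consolidation

def offline_replay(stored_plans: list[tuple[np.ndarray, TrajectoryPlan]],
                   n_trajectories: int, arm_state: ArmState,
                   params: ArmParams, ms: ModelSet, centre,
                   rng: np.random.Generator, scheme: str = "CM",
                   cfg: LoopConfig | None = None) -> int:
    """Replay stored desired trajectories with no plant and no sensing.

    Plans are sampled uniformly with replacement ("randomly replayed");
    the forward predictors run but receive no teaching (their weights
    stay put by the LTP/LTD balance), and the inverse correctors adapt
    from desired-minus-predicted errors whenever the forward gates are
    open. Returns the number of replayed trajectories.
    """
    if not stored_plans:
        raise ValueError("offline replay needs at least one stored plan")
    cfg = cfg or ms.loop_cfg
    mode = ModeConfig(scheme=scheme, phase=OFFLINE, bias_deg=0.0)
    for _ in range(n_trajectories):
        target, plan = stored_plans[rng.integers(len(stored_plans))]
        run_trajectory(arm_state, params, ms, mode, target, centre,
                       plan=plan, cfg=cfg)
    return n_trajectories
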