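"""The rotation-adaptation experiment: schedule, subjects, groups.

Protocol (mirroring the human study the simulation emulates): eight
targets evenly spaced on a circle around the start position S; training
runs 4 steps x 3 trials with the anticlockwise bias growing by 15 deg
per step (15..60 deg); one trial is 90 s = 90 one-second trajectories
toward randomly chosen targets. A first probe trial (13) at 60 deg
follows training; groups with an offline consolidation period then
replay stored desired trajectories (no plant, no sensory feedback)
before a second probe trial (14), again at 60 deg.

Three schemes are compared: FM (forward predictors only), IM (inverse
correctors only) and CM (both coupled). A simulated subject is one fresh
set of eight microcomplexes plus plant; subjects differ only by seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arm import ArmParams, ArmState, reset_arm
from .controller import TrajectoryPlan, make_plan
from .loop import (LoopConfig, ModeConfig, ModelSet, TaskRanges,
                   derive_task_ranges, offline_replay, run_trajectory)
from .metrics import MetricConfig, improvement, trajectory_errors
from .models import TeachingConfig
from .network import MicrocomplexConfig

#: default start position of the hand (m, shoulder at the origin)
DEFAULT_CENTRE = (0.0, 0.42)


class ProtocolError(ValueError):
    pass


@dataclass
class ProtocolConfig:
    """Everything needed to run one subject through the experiment."""

    arm: ArmParams = field(default_factory=ArmParams)
    net: MicrocomplexConfig = field(default_factory=MicrocomplexConfig)
    loop: LoopConfig = field(default_factory=LoopConfig)
    teaching: TeachingConfig = field(default_factory=TeachingConfig)
    metric: MetricConfig = field(default_factory=MetricConfig)

    centre: tuple[float, float] = DEFAULT_CENTRE
    n_targets: int = 8
    #: radius chosen so the 15 deg chord equals the 36 mm normalization
    target_radius: float = 0.036 / (2.0 * math.sin(math.radians(7.5)))

    trial_trajectories: int = 90     # 90 s trials, one trajectory per second
    steps: int = 4                   # bias steps
    trials_per_step: int = 3
    bias_start_deg: float = 15.0
    bias_increment_deg: float = 15.0
    probe_bias_deg: float = 60.0
    consolidation_trials: int = 48
    n_subjects: int = 10

    @property
    def n_training_trials(self) -> int:
        return self.steps * self.trials_per_step

    def bias_schedule(self) -> list[float]:
        """Bias per training trial (trials 1..12 at defaults)."""
        return [self.bias_start_deg + self.bias_increment_deg * s
                for s in range(self.steps) for _ in range(self.trials_per_step)]

    def validate(self) -> None:
        sched = self.bias_schedule()
        if len(sched) != self.n_training_trials:
            raise ProtocolError("schedule does not cover the training trials")
        if any(b2 < b1 for b1, b2 in zip(sched, sched[1:])):
            raise ProtocolError("biases must be non-decreasing across trials")


def desk_scale_protocol(**overrides) -> ProtocolConfig:
    """A reduced configuration for desk-scale runs: 20 MFs per
    microcomplex (2000 GCs) and 30 trajectories per trial. Everything
    else, including the bias schedule, matches the full protocol."""
    cfg = ProtocolConfig(**overrides)
    cfg.net = MicrocomplexConfig(n_mf=20)
    cfg.trial_trajectories = 30
    return cfg


def make_targets(radius: float, centre, arm: ArmParams | None = None,
                 n_targets: int = 8) -> np.ndarray:
    """``n_targets`` positions evenly spaced (45 deg apart for 8) on the
    circle of the given radius around S, starting at +x."""
    centre = np.asarray(centre, float)
    if arm is not None:
        r_max = arm.L1 + arm.L2
        d = np.linalg.norm(centre) + radius
        if d > r_max:
            raise ProtocolError(
                f"target circle (max hand distance {d:.3f} m) exceeds reach {r_max:.3f} m")
    angles = np.arange(n_targets) * 2.0 * math.pi / n_targets
    return centre[None, :] + radius * np.stack([np.cos(angles), np.sin(angles)], axis=1)


@dataclass
class SubjectResult:
    """Per-trial mean errors and probe bookkeeping of one subject."""

    scheme: str
    seed: int
    trial_directional: np.ndarray    # mean normalized directional error per trial
    trial_distance: np.ndarray
    probe13: tuple[float, float]     # (directional, distance)
    probe14: tuple[float, float] | None
    consolidation_trajectories: int
    weight_checksums: dict

    @property
    def n_trials(self) -> int:
        return self.trial_directional.size

    def improvement(self) -> tuple[float, float] | None:
        """Percent improvement (directional, distance) between probes."""
        if self.probe14 is None:
            return None
        return (improvement(self.probe13[0], self.probe14[0]),
                improvement(self.probe13[1], self.probe14[1]))


class Subject:
    """One simulated individual: arm + eight microcomplexes + RNG."""

    def __init__(self, protocol: ProtocolConfig, seed: int,
                 ranges: TaskRanges | None = None):
        protocol.validate()
        self.protocol = protocol
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        s_models, s_targets, s_replay = (int(s.generate_state(1)[0] % (2 ** 31))
                                         for s in ss.spawn(3))
        self.rng = np.random.default_rng(s_targets)
        self.replay_rng = np.random.default_rng(s_replay)
        self.centre = np.asarray(protocol.centre, float)
        self.targets = make_targets(protocol.target_radius, self.centre,
                                    protocol.arm, protocol.n_targets)
        if ranges is None:
            ranges = derive_task_ranges(
                protocol.arm, self.centre, protocol.target_radius,
                protocol.loop.movement_s)
        self.models = ModelSet(protocol.net, ranges, s_models,
                               protocol.loop, protocol.teaching)
        self.arm_state = reset_arm(ArmState(), self.centre, protocol.arm)
        self.base_plans = [make_plan(self.centre, self.targets[k],
                                     protocol.loop.movement_s, protocol.arm)
                           for k in range(protocol.n_targets)]
        self.online_target_log: list[int] = []

    def run_trial(self, bias_deg: float, scheme: str,
                  log_targets: bool = True) -> tuple[float, float]:
        """One 90 s trial; returns the mean (directional, distance) error
        over its trajectories."""
        p = self.protocol
        mode = ModeConfig(scheme=scheme, bias_deg=bias_deg)
        dir_sum = dist_sum = 0.0
        for _ in range(p.trial_trajectories):
            k = int(self.rng.integers(p.n_targets))
            if log_targets:
                self.online_target_log.append(k)
            rec, self.arm_state = run_trajectory(
                self.arm_state, p.arm, self.models, mode,
                self.targets[k], self.centre, plan=self.base_plans[k],
                cfg=p.loop, seed=self.seed)
            err = trajectory_errors(rec.movement_path, self.centre,
                                    self.targets[k], bias_deg, p.metric,
                                    p.loop.dt, rec.movement_vel)
            dir_sum += err.directional
            dist_sum += err.distance
        n = p.trial_trajectories
        return dir_sum / n, dist_sum / n

    def run_consolidation(self, n_trials: int, scheme: str = "CM") -> int:
        """Offline replay of stored desired trajectories; returns the
        number of trajectories replayed."""
        p = self.protocol
        if not self.online_target_log:
            raise ProtocolError("no stored online trajectories to replay")
        stored = [(self.targets[k], self.base_plans[k])
                  for k in self.online_target_log]
        n = n_trials * p.trial_trajectories
        return offline_replay(stored, n, self.arm_state, p.arm, self.models,
                              self.centre, self.replay_rng, scheme, p.loop)


def run_subject(scheme: str, protocol: ProtocolConfig,
                consolidation_trials: int, seed: int,
                ranges: TaskRanges | None = None) -> SubjectResult:
    """Run one subject through training, probe 13, optional offline
    consolidation and probe 14."""
    subj = Subject(protocol, seed, ranges)
    sched = protocol.bias_schedule()
    dir_err = []
    dist_err = []
    for bias in sched:
        d, l = subj.run_trial(bias, scheme)
        dir_err.append(d)
        dist_err.append(l)
    checks = {}
    probe13 = subj.run_trial(protocol.probe_bias_deg, scheme, log_targets=False)
    checks["probe13"] = subj.models.checksums()
    n_replayed = 0
    if consolidation_trials > 0:
        n_replayed = subj.run_consolidation(consolidation_trials, scheme)
        checks["post_consolidation"] = subj.models.checksums()
    probe14 = subj.run_trial(protocol.probe_bias_deg, scheme, log_targets=False)
    checks["probe14"] = subj.models.checksums()
    dir_err += [probe13[0], probe14[0]]
    dist_err += [probe13[1], probe14[1]]
    return SubjectResult(scheme, seed, np.array(dir_err), np.array(dist_err),
                         probe13, probe14, n_replayed, checks)


@dataclass
class GroupResult:
    scheme: str
    subjects: list[SubjectResult]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def trial_matrix(self, which: str = "directional") -> np.ndarray:
        """(n_subjects, n_trials) error matrix."""
        attr = "trial_directional" if which == "directional" else "trial_distance"
        return np.stack([getattr(s, attr) for s in self.subjects])

    def mean_errors(self, which: str = "directional") -> np.ndarray:
        return self.trial_matrix(which).mean(axis=0)

    def sem_errors(self, which: str = "directional") -> np.ndarray:
        m = self.trial_matrix(which)
        return m.std(axis=0, ddof=1) / math.sqrt(m.shape[0])

    def improvements(self) -> np.ndarray:
        """(n_subjects, 2) percent improvements between probes 13 and 14."""
        return np.array([s.improvement() for s in self.subjects])


def run_group(scheme: str, n_subjects: int, protocol: ProtocolConfig,
              seeds, consolidation_trials: int = 0,
              ranges: TaskRanges | None = None) -> GroupResult:
    """Run an independent group of subjects (distinct seeds required)."""
    seeds = list(seeds)
    if len(seeds) != n_subjects:
        raise ProtocolError("need exactly one seed per subject")
    if len(set(seeds)) != len(seeds):
        raise ProtocolError("duplicate seeds: subjects must be independent")
    if n_subjects < 2:
        raise ProtocolError("a group needs at least two subjects")
    if ranges is None:
        centre = np.asarray(protocol.centre, float)
        ranges = derive_task_ranges(protocol.arm, centre,
                                    protocol.target_radius,
                                    protocol.loop.movement_s)
    results = [run_subject(scheme, protocol, consolidation_trials, s, ranges)
               for s in seeds]
    return GroupResult(scheme, results)


def run_consolidation_sweep(durations, protocol: ProtocolConfig, seeds,
                            n_subjects: int | None = None,
                            ranges: TaskRanges | None = None) -> dict:
    """Independent CM_sleep groups, one per consolidation duration.

    ``durations`` is the list of offline trial counts (the full protocol
    uses 1, 2, 3, 4, 6, 12, 24, 48); each duration gets its own group.
    Returns {duration: GroupResult}. Duration 0 reproduces CM_wake.
    """
    n_subjects = n_subjects or protocol.n_subjects
    out = {}
    for i, d in enumerate(durations):
        group_seeds = [s + 1_000_003 * i for s in seeds]
        out[int(d)] = run_group("CM", n_subjects, protocol, group_seeds,
                                consolidation_trials=int(d), ranges=ranges)
    return out
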