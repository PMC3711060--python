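"""Forward predictors and inverse correctors built on microcomplexes.

Each internal model wraps one cerebellar microcomplex with

* an **encoder** that population-codes its physical inputs onto the MF
  layer (Gaussian tuning curves tiling the normalized input box),
* a **decoder** over the DCN output — a local code (rate-weighted
  preferred values plus a confidence gate) for the four forward
  predictors, the population mean rate for the four inverse correctors,
* a **teaching-signal** rule that maps the relevant error onto CF rates.

Forward predictors receive the efference copy of the final torque
command together with the desired joint state, and predict the *future
deviation* of the joint from its plan (actual minus desired, one
predictor each for shoulder/elbow position and velocity); the emitted
prediction is desired + decoded deviation, i.e. the future angular state
itself. Spanning the local code over the deviation rather than the raw
angle keeps the code's dynamic range small and makes the confidence gate
meaningful: an untrained predictor produces a flat DCN profile and stays
silent.

Inverse correctors come in agonist/antagonist pairs per joint (positive
and negative torque ranges). Their teaching signal is the sensorimotor
error transform e = Kp (theta_d - theta_ref) + Kv (dtheta_d - dtheta_ref),
with the reference being the delayed sensed state online and the forward
prediction during offline replay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import MicrocomplexConfig

# phase tags
ONLINE = "online"
OFFLINE = "offline"


class PhaseError(RuntimeError):
    """A teaching rule was invoked in a phase that forbids it."""


# ---------------------------------------------------------------------------
# MF population encoding

@dataclass
class EncoderConfig:
    """Gaussian tuning curves tiling a (possibly multi-dimensional) box.

    ``ranges`` is (d, 2) with the physical [lo, hi] of each input; MF
    centres tile the normalized unit box with spacing-proportional width
    sigma = sigma_scale * spacing. Centres extend one spacing beyond the
    box so the summed drive stays nearly flat across the whole range.
    """

    centres: np.ndarray          # (n_mf, d) in normalized coordinates
    sigma: float                 # normalized units
    ranges: np.ndarray           # (d, 2)
    max_rate_hz: float = 120.0

    @property
    def n_mf(self) -> int:
        return self.centres.shape[0]


def make_encoder(n_mf: int, ranges, max_rate_hz: float = 120.0,
                 sigma_scale: float = 1.5, margin: float = 1.0,
                 samples: np.ndarray | None = None) -> EncoderConfig:
    """Lay out ``n_mf`` Gaussian tuning curves over the input space.

    Without ``samples``, 1-D and 2-D inputs get a regular grid and
    higher dimensions a deterministic low-discrepancy (Halton) point
    set over the whole box. With ``samples`` — a set of input vectors
    representative of what the task actually visits — the centres are
    placed on that manifold by (deterministic, seeded) k-means, and the
    tuning width follows the typical nearest-neighbour spacing of the
    centres. The layout is a pure function of the arguments, so
    identically-configured encoders are identical across subjects.
    """
    ranges = np.atleast_2d(np.asarray(ranges, float))
    d = ranges.shape[0]
    lo, hi = ranges[:, 0], ranges[:, 1]
    if samples is not None:
        from scipy.cluster.vq import kmeans2
        z = (np.clip(np.asarray(samples, float), lo, hi) - lo) / (hi - lo)
        centres, _ = kmeans2(z, n_mf, minit="++", seed=1234)
        dists = np.sqrt(((centres[:, None, :] - centres[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(dists, np.inf)
        spacing = float(np.median(dists.min(axis=1)))
    elif d == 1:
        spacing = 1.0 / n_mf
        pad = margin * spacing
        centres = np.linspace(-pad, 1.0 + pad, n_mf)[:, None]
    elif d == 2:
        n1 = int(round(math.sqrt(n_mf)))
        while n_mf % n1:
            n1 -= 1
        n2 = n_mf // n1
        spacing = 1.0 / math.sqrt(n1 * n2)
        pad = margin * spacing
        g1 = np.linspace(-pad, 1.0 + pad, n1)
        g2 = np.linspace(-pad, 1.0 + pad, n2)
        centres = np.stack(np.meshgrid(g1, g2, indexing="ij"), axis=-1).reshape(-1, 2)
    else:
        from scipy.stats import qmc
        spacing = n_mf ** (-1.0 / d)
        pad = margin * spacing
        sampler = qmc.Halton(d=d, scramble=False)
        centres = sampler.random(n_mf) * (1.0 + 2 * pad) - pad
    sigma = sigma_scale * spacing
    return EncoderConfig(centres, sigma, ranges, max_rate_hz)


def encode_mf(values, enc: EncoderConfig) -> np.ndarray:
    """Per-MF drive (Hz) for a physical input vector.

    Values outside the configured ranges are clamped. Each MF responds
    with max_rate times a Gaussian of the normalized distance to its
    tuning centre.
    """
    v = np.atleast_1d(np.asarray(values, float))
    if v.shape[0] != enc.ranges.shape[0]:
        raise ValueError(f"expected {enc.ranges.shape[0]} input values, got {v.shape[0]}")
    lo, hi = enc.ranges[:, 0], enc.ranges[:, 1]
    z = (np.clip(v, lo, hi) - lo) / (hi - lo)
    d2 = ((enc.centres - z[None, :]) ** 2).sum(axis=1)
    return enc.max_rate_hz * np.exp(-0.5 * d2 / enc.sigma ** 2)


# ---------------------------------------------------------------------------
# DCN decoding

@dataclass
class TeachingSignal:
    """CF drive (Hz per IO cell) for one microcomplex, with provenance."""

    io_rates: np.ndarray
    phase: str = ONLINE
    source: str = "sensed"        # sensed | predicted | actual-state
    normalized_error: float = 0.0  # in [-1, 1]


def decode_forward(dcn_rates: np.ndarray, preferred_values: np.ndarray,
                   confidence_threshold: float = 2.0,
                   min_rate_hz: float = 2.0):
    """Local-code readout: rate-weighted preferred value + confidence gate.

    The population mean is subtracted before weighting so the flat
    (uninformative) component of the profile does not drag the estimate
    toward the centre of the range. Confidence measures how peaked the
    profile is above its own floor, (peak - min) / (mean - min): a flat
    (untrained, uninformative) profile scores ~1 and keeps the gate
    closed; a single dominant cell scores the population size. Returns
    (value | None, confidence).
    """
    r = np.asarray(dcn_rates, float)
    mn, mx, mean = r.min(), r.max(), r.mean()
    if mx < min_rate_hz or mean <= mn:
        return None, 0.0
    confidence = float((mx - mn) / (mean - mn))
    excess = np.maximum(r - mean, 0.0)
    total = excess.sum()
    if confidence < confidence_threshold or total <= 0:
        return None, confidence
    return float(np.dot(excess, preferred_values) / total), confidence


def decode_inverse(agonist_rates: np.ndarray, antagonist_rates: np.ndarray,
                   gain: float, max_rate_hz: float) -> float:
    """Population-rate readout of a corrector pair:
    tau = gain * (mean agonist - mean antagonist) / max_rate."""
    return gain * (float(np.mean(agonist_rates)) - float(np.mean(antagonist_rates))) / max_rate_hz


# ---------------------------------------------------------------------------
# teaching-signal construction

@dataclass
class TeachingConfig:
    """Sensorimotor error transform and CF rate mapping."""

    k_p: float = 1.0              # N m / rad
    k_v: float = 0.1              # N m s / rad
    error_scale: float = 0.8      # motor error (N m) mapped to full CF range
    fwd_error_scale: float = 0.5  # prediction error, fraction of the value range
    deadband: float = 0.03        # errors below this fraction leave CF at baseline
    #: rate of suppression-recovery events on the unit whose IO is pushed
    #: below baseline by the error (net potentiation of its active PFs)
    recovery_hz: float = 5.0
    cf_baseline_hz: float = 1.0
    cf_max_hz: float = 10.0
    teach_sigma: float = 0.08     # width of the CF value profile (normalized)


def motor_error(desired_pos: float, desired_vel: float,
                ref_pos: float, ref_vel: float, cfg: TeachingConfig) -> float:
    """Sensory-to-motor error transform (assumed known): a PD combination
    of the position and velocity discrepancies for one joint."""
    return cfg.k_p * (desired_pos - ref_pos) + cfg.k_v * (desired_vel - ref_vel)


def teach_forward_rates(target_value: float, predicted_value: float | None,
                        preferred_values: np.ndarray, value_range: tuple[float, float],
                        cfg: TeachingConfig, phase: str = ONLINE) -> TeachingSignal:
    """CF rates for one forward predictor (online only).

    The supervised target is the actual (delayed sensed) deviation; CF
    drive rises above baseline only where the prediction disagrees with
    it, with a Gaussian profile centred on the target value so that LTD
    disinhibits the DCN cells coding for the correct value.
    """
    if phase != ONLINE:
        raise PhaseError("forward-model teaching is absent during offline consolidation")
    lo, hi = value_range
    span = hi - lo
    t = float(np.clip(target_value, lo, hi))
    if predicted_value is None:
        err = 1.0
    else:
        err = abs(t - predicted_value) / (cfg.fwd_error_scale * span)
        err = min(err, 1.0)
    z_t = (t - lo) / span
    z_pref = (np.asarray(preferred_values, float) - lo) / span
    profile = np.exp(-0.5 * ((z_pref - z_t) / cfg.teach_sigma) ** 2)
    rates = cfg.cf_baseline_hz + (cfg.cf_max_hz - cfg.cf_baseline_hz) * err * profile
    signed = err if predicted_value is None or t >= predicted_value else -err
    return TeachingSignal(rates, ONLINE, "actual-state", signed)


def teach_inverse_rates(e_tau: float, n_io: int, cfg: TeachingConfig,
                        sign: int, phase: str = ONLINE,
                        source: str = "sensed") -> TeachingSignal:
    """CF rates for one inverse corrector unit.

    A positive motor error drives the agonist unit's CFs above baseline,
    a negative error the antagonist's; the opposite unit stays at
    baseline. ``sign`` is +1 for the agonist, -1 for the antagonist.
    """
    e_norm = float(np.clip(e_tau / cfg.error_scale, -1.0, 1.0))
    drive = max(0.0, sign * e_norm)
    rates = np.full(n_io, cfg.cf_baseline_hz + (cfg.cf_max_hz - cfg.cf_baseline_hz) * drive)
    return TeachingSignal(rates, phase, source, e_norm)


# ---------------------------------------------------------------------------
# model wrappers

FORWARD_QUANTITIES = ("shoulder_angle", "shoulder_velocity",
                      "elbow_angle", "elbow_velocity")


@dataclass
class ForwardPredictor:
    """One microcomplex predicting the future deviation of one joint
    quantity from its plan, 50 ms ahead of the efference copy."""

    quantity: str                        # one of FORWARD_QUANTITIES
    encoder: EncoderConfig               # over (own-joint torque, full desired state)
    preferred_values: np.ndarray         # deviation axis (PC-indexed)
    dcn_preferred: np.ndarray            # deviation axis (DCN-indexed)
    deviation_range: tuple[float, float]
    confidence_threshold: float = 2.0
    joint: int = 0                       # 0 shoulder, 1 elbow
    is_velocity: bool = False
    teaching: TeachingConfig = field(default_factory=TeachingConfig)

    def encode(self, torque: float, desired_theta, desired_dtheta) -> np.ndarray:
        """MF drive for (own-joint torque efference, full desired state)."""
        return encode_mf((torque, desired_theta[0], desired_theta[1],
                          desired_dtheta[0], desired_dtheta[1]), self.encoder)

    def decode(self, dcn_rates: np.ndarray):
        """(deviation | None, confidence); gate closed => no prediction."""
        return decode_forward(dcn_rates, self.dcn_preferred, self.confidence_threshold)

    def teach(self, actual_deviation: float, predicted_deviation: float | None,
              phase: str = ONLINE) -> TeachingSignal:
        return teach_forward_rates(actual_deviation, predicted_deviation,
                                   self.preferred_values, self.deviation_range,
                                   self.teaching, phase)


@dataclass
class InverseCorrector:
    """One microcomplex contributing half of a joint's corrective torque:
    the agonist unit covers the positive torque range, the antagonist the
    negative one."""

    joint: int                           # 0 shoulder, 1 elbow
    sign: int                            # +1 agonist, -1 antagonist
    encoder: EncoderConfig               # over the full desired joint state
    torque_gain: float = 2.0             # N m at full population rate
    max_rate_hz: float = 100.0
    n_io: int = 30
    teaching: TeachingConfig = field(default_factory=TeachingConfig)

    def encode(self, desired_state) -> np.ndarray:
        """MF drive for the desired state vector (theta_s, theta_e,
        dtheta_s, dtheta_e)."""
        return encode_mf(desired_state, self.encoder)

    def decode(self, dcn_rates: np.ndarray) -> float:
        """Signed torque contribution; agonist >= 0, antagonist <= 0."""
        r = float(np.mean(dcn_rates))
        return self.sign * self.torque_gain * r / self.max_rate_hz

    def teach(self, desired_pos: float, desired_vel: float,
              ref_pos: float, ref_vel: float, phase: str = ONLINE,
              source: str = "sensed") -> TeachingSignal:
        e = motor_error(desired_pos, desired_vel, ref_pos, ref_vel, self.teaching)
        return teach_inverse_rates(e, self.n_io, self.teaching,
                                   self.sign, phase, source)
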