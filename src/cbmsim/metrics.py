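"""Performance measures for the rotation-adaptation task.

Two normalized, independently computed measures quantify motor learning:

* **directional error** — the unsigned angle between the straight line
  from the start position S to the target and the instantaneous movement
  direction at the moment of peak outward (radial) hand speed, divided
  by a normalization angle;
* **distance error** — the Euclidean distance between the target T and
  the final hand position E, divided by a normalization distance.

The normalization is bias-relative by default: the raw angle is divided
by the current rotation bias and the raw distance by the chord that the
bias subtends on the target circle, so a completely unadapted subject
scores ~1 at every bias step. At the 15 deg step this makes an error of
1 correspond to 15 deg and 36 mm respectively. A fixed-at-15-deg
normalization is available as a config switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class MetricConfig:
    """Normalization constants for the two error measures."""

    #: radius of the target circle (m); the default makes the 15 deg chord
    #: exactly 36 mm: R = 0.036 / (2 sin 7.5 deg)
    target_radius: float = 0.036 / (2.0 * math.sin(math.radians(7.5)))
    #: divide by the current bias (True) or always by the 15 deg constants
    bias_relative: bool = True
    reference_bias_deg: float = 15.0

    def norm_angle_deg(self, bias_deg: float) -> float:
        b = bias_deg if self.bias_relative else self.reference_bias_deg
        if b <= 0:
            raise ValueError("normalization requires a positive bias")
        return b

    def norm_distance_m(self, bias_deg: float) -> float:
        b = self.norm_angle_deg(bias_deg)
        return 2.0 * self.target_radius * math.sin(math.radians(b) / 2.0)


@dataclass
class ErrorMetrics:
    """Raw and normalized errors of one trajectory."""

    directional: float      # normalized, dimensionless, >= 0
    distance: float         # normalized, dimensionless, >= 0
    raw_angle_deg: float
    raw_distance_mm: float
    trajectory_id: int = -1


class MotionlessRecordError(ValueError):
    """No outward motion found in the movement window."""


def peak_outward_velocity_direction(hand_path: np.ndarray, centre,
                                    dt: float = 1e-3,
                                    velocity: np.ndarray | None = None):
    """Movement heading (unit vector) at peak outward speed, and its index.

    ``hand_path`` is the (N, 2) hand trajectory of the 0.7 s movement
    window; ``centre`` the start position S. The outward speed is the
    radial component (away from S) of the hand velocity; ties are broken
    by the earliest index. If ``velocity`` is not given it is obtained by
    central differences of the path.
    """
    path = np.asarray(hand_path, float)
    if path.ndim != 2 or path.shape[0] < 2:
        raise ValueError("need at least two samples of the hand path")
    centre = np.asarray(centre, float)
    if velocity is None:
        velocity = np.gradient(path, dt, axis=0)
    rel = path - centre[None, :]
    dist = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        radial_dir = np.where(dist[:, None] > 1e-12, rel / np.maximum(dist, 1e-12)[:, None], 0.0)
    outward = np.einsum("ij,ij->i", radial_dir, velocity)
    # require genuinely outward motion: a purely tangential path only has
    # numerical-differentiation residue in its radial component
    floor = max(1e-9, 3e-3 * float(np.linalg.norm(velocity, axis=1).max()))
    if np.all(outward <= floor):
        raise MotionlessRecordError("no outward motion in the movement window")
    idx = int(np.argmax(outward))  # argmax returns the earliest maximum
    speed = np.linalg.norm(velocity[idx])
    if speed <= 0:
        raise MotionlessRecordError("zero hand speed at the peak-outward sample")
    return velocity[idx] / speed, idx


def directional_error(hand_path: np.ndarray, centre, target, bias_deg: float,
                      cfg: MetricConfig | None = None, dt: float = 1e-3,
                      velocity: np.ndarray | None = None) -> tuple[float, float]:
    """(normalized, raw degrees) directional error of one trajectory."""
    cfg = cfg or MetricConfig()
    heading, _ = peak_outward_velocity_direction(hand_path, centre, dt, velocity)
    tvec = np.asarray(target, float) - np.asarray(centre, float)
    tnorm = np.linalg.norm(tvec)
    if tnorm <= 0:
        raise ValueError("target coincides with the start position")
    cosang = float(np.clip(np.dot(heading, tvec / tnorm), -1.0, 1.0))
    raw_deg = math.degrees(math.acos(cosang))
    return raw_deg / cfg.norm_angle_deg(bias_deg), raw_deg


def distance_error(endpoint, target, bias_deg: float,
                   cfg: MetricConfig | None = None) -> tuple[float, float]:
    """(normalized, raw mm) distance error between endpoint E and target T."""
    cfg = cfg or MetricConfig()
    d = float(np.linalg.norm(np.asarray(endpoint, float) - np.asarray(target, float)))
    return d / cfg.norm_distance_m(bias_deg), d * 1000.0


def trajectory_errors(hand_path: np.ndarray, centre, target, bias_deg: float,
                      cfg: MetricConfig | None = None, dt: float = 1e-3,
                      velocity: np.ndarray | None = None,
                      trajectory_id: int = -1) -> ErrorMetrics:
    nd, raw_deg = directional_error(hand_path, centre, target, bias_deg, cfg, dt, velocity)
    nl, raw_mm = distance_error(hand_path[-1], target, bias_deg, cfg)
    return ErrorMetrics(nd, nl, raw_deg, raw_mm, trajectory_id)


def percent_change(error_13: float, error_14: float) -> float:
    """(e14 - e13) / e13 * 100; negative values mean the error decreased.

    The reported *improvement* is the negation of this quantity.
    """
    if error_13 <= 0:
        raise ValueError("percent change undefined for a zero trial-13 error")
    return (error_14 - error_13) / error_13 * 100.0


def improvement(error_13: float, error_14: float) -> float:
    """Positive when performance improved between the two probe trials."""
    return -percent_change(error_13, error_14)


def one_way_anova(*groups) -> tuple[float, float, tuple[int, int]]:
    """One-way fixed-effects ANOVA over per-subject values.

    Returns (F, p, (df_between, df_within)) with df = (k-1, N-k). A fully
    degenerate input (zero between- and within-group variance) yields F=0.
    """
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need at least two groups of at least two subjects")
    n_total = sum(a.size for a in arrays)
    df = (len(arrays) - 1, n_total - len(arrays))
    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0:
        return 0.0, 1.0, df
    f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):
        f, p = 0.0, 1.0
    return float(f), float(p), df
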