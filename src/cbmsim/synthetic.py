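"""Synthetic inputs with analytically known ground truth.

These generators make every stage testable without running the full
closed loop: canned hand trajectories whose metric values are known by
construction, and Poisson spike rasters with specified rates for
exercising decoders and plasticity in isolation. Everything is generated
programmatically; nothing is stored on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .controller import minimum_jerk
from .metrics import MetricConfig


def rotate_about(points: np.ndarray, angle_deg: float, centre) -> np.ndarray:
    """Rotate points anticlockwise by ``angle_deg`` about ``centre``."""
    a = math.radians(angle_deg)
    R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    pts = np.atleast_2d(np.asarray(points, float))
    centre = np.asarray(centre, float)
    out = (pts - centre) @ R.T + centre
    return out if np.ndim(points) > 1 else out[0]


@dataclass
class CannedTrajectory:
    """An analytic hand path with its known metric ground truth attached."""

    hand_path: np.ndarray       # (N, 2)
    velocity: np.ndarray        # (N, 2), analytic
    centre: np.ndarray          # start position S
    target: np.ndarray          # intended target T
    bias_deg: float
    dt: float
    expected_directional: float   # normalized, by construction
    expected_distance: float
    expected_raw_angle_deg: float
    expected_raw_distance_mm: float


def make_rotated_reach(bias_deg: float, radius: float | None = None,
                       centre=(0.0, 0.0), target_angle_deg: float = 0.0,
                       duration: float = 0.7, dt: float = 1e-3,
                       cfg: MetricConfig | None = None) -> CannedTrajectory:
    """Straight minimum-jerk reach rotated anticlockwise by ``bias_deg``.

    The reach aims at a target at ``target_angle_deg`` on the circle of
    the configured radius around ``centre``; the executed path is the
    same reach rotated by the bias, which pins both metric values
    analytically: the heading at peak speed deviates by exactly the bias,
    and the endpoint misses the target by the chord of the bias.
    """
    cfg = cfg or MetricConfig()
    radius = cfg.target_radius if radius is None else radius
    if not (0.0 <= bias_deg < 90.0):
        raise ValueError("bias must lie in [0, 90) degrees")
    centre = np.asarray(centre, float)
    ang = math.radians(target_angle_deg)
    target = centre + radius * np.array([math.cos(ang), math.sin(ang)])
    t = np.arange(int(round(duration / dt))) * dt
    pos, vel, _ = minimum_jerk(centre, target, duration, t)
    path = rotate_about(pos, bias_deg, centre)
    velr = rotate_about(vel, bias_deg, (0.0, 0.0))

    norm_angle = cfg.norm_angle_deg(bias_deg) if bias_deg > 0 else None
    chord = 2.0 * radius * math.sin(math.radians(bias_deg) / 2.0)
    if bias_deg > 0:
        expected_dir = bias_deg / norm_angle
        expected_dist = chord / cfg.norm_distance_m(bias_deg)
    else:
        expected_dir = 0.0
        expected_dist = 0.0
    return CannedTrajectory(path, velr, centre, target, bias_deg, dt,
                            expected_dir, expected_dist, bias_deg, chord * 1000.0)


def make_curved_arc(sweep_deg: float, radius: float, centre=(0.0, 0.0),
                    duration: float = 0.7, dt: float = 1e-3) -> np.ndarray:
    """Purely tangential circular motion around the centre (no outward
    component) — useful for exercising degenerate metric inputs."""
    t = np.arange(int(round(duration / dt))) * dt
    ang = np.radians(sweep_deg) * t / duration
    centre = np.asarray(centre, float)
    return centre + radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)


@dataclass
class SyntheticSpikeStream:
    """Independent-Poisson spike raster with its generating rates."""

    raster: np.ndarray      # (n_steps, n_neurons) bool
    rates: np.ndarray       # (n_neurons,) Hz
    dt: float
    seed: int


def make_poisson_raster(rates, duration: float, seed: int,
                        dt: float = 1e-3) -> SyntheticSpikeStream:
    """Seed-deterministic independent Poisson spikes per neuron."""
    rates = np.asarray(rates, float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    raster = rng.random((n_steps, rates.size)) < rates[None, :] * dt
    return SyntheticSpikeStream(raster, rates, dt, seed)
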