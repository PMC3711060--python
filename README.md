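# cbmsim — coupled spiking cerebellar internal models for arm control

`cbmsim` is a research simulator for studying how *forward* and
*inverse* internal models, implemented as spiking cerebellar
microcomplexes, cooperate during sensorimotor adaptation — online,
through delayed sensory feedback, and offline, by replaying desired
trajectories against the forward models' own predictions.

A purely algorithmic high-level controller plans minimum-jerk reaches of
a planar two-joint arm (M(θ)θ̈ + C(θ,θ̇) + Bθ̇ = τ, Δt = 1 ms) toward
eight targets on a circle, with command and sensory pathways each
delayed by δ = 50 ms. Eight cerebellar microcomplexes — granule-layer
expansion recoding (|GC| = 100·|MF|, granule in-degree 4), Purkinje
cells, and deep-nucleus output, with parallel-fibre→Purkinje-cell
synapses as the only plastic site (non-associative LTP, climbing-fibre
gated heterosynaptic LTD, calibrated so the two balance exactly without
a teaching signal) — implement:

* four **inverse correctors** (agonist/antagonist per joint) that add
  corrective torques, trained by the sensorimotor error
  e = K_p(θ_d − θ̄) + K_v(θ̇_d − θ̇̄);
* four **forward predictors** that estimate each joint's future state
  from the efference copy of the final command, feeding mid-movement
  replanning and, during offline consolidation, standing in for the
  missing sensory feedback.

The experiment is a visuomotor rotation-adaptation protocol: an
anticlockwise bias (15°→60° in four steps of three 90-trajectory
trials) rotates the executed hand paths; probe trials 13/14 at 60°
bracket an optional offline replay period. Performance is measured by
the normalized **directional error** (heading at peak outward speed vs
the straight line to the target; 1.0 ≙ 15° at the first step) and
**distance error** (endpoint miss; 1.0 ≙ 36 mm), and compared across
the forward-only (FM), inverse-only (IM) and coupled (CM) schemes.

The model and the science behind every constant are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```bash
python examples/02_corrector_adaptation.py
```

runs one desk-scale subject (20 mossy fibres per microcomplex, 30
trajectories per trial) in the inverse-only scheme at a fixed 15° bias
and prints:

```
trial  directional  distance   (normalized; 1.0 = unadapted)
    1        0.739     0.995
    2        0.487     0.833
    3        0.472     0.745
    4        0.545     0.757
    5        0.422     0.517
    6        0.369     0.806
```

Trial 1 already sits below 1.0 — the correctors start learning within
the first 90 seconds — and by trial 5–6 the heading error is down to
roughly a third of the imposed rotation (individual trials stay noisy
at this scale; group curves in the test suite average three subjects). The other example scripts show
the unperturbed feedforward baseline (`01`), the LTP/LTD balance that
protects stored memories when no teaching signal arrives (`03`), and a
paired wake-versus-replay probe comparison (`04`).

A thin command-line interface wraps the protocol runner for batch use:

```bash
cbmsim run-group --scheme CM --n-subjects 3 --seed 1 --out results_group
cbmsim sweep-consolidation --durations 2,6,12 --seed 1 --out results_sweep
```

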