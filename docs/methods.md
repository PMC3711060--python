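# Methods

`cbmsim` simulates a pair of coupled cerebellar internal models — four
*forward predictors* and four *inverse correctors*, each a spiking
microcomplex — controlling a planar two-joint arm in a visuomotor
rotation-adaptation task, with online learning from delayed sensory
feedback and offline consolidation by replaying desired trajectories
against the forward models' predictions.

## The plant and the high-level controller

The arm is a rigid two-link chain (shoulder + elbow) moving in the
horizontal plane:

    M(θ) θ̈ + C(θ, θ̇) + B θ̇ = τ

with link lengths L1 = L2 = 0.30 m, masses 1.4/1.0 kg, uniform-rod
inertias, viscous friction 0.05 N·m·s/rad per joint and no gravity. The
plant advances with an explicit-midpoint step at the global Δt = 1 ms;
second-order accuracy keeps the 1 ms step within 1e-4 rad of a fine-step
reference integration over a reach. Torques are clamped at ±20 N·m.

The high-level controller is purely algorithmic: a minimum-jerk quintic
plans the hand path (0.7 s per reach), the closed-form two-link inverse
kinematics (elbow-positive branch, fixed for reproducibility) and the
analytic Jacobian map it to joint space, and a computed-torque law on
the nominal model emits feedforward commands. Commands and sensory
feedback are each delayed by δ = 50 ms. The controller indexes its plan
δ ahead when emitting (it knows its own actuation latency) and issues
the first δ of commands during the tail of the preceding reset window,
so the unbiased baseline tracks the plan essentially exactly; all
remaining error is what the cerebellar models must learn.

Mid-movement replanning (forward/coupled schemes only) re-issues a
quintic with full position/velocity/acceleration boundary conditions
every 10 ms from the predicted hand position — blended at 40% of the
predicted offset, with the plan's own velocity boundary and a 1.5 cm
deadband, because decoded predictions are too coarse to anchor a
quintic's velocity. A replan whose path would leave the workspace is
discarded.

## The microcomplex

Each internal model is one microcomplex: |GC| = 100·|MF|, MF→GC wiring
Bernoulli with mean granule-cell in-degree 4 (probability 0.04 at the
reference |MF| = 100; scaled runs keep the in-degree, not the
probability), 30 Purkinje cells, 6 deep-nucleus cells, one climbing
fibre per PC. MFs excite the DCN all-to-all with fixed weights; PCs
inhibit it; PF→PC synapses are the only plastic ones. Neurons are
current-based leaky integrate-and-fire (τ_m = 10 ms for GC/PC, 20 ms for
DCN, refractory 1–2 ms). The DCN input passes through a slow (15 ms)
synaptic filter — the model's reading of slow mossy-fibre–nuclear
conductances — which regularizes DCN firing enough for a low-noise rate
code downstream.

MF spike generation defaults to clock-like phase accumulators (per-fibre
phases fixed per subject) rather than Poisson sampling. With a purely
feedforward plant, Poisson input noise propagates into a corrective-
torque jitter that integrates into centimetre-scale endpoint scatter and
drives spurious bidirectional teaching; the clock code keeps the rate
information and removes the sampling noise. Poisson generation remains
available (`mf_mode="poisson"`).

### Plasticity

Two processes act at PF–PC synapses:

* non-associative LTP: each PF spike adds `alpha_ltp` to that fibre's
  synapses;
* CF-gated heterosynaptic LTD: a CF event on PC j subtracts
  `alpha_ltd · trace_i` from every synapse (i, j), where `trace_i` is an
  exponential eligibility trace (τ = 50 ms) of PF spikes.

The CF baseline rate (1 Hz) is calibrated against LTP:
`alpha_ltp = alpha_ltd · r_baseline · τ_trace`, and the baseline
component is applied as its deterministic per-step expectation, which
makes the compensation exact per PF spike: without a teaching signal a
stored input–output mapping persists indefinitely (the homeostatic
property offline consolidation relies on). Only supra-baseline CF
activity arrives as discrete events. Teaching can also *suppress* an IO
below baseline; the balance then tips toward net potentiation of the
recently active synapses (events at the deficit rate). This
suppression-recovery channel is what lets an overcommitted corrector
relax instead of ratcheting both agonist and antagonist to their weight
floors, and what erases stale peaks in the forward models' local code.

PF spikes enter the plasticity machinery (eligibility + LTP) after a
*credit lag* derived from the loop's latencies (actuation delay + decode
lag + activation lag + half a trace lifetime; ≈ 0.10 s for forward nets,
≈ 0.18 s for correctors). Without it, CF teaching — which reports errors
from 2δ in the past — would credit the wrong moment of a sweeping
context. A δ-long teaching flush continues into the reset window so the
final part of each reach (where the distance error is measured) is
credited too.

### Encoding and decoding

Inputs are population-coded with Gaussian tuning curves whose centres
are placed on the task manifold by deterministic k-means over the states
the task actually visits; widths follow the nearest-neighbour spacing.
The inverse correctors (agonist/antagonist pair per joint, built as
wiring twins so the net correction starts at exactly zero) share one
context: the full desired joint state (θ_s, θ_e, θ̇_s, θ̇_e). Their output
is the population mean DCN rate, mapped to torque as
τ̂ = ±g·rate/rate_max (g = 2.5 N·m) and smoothed by an 80 ms activation
filter. Their teaching signal is the sensorimotor transform
e = K_p(θ_d − θ_ref) + K_v(θ̇_d − θ̇_ref) with the delayed sensed state as
reference online and the forward prediction offline; positive errors
drive the agonist's CF above baseline and push the antagonist's below
it.

Each forward predictor encodes (own-joint final torque efference, full
desired state) and carries a *local code* over the future **deviation**
of its quantity from the plan (actual − desired, 50 ms ahead), rather
than the raw state: the deviation axis is narrow, so the same number of
cells resolves it much more finely, and an untrained predictor shows a
flat profile and stays silent. The emitted prediction is
desired + decoded deviation, i.e. the future angular state itself.
Forward nets use a denser sheet (60 PC, 24 DCN), higher granule-layer
gain, a 25 ms trace and a 25 Hz CF teaching ceiling; PC preferred values
connect to DCN cells through a narrow Gaussian kernel (every PC contacts
every DCN, so the anatomical convergence stays at the full PC count).
Decoding is a population vector over the mean-subtracted, spatially
smoothed DCN profile.

Predictions are released through two gates. A *confidence* gate opens
when the profile is peaked, (peak − min)/(mean − min) ≥ 2 — the model's
operationalization of the forward model's bistability (active output
only with structured predictions). An *accuracy* gate additionally
requires the running (deviation-weighted EMA) prediction error to stay
below a fraction of the running deviation magnitude before predictions
may steer replanning online; inaccurate predictions would make
trajectory planning catastrophic. Offline teaching is gated by
confidence only, since the accuracy monitor is a sensory-comparison
quantity that does not exist without feedback.

## Task and protocol

Eight targets sit on a circle of radius 36 mm / (2 sin 7.5°) ≈ 138 mm
around the start position S = (0, 0.42) m (the radius makes the 15°
chord exactly the 36 mm distance normalization). An anticlockwise bias
rotates the generator's desired Cartesian trajectory about S before
inverse kinematics; everything else keeps the unrotated plan. Training
runs 4 steps × 3 trials with bias 15/30/45/60°, one trial = 90
one-second trajectories toward uniformly random targets; probe trials 13
and 14 run at 60°, with an optional offline consolidation period (48
trials = 4320 replayed trajectories at full scale) in between. Probe
trials keep plasticity enabled. Replay has no plant and no sensing: the
stored desired plans are sampled uniformly with replacement, forward
predictors run on the efference of the commands the correctors would
issue, and the correctors adapt from desired-minus-predicted errors
whenever the forward gates are open.

Directional error is the unsigned angle between the straight line to
the target and the movement heading at peak outward hand speed; distance
error is the endpoint miss. Both are normalized bias-relatively (raw
angle over the current bias; raw distance over the current bias' chord),
so an unadapted subject scores ≈ 1 at every step; a fixed-at-15°
normalization is a config switch. Group statistics use a one-way
fixed-effects ANOVA (df = (k−1, N−k)).

## Problem sizes used by the test suite

The package's desk-scale configuration runs 20 MFs per microcomplex
(2000 GCs), 24–30 trajectories per trial and three subjects per group,
with the full bias schedule; the consolidation comparison reuses each
trained subject from a state snapshot at probe 13 (a paired design) with
replay periods of 2, 6 and 12 trials. The full-scale protocol objects
(|MF| = 100, 90 trajectories per trial, ten subjects, independent sweep
groups over 1–48 trials) are the defaults of `ProtocolConfig` and
`run_consolidation_sweep`.

## What the synthetic generators emulate — and what they do not

`synthetic.make_rotated_reach` produces a minimum-jerk reach rotated by
a known bias, carrying its exact metric ground truths; it emulates the
geometry of an unadapted movement, not the dynamics of one (no torque
noise, no curvature from corrections). `make_poisson_raster` produces
independent Poisson spike trains for decoder tests. Passing tests on
these fixtures validates the measurement and decoding pipelines; it says
nothing about human kinematic variability, muscle dynamics or visual
feedback, none of which are modelled.

## Numerical choices and degenerate inputs

Quintic replanning keeps the current plan when fewer than one replan
period remains. The inverse kinematics always takes the elbow-positive
branch and raises on unreachable points; trajectories that would leave
the annulus abort the replan, not the reach. A purely tangential or
motionless path raises rather than yielding a spurious heading (the
outward-speed floor is 0.3% of peak hand speed, above
finite-differencing residue). Degenerate ANOVA input (zero total
variance) returns F = 0. All randomness flows from explicitly passed
generators seeded per subject via `SeedSequence` spawning; identical
seeds give bit-identical trajectories.

## Known limitations

Prediction accuracy at desk scale is the binding constraint: measured
under deterministic conditions, decoded deviations carry ~60% relative
error. The accuracy gate therefore rarely releases predictions while the
correctors are active, so at this network scale the coupled scheme does
not measurably improve on the inverse-only scheme, and the offline
consolidation effect is small and can go either way per subject —
dominated by the probe-to-probe sampling noise that both the wake and
replay arms share. Both behaviours are consequences of local-code
readout precision at the reduced cell counts, not of the protocol. The model
omits cerebellar interneurons, MF→DCN plasticity, conductance-based
neurons and within-microcomplex axonal delays, and does not address how
sensory errors become motor errors (the transform is assumed known).
The online/offline teaching switch is an explicit mode flag.
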