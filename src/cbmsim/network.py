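"""Spiking cerebellar microcomplex: populations, wiring, plasticity.

One microcomplex is the cerebellar computational unit used throughout:
mossy fibres (MF) carry the contextual input, granule cells (GC) provide
a ~100x sparse expansion recoding of it (parallel fibres, PF, are the GC
axons), Purkinje cells (PC) read the PF code through the only plastic
synapses in the circuit, and the deep cerebellar nuclei (DCN) — excited
all-to-all by MFs and inhibited by PCs — form the output. Inferior-olive
(IO) neurons deliver the climbing-fibre (CF) teaching signal, one CF per
PC.

Plasticity at PF–PC synapses combines:

* non-associative LTP — every PF spike potentiates its synapses by a
  fixed increment ``alpha_ltp``;
* CF-supervised heterosynaptic LTD — a CF spike to PC j depresses all of
  j's PF synapses in proportion to their exponential eligibility traces.

The CF baseline rate is calibrated so LTP and baseline LTD compensate
exactly in expectation (``alpha_ltp = alpha_ltd * r_baseline * tau_trace``).
The baseline component is applied as its deterministic rate expectation
each step, which makes the compensation exact per PF spike; only the
supra-baseline (error-driven) CF activity is delivered as discrete spikes.
Without a teaching signal the stored input–output mapping therefore
persists unchanged — the homeostatic property that offline consolidation
relies on.

Two execution paths exist: the explicit single-net path here (readable,
used by unit tests), and :class:`MicrocomplexBank`, a batched
vectorization of several identically-shaped nets used by the closed
loop. The two are equivalent given identical spike inputs (tested).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

#: global simulation step (s)
DT = 1e-3


# ---------------------------------------------------------------------------
# configuration

@dataclass
class LIFConfig:
    """Leaky integrate-and-fire constants (dimensionless voltage)."""

    tau_m_ms: float = 10.0
    v_rest: float = 0.0
    v_reset: float = 0.0
    v_th: float = 1.0
    t_ref_ms: float = 2.0

    def decay(self, dt: float = DT) -> float:
        return math.exp(-dt * 1000.0 / self.tau_m_ms)

    def ref_steps(self, dt: float = DT) -> int:
        return int(round(self.t_ref_ms / (dt * 1000.0)))


@dataclass
class MicrocomplexConfig:
    """Sizes, wiring constants and plasticity rates of one microcomplex.

    The GC population is always 100x the MF population. The MF->GC
    connection probability defaults to ``gc_in_degree / n_mf`` so that
    each GC receives 4 MF afferents on average; at the reference size
    n_mf=100 this is the anatomical value 0.04 (each MF then innervates
    400 GCs on average).
    """

    n_mf: int = 100
    gc_ratio: int = 100
    n_pc: int = 30
    n_dcn: int = 6
    gc_in_degree: float = 4.0
    p_mfgc: float | None = None          # None -> gc_in_degree / n_mf
    min_convergence: int = 20            # required PC->DCN convergence

    # fixed synaptic efficacies (calibrated so that mid-range PF-PC
    # weights put the DCN near the middle of its firing range)
    w_mfgc: float = 0.3
    w_mfdcn: float = 0.25
    g_inh_dcn: float = 0.8               # total PC->DCN inhibition weight

    # PC->DCN weight profile: "uniform" (rate-decoded inverse units) or
    # "kernel" (value-aligned Gaussian profile for the local code of
    # forward units); every PC contacts every DCN in both cases.
    pc_dcn_profile: str = "uniform"
    kernel_sigma: float = 0.10           # in units of the preferred-value range

    # neuron constants
    lif_gc: LIFConfig = field(default_factory=lambda: LIFConfig(10.0, 0.0, 0.0, 1.0, 2.0))
    lif_pc: LIFConfig = field(default_factory=lambda: LIFConfig(10.0, 0.0, 0.0, 1.0, 2.0))
    lif_dcn: LIFConfig = field(default_factory=lambda: LIFConfig(20.0, 0.0, 0.0, 1.0, 1.0))
    #: slow synaptic filtering of the DCN input (slow MF->DCN conductances);
    #: regularizes DCN firing so the decoded output is a low-noise rate code
    tau_dcn_syn_ms: float = 15.0

    # PF-PC plasticity
    w_min: float = 0.0
    w_max: float = 0.04
    w_init_frac: float = 0.5             # initial weights, fraction of the range
    alpha_ltd: float = 0.001             # depression per CF spike x unit trace
    cf_baseline_hz: float = 1.0
    cf_max_hz: float = 10.0
    trace_tau_ms: float = 50.0
    #: MF spike generation: "regular" (clock-like phase accumulators,
    #: subject-specific phases; near-noiseless rate code) or "poisson"
    mf_mode: str = "regular"
    #: PF spikes enter the plasticity machinery (eligibility + LTP) this
    #: long after emission, centring CF credit on the PF activity that
    #: caused the error: the command-to-sensed-consequence latency is
    #: 2 delta = 100 ms, and the lag plus half a trace lifetime matches it
    plasticity_lag_ms: float = 75.0

    @property
    def n_gc(self) -> int:
        return self.gc_ratio * self.n_mf

    @property
    def n_io(self) -> int:
        return self.n_pc

    @property
    def connection_probability(self) -> float:
        p = self.p_mfgc if self.p_mfgc is not None else self.gc_in_degree / self.n_mf
        if not (0.0 < p <= 1.0):
            raise ValueError(f"MF->GC connection probability {p} outside (0, 1]")
        return p

    @property
    def alpha_ltp(self) -> float:
        """LTP increment that exactly balances baseline-rate LTD."""
        return self.alpha_ltd * self.cf_baseline_hz * self.trace_tau_ms / 1000.0

    @property
    def w_init(self) -> float:
        return self.w_min + self.w_init_frac * (self.w_max - self.w_min)

    def lag_steps(self, dt: float = DT) -> int:
        return int(round(self.plasticity_lag_ms / (dt * 1000.0)))


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# populations and synapse groups

class NeuronPop:
    """A population of current-based LIF neurons stepped at the global dt."""

    def __init__(self, size: int, cfg: LIFConfig, dt: float = DT):
        if size < 1:
            raise ConfigurationError("population size must be >= 1")
        self.size = size
        self.cfg = cfg
        self.dt = dt
        self._decay = cfg.decay(dt)
        self._ref_steps = cfg.ref_steps(dt)
        self.v = np.full(size, cfg.v_rest)
        self.refrac = np.zeros(size, dtype=np.int64)
        self.spikes = np.zeros(size, dtype=bool)

    def step(self, input_charge: np.ndarray) -> np.ndarray:
        """One LIF update; ``input_charge`` is the summed synaptic charge
        delivered this step (dimensionless voltage increments)."""
        input_charge = np.asarray(input_charge, float)
        if input_charge.shape != (self.size,):
            raise ValueError(f"drive length {input_charge.shape} != population size {self.size}")
        c = self.cfg
        self.v = c.v_rest + (self.v - c.v_rest) * self._decay
        active = self.refrac <= 0
        self.v = np.where(active, self.v + input_charge, c.v_reset)
        spk = active & (self.v >= c.v_th)
        self.v[spk] = c.v_reset
        np.maximum(self.refrac - 1, 0, out=self.refrac)
        self.refrac[spk] = self._ref_steps
        self.spikes = spk
        return spk

    def reset(self) -> None:
        self.v[:] = self.cfg.v_rest
        self.refrac[:] = 0
        self.spikes[:] = False


@dataclass
class SynapseGroup:
    """A set of synapses between two populations."""

    source: str
    target: str
    weights: np.ndarray               # dense (n_source, n_target) efficacy >= 0
    mask: np.ndarray | None = None    # bool connectivity; None = all-to-all
    plastic: bool = False
    w_min: float = 0.0
    w_max: float = np.inf
    sign: int = 1                     # +1 excitatory, -1 inhibitory

    def __post_init__(self) -> None:
        if np.any(self.weights < 0):
            raise ConfigurationError("synaptic efficacies must be >= 0")

    @property
    def pairs(self) -> np.ndarray:
        """Connectivity list as (source, target) index pairs."""
        m = self.mask if self.mask is not None else np.ones(self.weights.shape, bool)
        return np.argwhere(m)


# ---------------------------------------------------------------------------
# plasticity primitives (spec surface; operate in place on a weight matrix)

def ltp_update(weights: np.ndarray, pf_spikes: np.ndarray, alpha_ltp: float,
               w_max: float) -> np.ndarray:
    """Non-associative LTP: every PF spike potentiates that PF's synapses
    onto all PCs by ``alpha_ltp``, saturating at ``w_max``. Independent of
    CF activity."""
    idx = np.nonzero(np.asarray(pf_spikes, bool))[0]
    if idx.size:
        weights[idx] = np.minimum(weights[idx] + alpha_ltp, w_max)
    return weights

def ltd_update(weights: np.ndarray, cf_spikes: np.ndarray, pf_traces: np.ndarray,
               alpha_ltd: float, w_min: float) -> np.ndarray:
    """CF-supervised heterosynaptic LTD: a CF spike to PC j depresses all
    of j's PF synapses in proportion to their eligibility traces, with a
    floor at ``w_min``."""
    jdx = np.nonzero(np.asarray(cf_spikes, bool))[0]
    if jdx.size:
        weights[:, jdx] = np.maximum(
            weights[:, jdx] - alpha_ltd * pf_traces[:, None], w_min)
    return weights


def baseline_ltd_update(weights: np.ndarray, pf_traces: np.ndarray,
                        alpha_ltp: float, trace_decay: float,
                        w_min: float) -> np.ndarray:
    """Deterministic rate expectation of baseline CF firing.

    Applied to every PC each step *before* the trace update, with the
    exact discrete decrement ``alpha_ltp * (1 - trace_decay) * trace``:
    summed over a trace lifetime this cancels one LTP increment exactly,
    so under baseline CF drive the weights perform a closed excursion per
    PF spike and return to their stored values.
    """
    dec = alpha_ltp * (1.0 - trace_decay)
    if dec > 0:
        weights -= dec * pf_traces[:, None]
        np.maximum(weights, w_min, out=weights)
    return weights


# ---------------------------------------------------------------------------
# the microcomplex

@dataclass
class SpikeRecord:
    """Spike flags of every population for one step (or stacked steps)."""

    mf: np.ndarray
    gc: np.ndarray
    pc: np.ndarray
    dcn: np.ndarray
    io: np.ndarray
    dt: float = DT


class MicrocomplexNet:
    """One cerebellar microcomplex (explicit reference implementation)."""

    def __init__(self, cfg: MicrocomplexConfig, seed: int,
                 preferred_values: np.ndarray | None = None, dt: float = DT):
        self.cfg = cfg
        self.seed = seed
        self.dt = dt
        self.rng = np.random.default_rng(seed)
        c = cfg

        if c.n_gc != c.gc_ratio * c.n_mf:
            raise ConfigurationError("GC population must be gc_ratio x MF population")

        self.pops = {
            "GC": NeuronPop(c.n_gc, c.lif_gc, dt),
            "PC": NeuronPop(c.n_pc, c.lif_pc, dt),
            "DCN": NeuronPop(c.n_dcn, c.lif_dcn, dt),
        }

        # MF -> GC: sparse Bernoulli wiring
        p = c.connection_probability
        mask = self.rng.random((c.n_gc, c.n_mf)) < p
        self.mf_gc = SynapseGroup("MF", "GC", mask.astype(float) * c.w_mfgc, mask)

        # PF -> PC: dense, plastic, initialized so DCN output starts
        # mid-range (the DCN response to the PF-PC weight is nonlinear,
        # so the mid-output weight is below the arithmetic mid-point)
        w0 = np.full((c.n_gc, c.n_pc), c.w_init)
        self.pf_pc = SynapseGroup("GC", "PC", w0, None, plastic=True,
                                  w_min=c.w_min, w_max=c.w_max)

        # MF -> DCN: all-to-all constant excitation
        self.mf_dcn = SynapseGroup("MF", "DCN",
                                   np.full((c.n_mf, c.n_dcn), c.w_mfdcn))

        # PC -> DCN: fixed inhibition; uniform, or value-aligned Gaussian
        # kernel when the net carries a local output code
        if c.pc_dcn_profile == "kernel":
            if preferred_values is None:
                raise ConfigurationError("kernel profile requires preferred values")
            v_pc = np.linspace(0.0, 1.0, c.n_pc)
            v_dcn = np.linspace(0.0, 1.0, c.n_dcn)
            K = np.exp(-0.5 * ((v_pc[:, None] - v_dcn[None, :]) / c.kernel_sigma) ** 2)
            K = K / K.sum(axis=0, keepdims=True) * c.n_pc
            w_pcdcn = c.g_inh_dcn / c.n_pc * K
        else:
            w_pcdcn = np.full((c.n_pc, c.n_dcn), c.g_inh_dcn / c.n_pc)
        self.pc_dcn = SynapseGroup("PC", "DCN", w_pcdcn, sign=-1)

        conv = int(np.min((self.pc_dcn.weights > 0).sum(axis=0)))
        if conv < c.min_convergence:
            raise ConfigurationError(
                f"PC->DCN convergence {conv} below required minimum {c.min_convergence}")
        self.convergence = conv

        #: preferred values on the decoded axis (forward/local-code nets)
        self.preferred_values = preferred_values

        # CF -> PC: one teaching fibre per PC (identity routing)
        self.trace = np.zeros(c.n_gc)
        self._trace_decay = math.exp(-dt * 1000.0 / c.trace_tau_ms)
        self.plastic = True
        self._lag = c.lag_steps(dt)
        self._spike_ring: list[np.ndarray] = [np.zeros(c.n_gc, bool)
                                              for _ in range(self._lag)]
        #: per-fibre spike-clock phases (subject-specific, fixed at build)
        self._mf_phase0 = self.rng.random(c.n_mf)
        self._mf_acc = self._mf_phase0.copy()
        self._dcn_syn = np.zeros(c.n_dcn)
        self._dec_syn = math.exp(-dt * 1000.0 / c.tau_dcn_syn_ms)

    # -- dynamics -----------------------------------------------------------

    def step_network(self, mf_drive: np.ndarray | None = None,
                     cf_drive: np.ndarray | None = None,
                     mf_spikes: np.ndarray | None = None,
                     cf_spikes: np.ndarray | None = None) -> SpikeRecord:
        """One update of all populations in topological order.

        ``mf_drive`` is the per-MF instantaneous rate (Hz), ``cf_drive``
        the per-IO teaching rate (Hz, including the baseline; only the
        supra-baseline excess is emitted as spikes). Pre-drawn spike
        vectors may be supplied instead, which makes the step fully
        deterministic.
        """
        c = self.cfg
        if mf_spikes is None:
            if mf_drive is None:
                mf_drive = np.zeros(c.n_mf)
            mf_drive = np.asarray(mf_drive, float)
            if mf_drive.shape != (c.n_mf,):
                raise ValueError(f"MF drive length {mf_drive.shape} != {c.n_mf}")
            if c.mf_mode == "regular":
                self._mf_acc += mf_drive * self.dt
                mf_spikes = self._mf_acc >= 1.0
                self._mf_acc[mf_spikes] -= 1.0
            else:
                mf_spikes = self.rng.random(c.n_mf) < mf_drive * self.dt
        mf_spikes = np.asarray(mf_spikes, bool)
        mf_f = mf_spikes.astype(float)

        gc_in = self.mf_gc.weights @ mf_f
        gc_spk = self.pops["GC"].step(gc_in)

        gc_f = gc_spk.astype(float)
        pc_in = self.pf_pc.weights.T @ gc_f
        pc_spk = self.pops["PC"].step(pc_in)

        dcn_raw = self.mf_dcn.weights.T @ mf_f - self.pc_dcn.weights.T @ pc_spk.astype(float)
        self._dcn_syn += (1.0 - self._dec_syn) * (dcn_raw - self._dcn_syn)
        dcn_spk = self.pops["DCN"].step(self._dcn_syn)

        rec_events = np.zeros(c.n_io, bool)
        if cf_spikes is None:
            if cf_drive is not None:
                cf_drive = np.asarray(cf_drive, float)
                if cf_drive.shape != (c.n_io,):
                    raise ValueError(f"CF drive length {cf_drive.shape} != {c.n_io}")
                excess = np.maximum(cf_drive - c.cf_baseline_hz, 0.0)
                deficit = np.maximum(c.cf_baseline_hz - cf_drive, 0.0)
                u = self.rng.random(c.n_io)
                cf_spikes = u < excess * self.dt
                rec_events = (~cf_spikes) & (u < deficit * self.dt)
            else:
                cf_spikes = np.zeros(c.n_io, bool)
        cf_spikes = np.asarray(cf_spikes, bool)

        # PF spikes enter the plasticity machinery after the credit lag
        if self._lag > 0:
            self._spike_ring.append(gc_spk.copy())
            plast_spk = self._spike_ring.pop(0)
        else:
            plast_spk = gc_spk

        if self.plastic:
            baseline_ltd_update(self.pf_pc.weights, self.trace, c.alpha_ltp,
                                self._trace_decay, c.w_min)

        # eligibility: decay, then accumulate the lagged PF spikes
        self.trace *= self._trace_decay
        self.trace[plast_spk] += 1.0

        if self.plastic:
            w = self.pf_pc.weights
            ltp_update(w, plast_spk, c.alpha_ltp, c.w_max)
            ltd_update(w, cf_spikes, self.trace, c.alpha_ltd, c.w_min)
            # olivary suppression below baseline tips the LTP/LTD balance
            # toward net potentiation of the recently active synapses
            jdx = np.nonzero(rec_events)[0]
            if jdx.size:
                w[:, jdx] = np.minimum(
                    w[:, jdx] + c.alpha_ltd * self.trace[:, None], c.w_max)

        return SpikeRecord(mf_spikes, gc_spk, pc_spk, dcn_spk, cf_spikes, self.dt)

    def reset_to_baseline(self) -> "MicrocomplexNet":
        """Membrane potentials to rest, eligibility traces to zero;
        synaptic weights (the stored memory) untouched. Idempotent.

        The transient potentiation still riding on live eligibility
        traces (exactly ``alpha_ltp * trace`` per synapse row) decays
        away with the traces, so the weights collapse back onto the
        stored mapping — keeping the LTP/LTD balance exact across
        resets.
        """
        for pop in self.pops.values():
            pop.reset()
        if self.plastic and self.trace.any():
            self.pf_pc.weights -= self.cfg.alpha_ltp * self.trace[:, None]
            np.maximum(self.pf_pc.weights, self.cfg.w_min,
                       out=self.pf_pc.weights)
        self.trace[:] = 0.0
        self._spike_ring = [np.zeros(self.cfg.n_gc, bool)
                            for _ in range(self._lag)]
        self._mf_acc = self._mf_phase0.copy()
        self._dcn_syn[:] = 0.0
        return self

    # -- introspection ------------------------------------------------------

    @property
    def weights(self) -> np.ndarray:
        return self.pf_pc.weights

    def wiring_density(self) -> float:
        return float(self.mf_gc.mask.mean())


def dump_spike_record(records, path, dt: float = DT) -> int:
    """Write stacked spike records as columnar text: time_ms, population,
    neuron_id — one row per spike. Returns the number of rows written."""
    import pathlib
    lines = ["time_ms\tpopulation\tneuron_id"]
    for step, rec in enumerate(records):
        t_ms = step * dt * 1000.0
        for name in ("mf", "gc", "pc", "dcn", "io"):
            for idx in np.nonzero(getattr(rec, name))[0]:
                lines.append(f"{t_ms:.1f}\t{name.upper()}\t{idx}")
    pathlib.Path(path).write_text("\n".join(lines) + "\n")
    return len(lines) - 1


def build_microcomplex(cfg: MicrocomplexConfig, seed: int,
                       preferred_values: np.ndarray | None = None,
                       dt: float = DT) -> MicrocomplexNet:
    """Build a microcomplex whose wiring satisfies all structural
    invariants; identical seeds give byte-identical wiring and weights."""
    return MicrocomplexNet(cfg, seed, preferred_values, dt)


# ---------------------------------------------------------------------------
# batched execution path

class MicrocomplexBank:
    """B identically-configured microcomplexes stepped as stacked arrays.

    The closed loop runs four forward predictors and four inverse
    correctors; batching them removes almost all per-step Python
    overhead. Plasticity uses an exact reformulation of the balanced
    LTP/baseline-LTD pair: the net row potentiation at any instant equals
    ``alpha_ltp * trace``, so the stored matrix ``u`` only changes on
    error-driven CF events and the effective weight is
    ``u + alpha_ltp * trace`` (equal to the explicit path's weights).
    """

    def __init__(self, nets: list[MicrocomplexNet], seed: int):
        if not nets:
            raise ConfigurationError("bank needs at least one net")
        cfg = nets[0].cfg
        for net in nets:
            if (net.cfg.n_mf, net.cfg.n_gc, net.cfg.n_pc, net.cfg.n_dcn) != \
               (cfg.n_mf, cfg.n_gc, cfg.n_pc, cfg.n_dcn):
                raise ConfigurationError("bank nets must share their shape")
        self.cfg = cfg
        self.B = len(nets)
        self.dt = nets[0].dt
        self.rng = np.random.default_rng(seed)

        self.W_mfgc = np.stack([n.mf_gc.weights for n in nets])         # (B, gc, mf)
        self.u = np.stack([n.pf_pc.weights for n in nets])              # (B, gc, pc)
        self.pc_dcn = np.stack([n.pc_dcn.weights for n in nets])        # (B, pc, dcn)
        self.w_mfdcn = cfg.w_mfdcn

        c = cfg
        self.v_gc = np.zeros((self.B, c.n_gc))
        self.v_pc = np.zeros((self.B, c.n_pc))
        self.v_dcn = np.zeros((self.B, c.n_dcn))
        self.ref_gc = np.zeros((self.B, c.n_gc), np.int64)
        self.ref_pc = np.zeros((self.B, c.n_pc), np.int64)
        self.ref_dcn = np.zeros((self.B, c.n_dcn), np.int64)
        self.trace = np.zeros((self.B, c.n_gc))
        self.dcn_rate = np.zeros((self.B, c.n_dcn))     # exp-filtered rate (Hz)

        self._dec_gc = c.lif_gc.decay(self.dt)
        self._dec_pc = c.lif_pc.decay(self.dt)
        self._dec_dcn = c.lif_dcn.decay(self.dt)
        self._ref_gc = c.lif_gc.ref_steps(self.dt)
        self._ref_pc = c.lif_pc.ref_steps(self.dt)
        self._ref_dcn = c.lif_dcn.ref_steps(self.dt)
        self._trace_decay = math.exp(-self.dt * 1000.0 / c.trace_tau_ms)
        self.rate_tau_s = 0.020
        self._rate_decay = math.exp(-self.dt / self.rate_tau_s)
        self._last_gc = np.zeros((self.B, c.n_gc), bool)
        self._last_pc = np.zeros((self.B, c.n_pc), bool)

        # outgoing MF->GC adjacency (per net and MF) for the compiled kernel
        masks = self.W_mfgc > 0                       # (B, gc, mf)
        out_counts = masks.sum(axis=1).reshape(-1)    # per (b, mf)
        self._mf_indptr = np.zeros(self.B * c.n_mf + 1, np.int64)
        np.cumsum(out_counts, out=self._mf_indptr[1:])
        tgt = masks.transpose(0, 2, 1).reshape(self.B * c.n_mf, c.n_gc)
        self._mf_indices = np.nonzero(tgt)[1]
        self._mf_spk = np.zeros((self.B, c.n_mf), bool)
        self._pc_spk = np.zeros((self.B, c.n_pc), bool)
        self._dcn_spk = np.zeros((self.B, c.n_dcn), bool)
        # lazy granule-layer state used only by the kernel path
        self._step_idx = 0
        self._gc_last = np.zeros((self.B, c.n_gc), np.int64)
        self._gc_ref_until = np.zeros((self.B, c.n_gc), np.int64)
        self._trace_last = np.zeros((self.B, c.n_gc), np.int64)
        self._cnt_scratch = np.zeros((self.B, c.n_gc), np.int64)
        self._touched_scratch = np.zeros(c.n_gc, np.int64)
        self._spk_scratch = np.zeros(c.n_gc, np.int64)
        self._mf_phase0 = np.stack([n._mf_phase0 for n in nets])
        self._mf_acc = self._mf_phase0.copy()
        self.dcn_syn = np.zeros((self.B, c.n_dcn))
        self._dec_syn = math.exp(-self.dt * 1000.0 / c.tau_dcn_syn_ms)
        # plasticity spike ring (credit lag)
        self._lag = c.lag_steps(self.dt)
        cap = max(self._lag, 1)
        self._hist_idx = np.zeros((cap, self.B, c.n_gc), np.int64)
        self._hist_cnt = np.zeros((cap, self.B), np.int64)
        self._ring_np: list[np.ndarray] = [np.zeros((self.B, c.n_gc), bool)
                                           for _ in range(self._lag)]
        from ._kernels import HAVE_NUMBA, bank_step
        self._kernel = bank_step if HAVE_NUMBA else None

    # -- stepping ----------------------------------------------------------

    def _lif(self, v, ref, decay, inp, ref_steps, th):
        v *= decay
        active = ref <= 0
        np.add(v, inp, out=v, where=active)
        v[~active] = 0.0
        spk = active & (v >= th)
        v[spk] = 0.0
        np.maximum(ref - 1, 0, out=ref)
        ref[spk] = ref_steps
        return spk

    def step(self, mf_rates: np.ndarray, cf_rates: np.ndarray | None = None,
             plastic: bool = True,
             mf_spikes: np.ndarray | None = None,
             cf_spikes: np.ndarray | None = None) -> np.ndarray:
        """One step of all B nets; returns the DCN spike matrix (B, n_dcn).

        Dispatches to the compiled kernel when available and when no
        pre-drawn spikes are supplied; the numpy path below is the
        reference (both consume the generator identically).
        """
        c = self.cfg
        if mf_spikes is None:
            if c.mf_mode == "regular":
                self._mf_acc += np.asarray(mf_rates, float) * self.dt
                mf_spikes = self._mf_acc >= 1.0
                self._mf_acc[mf_spikes] -= 1.0
            else:
                mf_spikes = self.rng.random((self.B, c.n_mf)) < \
                    np.asarray(mf_rates, float) * self.dt
        mf_spikes = np.ascontiguousarray(mf_spikes, dtype=bool)

        if self._kernel is not None and cf_spikes is None:
            apply_cf = plastic and cf_rates is not None
            if apply_cf:
                rates = np.asarray(cf_rates, float)
                cf_excess = np.maximum(rates - c.cf_baseline_hz, 0.0)
                cf_deficit = np.maximum(c.cf_baseline_hz - rates, 0.0)
                cf_u = self.rng.random((self.B, c.n_io))
            else:
                cf_excess = np.zeros((self.B, c.n_io))
                cf_deficit = np.zeros((self.B, c.n_io))
                cf_u = np.ones((self.B, c.n_io))
            self._kernel(
                self._step_idx, mf_spikes, self.dt,
                self._mf_indptr, self._mf_indices, c.w_mfgc,
                self.v_gc, self._gc_last, self._gc_ref_until,
                self._dec_gc, self._ref_gc,
                self.v_pc, self.ref_pc, self._dec_pc, self._ref_pc,
                self.v_dcn, self.ref_dcn, self._dec_dcn, self._ref_dcn,
                self.dcn_syn, self._dec_syn,
                self.u, self.trace, self._trace_last, c.alpha_ltp,
                self._trace_decay,
                self.pc_dcn, self.w_mfdcn,
                self.dcn_rate, self._rate_decay,
                (1.0 - self._rate_decay) / self.dt,
                cf_u, cf_excess, cf_deficit, c.alpha_ltd, c.w_min, c.w_max,
                apply_cf, self._lag, self._hist_idx, self._hist_cnt,
                self._cnt_scratch, self._touched_scratch, self._spk_scratch,
                self._pc_spk, self._dcn_spk)
            self._step_idx += 1
            self._last_pc = self._pc_spk
            return self._dcn_spk

        mf_f = mf_spikes.astype(float)

        gc_in = np.einsum("bgm,bm->bg", self.W_mfgc, mf_f)
        gc_spk = self._lif(self.v_gc, self.ref_gc, self._dec_gc, gc_in,
                           self._ref_gc, c.lif_gc.v_th)

        alpha_ltp = c.alpha_ltp
        pc_in = np.empty((self.B, c.n_pc))
        spk_idx = []
        for b in range(self.B):
            idx = np.nonzero(gc_spk[b])[0]
            spk_idx.append(idx)
            if idx.size:
                pc_in[b] = self.u[b, idx].sum(axis=0) + alpha_ltp * self.trace[b, idx].sum()
            else:
                pc_in[b] = 0.0
        pc_spk = self._lif(self.v_pc, self.ref_pc, self._dec_pc, pc_in,
                           self._ref_pc, c.lif_pc.v_th)
        self._last_gc = gc_spk
        self._last_pc = pc_spk

        dcn_raw = (self.w_mfdcn * mf_f.sum(axis=1)[:, None]
                   - np.einsum("bp,bpd->bd", pc_spk.astype(float), self.pc_dcn))
        self.dcn_syn += (1.0 - self._dec_syn) * (dcn_raw - self.dcn_syn)
        dcn_spk = self._lif(self.v_dcn, self.ref_dcn, self._dec_dcn,
                            self.dcn_syn.copy(), self._ref_dcn, c.lif_dcn.v_th)

        self.dcn_rate *= self._rate_decay
        self.dcn_rate += dcn_spk * ((1.0 - self._rate_decay) / self.dt)

        # eligibility (PF spikes enter after the credit lag)
        if self._lag > 0:
            self._ring_np.append(gc_spk.copy())
            plast_spk = self._ring_np.pop(0)
        else:
            plast_spk = gc_spk
        self.trace *= self._trace_decay
        self.trace[plast_spk] += 1.0

        # error-driven LTD and suppression-driven recovery (baseline + LTP
        # are folded into the trace term)
        if plastic:
            rec = None
            if cf_spikes is None and cf_rates is not None:
                rates = np.asarray(cf_rates, float)
                excess = np.maximum(rates - c.cf_baseline_hz, 0.0)
                deficit = np.maximum(c.cf_baseline_hz - rates, 0.0)
                uu = self.rng.random((self.B, c.n_io))
                cf_spikes = uu < excess * self.dt
                rec = (~cf_spikes) & (uu < deficit * self.dt)
            if cf_spikes is not None and np.any(cf_spikes):
                for b in range(self.B):
                    jdx = np.nonzero(cf_spikes[b])[0]
                    if jdx.size:
                        self.u[b][:, jdx] = np.clip(
                            self.u[b][:, jdx] - c.alpha_ltd * self.trace[b][:, None],
                            c.w_min, c.w_max)
            if rec is not None and np.any(rec):
                for b in range(self.B):
                    jdx = np.nonzero(rec[b])[0]
                    if jdx.size:
                        self.u[b][:, jdx] = np.clip(
                            self.u[b][:, jdx] + c.alpha_ltd * self.trace[b][:, None],
                            c.w_min, c.w_max)
        return dcn_spk

    @property
    def pc_spikes(self) -> np.ndarray:
        """PC spike flags of the last step (diagnostics)."""
        return self._last_pc

    @property
    def gc_spikes(self) -> np.ndarray:
        """GC spike flags of the last step (diagnostics)."""
        return self._last_gc

    def reset_to_baseline(self) -> None:
        self.v_gc[:] = 0.0
        self.v_pc[:] = 0.0
        self.v_dcn[:] = 0.0
        self.ref_gc[:] = 0
        self.ref_pc[:] = 0
        self.ref_dcn[:] = 0
        self.trace[:] = 0.0
        self.dcn_rate[:] = 0.0
        self._step_idx = 0
        self._gc_last[:] = 0
        self._gc_ref_until[:] = 0
        self._trace_last[:] = 0
        self._hist_cnt[:] = 0
        self._ring_np = [np.zeros((self.B, self.cfg.n_gc), bool)
                         for _ in range(self._lag)]
        self._mf_acc = self._mf_phase0.copy()
        self.dcn_syn[:] = 0.0

    # -- memory ------------------------------------------------------------

    def weights(self) -> np.ndarray:
        """Effective PF-PC weights (exact when traces are quiescent)."""
        return np.clip(self.u + self.cfg.alpha_ltp * self.trace[:, :, None],
                       self.cfg.w_min, self.cfg.w_max)

    def checksum(self) -> float:
        return float(self.u.sum())

    def snapshot(self) -> dict:
        return {
            "u": self.u.copy(),
            "rng": copy.deepcopy(self.rng.bit_generator.state),
        }

    def restore(self, snap: dict) -> None:
        self.u[:] = snap["u"]
        self.rng.bit_generator.state = copy.deepcopy(snap["rng"])
        self.reset_to_baseline()


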