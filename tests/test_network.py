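"""Spiking-core tests: wiring statistics, LIF dynamics, plasticity rules,
LTP-LTD balance and the equivalence of the execution paths."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbmsim.models import encode_mf, make_encoder
from cbmsim.network import (LIFConfig, MicrocomplexBank, MicrocomplexConfig,
                            ConfigurationError, NeuronPop, build_microcomplex,
                            ltd_update, ltp_update)


# ---------------------------------------------------------------------------
# construction

class TestBuild:
    def test_reference_size_statistics(self):
        """At |MF|=100: |GC|=10000, density 0.04, in-degree 4, out-degree 400."""
        cfg = MicrocomplexConfig(n_mf=100)
        net = build_microcomplex(cfg, seed=7)
        assert cfg.n_gc == 100 * cfg.n_mf == 10000
        mask = net.mf_gc.mask
        n = mask.size
        p = 0.04
        assert cfg.connection_probability == pytest.approx(p)
        # exact binomial 99% CI for the empirical density over n draws
        half = 2.576 * math.sqrt(p * (1 - p) / n)
        assert abs(mask.mean() - p) < half
        in_deg = mask.sum(axis=1).mean()
        out_deg = mask.sum(axis=0).mean()
        assert in_deg == pytest.approx(4.0, abs=4 * math.sqrt(4 / 10000))
        assert out_deg == pytest.approx(400.0, rel=0.02)

    def test_same_seed_gives_identical_wiring_and_weights(self, small_net_config):
        a = build_microcomplex(small_net_config, seed=42)
        b = build_microcomplex(small_net_config, seed=42)
        assert np.array_equal(a.mf_gc.mask, b.mf_gc.mask)
        assert np.array_equal(a.pf_pc.weights, b.pf_pc.weights)
        assert np.array_equal(a._mf_phase0, b._mf_phase0)

    def test_convergence_constraint_enforced(self):
        cfg = MicrocomplexConfig(n_mf=10, n_pc=10, min_convergence=20)
        with pytest.raises(ConfigurationError):
            build_microcomplex(cfg, seed=1)

    def test_invalid_connection_probability_rejected(self):
        cfg = MicrocomplexConfig(n_mf=2)   # in-degree 4 of 2 fibres
        with pytest.raises(ValueError):
            build_microcomplex(cfg, seed=1)

    def test_only_pf_pc_group_is_plastic(self, small_net_config):
        net = build_microcomplex(small_net_config, seed=3)
        assert net.pf_pc.plastic
        assert not net.mf_gc.plastic
        assert not net.pc_dcn.plastic
        assert net.pc_dcn.sign == -1


# ---------------------------------------------------------------------------
# neuron dynamics

def _lif_rate_closed_form(cfg: LIFConfig, charge_per_step: float, dt=1e-3):
    """Independent oracle: steps to threshold of the discrete LIF map under
    a constant per-step input charge."""
    lam = math.exp(-dt * 1000.0 / cfg.tau_m_ms)
    v_inf = charge_per_step / (1.0 - lam)
    if v_inf <= cfg.v_th:
        return 0.0
    n = math.log((v_inf - cfg.v_th) / v_inf) / math.log(lam)
    n_steps = math.ceil(n)
    return 1.0 / ((n_steps + cfg.ref_steps(dt)) * dt)


class TestLIF:
    @pytest.mark.parametrize("charge", [0.12, 0.2, 0.5])
    def test_fi_curve_matches_closed_form(self, charge):
        cfg = LIFConfig(tau_m_ms=10.0, t_ref_ms=2.0)
        pop = NeuronPop(1, cfg)
        spikes = 0
        n = 4000
        for _ in range(n):
            spikes += int(pop.step(np.array([charge]))[0])
        rate = spikes / (n * 1e-3)
        assert rate == pytest.approx(_lif_rate_closed_form(cfg, charge), rel=0.05)

    def test_subthreshold_input_never_spikes(self):
        cfg = LIFConfig(tau_m_ms=10.0)
        pop = NeuronPop(5, cfg)
        for _ in range(2000):
            assert not pop.step(np.full(5, 0.05)).any()

    def test_zero_drive_from_rest_gives_no_spikes_anywhere(self, small_net_config):
        net = build_microcomplex(small_net_config, seed=5)
        for _ in range(300):
            rec = net.step_network(mf_drive=np.zeros(small_net_config.n_mf))
            assert not rec.gc.any() and not rec.pc.any() and not rec.dcn.any()

    def test_dcn_output_input_independent_without_pc_inhibition(self, small_net_config):
        """The defective circuit (no PC->DCN inhibition) cannot represent
        which MFs carry the input: permuting the input across fibres
        leaves its output unchanged, while the intact circuit (with
        heterogeneous PF-PC weights) responds differently."""
        enc = make_encoder(small_net_config.n_mf, [[-1, 1], [-1, 1]])
        drive = encode_mf((0.2, -0.3), enc)
        perm = np.random.default_rng(0).permutation(small_net_config.n_mf)

        def dcn_rate(weights_off, mf):
            net = build_microcomplex(small_net_config, seed=5)
            if weights_off:
                net.pc_dcn.weights[:] = 0.0
            else:
                r = np.random.default_rng(1)
                net.pf_pc.weights[:] = r.uniform(0, small_net_config.w_max,
                                                 net.pf_pc.weights.shape)
            net.plastic = False
            count = 0
            for _ in range(2000):
                count += net.step_network(mf_drive=mf).dcn.sum()
            return count / small_net_config.n_dcn / 2.0

        defective = (dcn_rate(True, drive), dcn_rate(True, drive[perm]))
        intact = (dcn_rate(False, drive), dcn_rate(False, drive[perm]))
        rel_def = abs(defective[0] - defective[1]) / np.mean(defective)
        rel_int = abs(intact[0] - intact[1]) / max(np.mean(intact), 1e-9)
        assert rel_def < 0.05
        assert rel_int > 2 * rel_def

    def test_population_sparseness(self, small_net_config):
        """The fraction of GCs spiking per step stays well below the
        fraction of MFs spiking per step (expansion recoding)."""
        enc = make_encoder(small_net_config.n_mf, [[-1, 1], [-1, 1]])
        net = build_microcomplex(small_net_config, seed=5)
        net.plastic = False
        drive = encode_mf((0.2, -0.1), enc)
        mf_frac = gc_frac = 0.0
        for _ in range(2000):
            rec = net.step_network(mf_drive=drive)
            mf_frac += rec.mf.mean()
            gc_frac += rec.gc.mean()
        assert gc_frac < 0.5 * mf_frac


# ---------------------------------------------------------------------------
# plasticity primitives

class TestPlasticityOps:
    def test_ltp_counts_spikes_exactly(self):
        w = np.full((5, 3), 0.01)
        spikes = np.array([True, False, True, False, False])
        for _ in range(4):
            ltp_update(w, spikes, alpha_ltp=1e-4, w_max=0.04)
        assert np.allclose(w[0], 0.01 + 4e-4)
        assert np.allclose(w[1], 0.01)

    def test_ltp_saturates_at_w_max(self):
        w = np.full((2, 2), 0.04)
        ltp_update(w, np.array([True, True]), alpha_ltp=1e-3, w_max=0.04)
        assert np.all(w == 0.04)

    def test_ltd_depresses_by_alpha_times_trace(self):
        w = np.full((3, 2), 0.02)
        traces = np.array([1.0, 0.5, 0.0])
        ltd_update(w, np.array([True, False]), traces, alpha_ltd=0.001, w_min=0.0)
        assert w[0, 0] == pytest.approx(0.019)
        assert w[1, 0] == pytest.approx(0.0195)
        assert w[2, 0] == pytest.approx(0.02)
        assert np.all(w[:, 1] == 0.02)   # no CF spike -> untouched

    def test_ltd_with_zero_traces_changes_nothing(self):
        w = np.full((4, 2), 0.02)
        ltd_update(w, np.array([True, True]), np.zeros(4), 0.001, 0.0)
        assert np.all(w == 0.02)

    def test_weights_never_cross_bounds(self, rng):
        w = rng.uniform(0, 0.04, (50, 4))
        for _ in range(300):
            ltp_update(w, rng.random(50) < 0.3, 2e-3, 0.04)
            ltd_update(w, rng.random(4) < 0.5, rng.uniform(0, 2, 50), 5e-3, 0.0)
            assert np.all(w >= 0.0) and np.all(w <= 0.04)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_bounds_hold_for_random_spike_streams(self, seed):
        r = np.random.default_rng(seed)
        w = r.uniform(0, 0.04, (30, 3))
        for _ in range(50):
            ltp_update(w, r.random(30) < 0.4, 3e-3, 0.04)
            ltd_update(w, r.random(3) < 0.6, r.uniform(0, 3, 30), 8e-3, 0.0)
        assert np.all(w >= 0.0) and np.all(w <= 0.04)


class TestBalance:
    def test_alpha_ltp_is_calibrated_to_baseline_ltd(self):
        cfg = MicrocomplexConfig()
        assert cfg.alpha_ltp == pytest.approx(
            cfg.alpha_ltd * cfg.cf_baseline_hz * cfg.trace_tau_ms / 1000.0)

    def test_no_teaching_weight_drift_below_criterion(self, small_net_config):
        """Stationary PF statistics, CF at baseline: mean weight drift over
        1e5 steps stays below 1e-4 of the weight ceiling."""
        net = build_microcomplex(small_net_config, seed=9)
        enc = make_encoder(small_net_config.n_mf, [[-1, 1], [-1, 1]])
        drive = encode_mf((0.15, -0.25), enc)
        baseline = np.full(small_net_config.n_io, small_net_config.cf_baseline_hz)
        w0 = net.pf_pc.weights.copy()
        for _ in range(100_000):
            net.step_network(mf_drive=drive, cf_drive=baseline)
        net.reset_to_baseline()   # let pending potentiation settle out
        drift = np.abs(net.pf_pc.weights.mean() - w0.mean())
        assert drift < 1e-4 * small_net_config.w_max

    def test_reset_preserves_stored_weights_and_silences_activity(self, small_net_config):
        """Resetting lets the transient trace-borne potentiation decay
        and returns the weights to the stored mapping; repeated resets
        are idempotent and activity goes quiet."""
        net = build_microcomplex(small_net_config, seed=2)
        enc = make_encoder(small_net_config.n_mf, [[-1, 1], [-1, 1]])
        drive = encode_mf((0.2, 0.2), enc)
        baseline = np.full(small_net_config.n_io, small_net_config.cf_baseline_hz)
        w_stored = net.pf_pc.weights.copy()   # no teaching has happened yet
        for _ in range(500):
            net.step_network(mf_drive=drive, cf_drive=baseline)
        net.reset_to_baseline()
        assert np.allclose(net.pf_pc.weights, w_stored, atol=1e-12)
        rec = net.step_network(mf_drive=np.zeros(small_net_config.n_mf))
        assert not rec.gc.any() and not rec.pc.any()
        net.reset_to_baseline()
        net.reset_to_baseline()   # idempotent
        assert np.allclose(net.pf_pc.weights, w_stored, atol=1e-12)


class TestConvergence:
    def test_decoded_output_stabilizes_with_convergence(self):
        """With baseline climbing-fibre activity delivered as discrete
        stochastic events, each PC's summed PF weight performs a random
        walk around the LTP/LTD balance point; a DCN averaging over C
        converging PCs sees fluctuations that shrink with C, and the
        stored association stays stable for C above ~20."""
        rng = np.random.default_rng(7)
        n_gc = 400
        alpha_ltd = 1e-3
        tau_tr = 50.0
        r_pf, r_cf = 30.0, 1.0
        alpha_ltp = alpha_ltd * r_cf * tau_tr / 1000.0
        lam = math.exp(-1.0 / tau_tr)
        stats = {}
        for conv in (5, 20, 40):
            w = np.full((n_gc, conv), 0.02)
            trace = np.zeros(n_gc)
            out = []
            for t in range(20000):
                pf = rng.random(n_gc) < r_pf * 1e-3
                trace = trace * lam
                trace[pf] += 1.0
                ltp_update(w, pf, alpha_ltp, 0.04)
                cf = rng.random(conv) < r_cf * 1e-3
                ltd_update(w, cf, trace, alpha_ltd, 0.0)
                if t % 50 == 0:
                    out.append(w.mean(axis=0).mean())   # DCN-side average
            out = np.array(out)
            half = len(out) // 2
            stats[conv] = (out.std(),
                           abs(out[half:].mean() - out[:half].mean()) / 0.04)
        assert stats[40][0] < stats[20][0] < stats[5][0]
        # stable stored association above the biological convergence regime
        assert stats[20][1] < 0.02 and stats[40][1] < 0.02


# ---------------------------------------------------------------------------
# execution-path equivalence

class TestPathEquivalence:
    def test_bank_matches_explicit_net_given_identical_spikes(self, small_net_config):
        net = build_microcomplex(small_net_config, seed=5)
        bank = MicrocomplexBank([build_microcomplex(small_net_config, seed=5)], 1)
        bank._kernel = None
        r = np.random.default_rng(3)
        enc = make_encoder(small_net_config.n_mf, [[-1, 1], [-1, 1]])
        drive = encode_mf((0.2, -0.3), enc)
        for _ in range(300):
            mfs = r.random(small_net_config.n_mf) < drive * 1e-3
            cfs = r.random(small_net_config.n_io) < 0.002
            net.step_network(mf_spikes=mfs, cf_spikes=cfs)
            bank.step(drive[None, :], None,
                      mf_spikes=mfs[None, :], cf_spikes=cfs[None, :])
        assert np.allclose(net.pf_pc.weights, bank.weights()[0], atol=1e-12)

    def test_kernel_matches_numpy_bank(self, small_net_config):
        if MicrocomplexBank([build_microcomplex(small_net_config, 1)], 1)._kernel is None:
            pytest.skip("compiled kernel unavailable")
        nets_a = [build_microcomplex(small_net_config, s) for s in (1, 2)]
        nets_b = [build_microcomplex(small_net_config, s) for s in (1, 2)]
        a = MicrocomplexBank(nets_a, 99)
        b = MicrocomplexBank(nets_b, 99)
        b._kernel = None
        enc = make_encoder(small_net_config.n_mf, [[-1, 1], [-1, 1]])
        mf = np.stack([encode_mf((0.2, -0.3), enc), encode_mf((-0.4, 0.1), enc)])
        cf = np.full((2, small_net_config.n_io), 5.0)
        for _ in range(1200):
            a.step(mf, cf)
            b.step(mf, cf)
        assert np.array_equal(a.u, b.u)
        assert np.array_equal(a.dcn_rate, b.dcn_rate)
        assert np.allclose(a.v_pc, b.v_pc, atol=1e-9)


def test_spike_record_dump_is_columnar_text(small_net_config, tmp_path):
    from cbmsim.network import dump_spike_record
    net = build_microcomplex(small_net_config, seed=4)
    enc = make_encoder(small_net_config.n_mf, [[-1, 1], [-1, 1]])
    drive = encode_mf((0.2, -0.1), enc)
    records = [net.step_network(mf_drive=drive) for _ in range(50)]
    path = tmp_path / "raster.tsv"
    n = dump_spike_record(records, path)
    lines = path.read_text().strip().split("\n")
    assert lines[0] == "time_ms\tpopulation\tneuron_id"
    assert len(lines) == n + 1
    assert n > 0
    t, pop, idx = lines[1].split("\t")
    float(t), int(idx)
    assert pop in {"MF", "GC", "PC", "DCN", "IO"}
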