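"""Internal-model tests: encoders, decoders, teaching signals and the
supervised-convergence properties of isolated predictors/correctors."""

import math

import numpy as np
import pytest

from cbmsim.models import (OFFLINE, ONLINE, PhaseError, TeachingConfig,
                           decode_forward, decode_inverse, encode_mf,
                           make_encoder, motor_error, teach_forward_rates,
                           teach_inverse_rates)
from cbmsim.network import MicrocomplexBank, MicrocomplexConfig, build_microcomplex


class TestEncoder:
    def test_value_at_tuning_centre_gives_max_drive(self):
        enc = make_encoder(16, [[-1, 1], [-1, 1]])
        c = enc.centres[5]
        lo, hi = enc.ranges[:, 0], enc.ranges[:, 1]
        phys = lo + c * (hi - lo)
        drive = encode_mf(phys, enc)
        assert drive[5] == pytest.approx(enc.max_rate_hz)

    def test_tiling_keeps_summed_drive_nearly_flat(self):
        """Sum of drives varies by less than 20% across the input range."""
        enc = make_encoder(25, [[-1, 1], [-1, 1]])
        sums = []
        for x in np.linspace(-1, 1, 15):
            for y in np.linspace(-1, 1, 15):
                sums.append(encode_mf((x, y), enc).sum())
        sums = np.array(sums)
        assert (sums.max() - sums.min()) / sums.mean() < 0.20

    def test_injective_on_grid(self):
        enc = make_encoder(16, [[-1, 1]])
        grid = np.linspace(-1, 1, 100)
        drives = np.stack([encode_mf((x,), enc) for x in grid])
        d = np.abs(drives[:, None, :] - drives[None, :, :]).max(axis=2)
        d += np.eye(100)
        assert d.min() > 1e-6

    def test_out_of_range_values_clamped(self):
        enc = make_encoder(10, [[-1, 1]])
        assert np.allclose(encode_mf((5.0,), enc), encode_mf((1.0,), enc))

    def test_dimension_mismatch_rejected(self):
        enc = make_encoder(10, [[-1, 1], [-1, 1]])
        with pytest.raises(ValueError):
            encode_mf((0.1,), enc)

    def test_manifold_layout_is_deterministic(self, rng):
        samples = rng.normal(size=(300, 3))
        a = make_encoder(20, [[-3, 3]] * 3, samples=samples)
        b = make_encoder(20, [[-3, 3]] * 3, samples=samples)
        assert np.array_equal(a.centres, b.centres)


class TestDecodeForward:
    PV = np.linspace(-1, 1, 6)

    def test_single_active_cell_returns_its_value(self):
        rates = np.array([0.0, 0.0, 0.0, 40.0, 0.0, 0.0])
        v, conf = decode_forward(rates, self.PV)
        assert v == pytest.approx(self.PV[3])
        assert conf == pytest.approx(6.0)

    def test_uniform_firing_keeps_gate_closed(self):
        v, conf = decode_forward(np.full(6, 30.0), self.PV)
        assert v is None

    def test_all_silent_keeps_gate_closed(self):
        v, conf = decode_forward(np.zeros(6), self.PV)
        assert v is None and conf == 0.0

    def test_poisson_raster_peaked_at_value_decodes_within_one_spacing(self, rng):
        """Simulate spiking from a known peaked rate profile and decode."""
        from cbmsim.synthetic import make_poisson_raster
        true_v = 0.2
        prof = 10 + 70 * np.exp(-0.5 * ((self.PV - true_v) / 0.3) ** 2)
        stream = make_poisson_raster(prof, duration=5.0, seed=8)
        rates = stream.raster.mean(axis=0) / stream.dt
        v, conf = decode_forward(rates, self.PV, confidence_threshold=1.2)
        spacing = self.PV[1] - self.PV[0]
        assert v is not None
        assert abs(v - true_v) < spacing


class TestDecodeInverse:
    def test_rate_arithmetic(self):
        assert decode_inverse(np.full(6, 30.0), np.full(6, 10.0),
                              gain=2.0, max_rate_hz=40.0) == pytest.approx(1.0)

    def test_equal_rates_cancel(self):
        assert decode_inverse(np.full(6, 22.0), np.full(6, 22.0), 2.0, 100.0) == 0.0

    def test_range_endpoint(self):
        assert decode_inverse(np.full(6, 100.0), np.zeros(6), 2.0, 100.0) == \
            pytest.approx(2.0)


class TestTeaching:
    def test_motor_error_pd_arithmetic(self):
        cfg = TeachingConfig(k_p=1.0, k_v=0.1)
        assert motor_error(0.1, 0.5, 0.0, 0.0, cfg) == pytest.approx(0.15)

    def test_converged_prediction_gives_baseline_cf(self):
        cfg = TeachingConfig()
        pv = np.linspace(-1, 1, 30)
        sig = teach_forward_rates(0.3, 0.3, pv, (-1, 1), cfg)
        assert np.allclose(sig.io_rates, cfg.cf_baseline_hz)

    def test_error_at_range_limit_reaches_ceiling(self):
        cfg = TeachingConfig()
        pv = np.linspace(-1, 1, 30)
        sig = teach_forward_rates(1.0, -1.0, pv, (-1, 1), cfg)
        assert sig.io_rates.max() == pytest.approx(cfg.cf_max_hz)

    def test_sign_symmetric_errors_give_mirrored_profiles(self):
        cfg = TeachingConfig()
        pv = np.linspace(-1, 1, 30)
        a = teach_forward_rates(0.5, 0.0, pv, (-1, 1), cfg).io_rates
        b = teach_forward_rates(-0.5, 0.0, pv, (-1, 1), cfg).io_rates
        assert np.allclose(a, b[::-1], atol=1e-9)

    def test_forward_teaching_forbidden_offline(self):
        cfg = TeachingConfig()
        with pytest.raises(PhaseError):
            teach_forward_rates(0.1, 0.0, np.linspace(-1, 1, 30), (-1, 1),
                                cfg, phase=OFFLINE)

    def test_positive_error_routes_to_agonist_only(self):
        cfg = TeachingConfig()
        ag = teach_inverse_rates(0.4, 10, cfg, sign=+1)
        ant = teach_inverse_rates(0.4, 10, cfg, sign=-1)
        assert ag.io_rates[0] > cfg.cf_baseline_hz
        assert ant.io_rates[0] <= cfg.cf_baseline_hz

    def test_zero_error_leaves_both_at_baseline(self):
        cfg = TeachingConfig()
        for sign in (+1, -1):
            sig = teach_inverse_rates(0.0, 10, cfg, sign=sign)
            assert np.allclose(sig.io_rates, cfg.cf_baseline_hz)

    def test_normalized_error_clamped_to_unit_interval(self):
        cfg = TeachingConfig()
        sig = teach_inverse_rates(10.0, 10, cfg, sign=+1)
        assert abs(sig.normalized_error) <= 1.0
        assert sig.io_rates.max() <= cfg.cf_max_hz


# ---------------------------------------------------------------------------
# supervised convergence of isolated models

def test_inverse_corrector_converges_against_constant_disturbance():
    """Constant context + sustained agonist teaching: the decoded
    correction grows toward countering the disturbance and the antagonist
    stays put."""
    cfg = MicrocomplexConfig(n_mf=20, plasticity_lag_ms=0.0)
    nets = [build_microcomplex(cfg, 11), build_microcomplex(cfg, 11)]
    bank = MicrocomplexBank(nets, 5)
    enc = make_encoder(20, [[-1, 1], [-1, 1]])
    drive = encode_mf((0.2, -0.3), enc)
    mf = np.stack([drive, drive])
    cf = np.full((2, cfg.n_io), cfg.cf_baseline_hz)
    cf[0] = 6.0
    early = late = None
    for t in range(6000):
        bank.step(mf, cf)
        if t == 1500:
            r = bank.dcn_rate.mean(axis=1)
            early = 2.0 * (r[0] - r[1]) / 100.0
    r = bank.dcn_rate.mean(axis=1)
    late = 2.0 * (r[0] - r[1]) / 100.0
    assert late > 0.15
    assert late > early - 0.1   # correction does not unwind
    # antagonist (no teaching beyond baseline) kept its weights
    assert np.allclose(bank.u[1], cfg.w_init, atol=1e-12)


def test_forward_predictor_error_decreases_with_training():
    """Training one predictor on a fixed context->value mapping reduces
    the decode error below the no-information level (predicting zero)."""
    cfg = MicrocomplexConfig(n_mf=20, pc_dcn_profile="kernel", n_dcn=12,
                             plasticity_lag_ms=0.0, alpha_ltd=0.0008,
                             cf_max_hz=25.0, trace_tau_ms=25.0, w_mfgc=0.40,
                             w_max=0.028)
    pv_pc = np.linspace(-1, 1, cfg.n_pc)
    pv_dcn = np.linspace(-1, 1, cfg.n_dcn)
    net = build_microcomplex(cfg, 11, preferred_values=pv_pc)
    bank = MicrocomplexBank([net], 5)
    enc = make_encoder(20, [[-1, 1], [-1, 1]])
    tc = TeachingConfig(teach_sigma=0.08, cf_max_hz=25.0)

    def raw_decode():
        r = bank.dcn_rate[0]
        mean = r.mean()
        ex = np.maximum(r - mean, 0)
        tot = ex.sum()
        return 0.0 if tot <= 0 else float((ex * pv_dcn).sum() / tot)

    rng = np.random.default_rng(0)
    errs_during = []
    for ep in range(250):
        x, y = rng.uniform(-1, 1, 2)
        target = 0.5 * x
        for t in range(60):
            rv = raw_decode()
            err = min(abs(target - rv), 1.0)
            zt = (target + 1) / 2
            prof = np.exp(-0.5 * ((np.linspace(0, 1, cfg.n_pc) - zt) / 0.08) ** 2)
            rates = 1.0 + 24.0 * err * prof
            bank.step(encode_mf((x, y), enc)[None, :], rates[None, :])
        errs_during.append(err)
        bank.reset_to_baseline()
    # smoothed training-error curve decreases
    first = np.mean(errs_during[:40])
    last = np.mean(errs_during[-40:])
    assert last < first
    # decode beats the no-information baseline on a probe grid
    errs, mags = [], []
    for x in np.linspace(-0.9, 0.9, 7):
        for t in range(150):
            bank.step(encode_mf((x, 0.0), enc)[None, :], None, plastic=False)
        errs.append(abs(raw_decode() - 0.5 * x))
        mags.append(abs(0.5 * x))
        bank.reset_to_baseline()
    assert np.mean(errs) < np.mean(mags)
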