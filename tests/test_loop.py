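"""Closed-loop tests: delay discipline, bias injection, scheme gating,
determinism and offline replay invariants."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbmsim.loop import (DelayLine, LoopConfig, ModeConfig, ModelSet,
                         apply_bias, offline_replay, run_trajectory)
from cbmsim.metrics import trajectory_errors
from cbmsim.protocol import Subject, desk_scale_protocol


@pytest.fixture(scope="module")
def subject_factory(task_ranges):
    protocol = desk_scale_protocol()

    def make(seed=7):
        return Subject(protocol, seed, ranges=task_ranges), protocol
    return make


class TestDelayLine:
    def test_fifo_latency_contract(self):
        line = DelayLine(5, -1)
        out = [line.push_pop(k) for k in range(12)]
        assert out[:5] == [-1] * 5
        assert out[5:] == list(range(7))

    @given(st.integers(1, 40), st.lists(st.integers(), min_size=1, max_size=80))
    @settings(max_examples=30, deadline=None)
    def test_item_pushed_at_k_returns_at_k_plus_n(self, n, items):
        line = DelayLine(n, None)
        for k, item in enumerate(items):
            got = line.push_pop(item)
            if k >= n:
                assert got == items[k - n]
            else:
                assert got is None

    def test_zero_latency_passthrough(self):
        line = DelayLine(0, None)
        assert line.push_pop(3) == 3

    def test_preload_must_fill_line(self):
        with pytest.raises(ValueError):
            DelayLine(3, None, preload=[1, 2])


class TestModeConfig:
    def test_scheme_gating_flags(self):
        fm = ModeConfig(scheme="FM")
        im = ModeConfig(scheme="IM")
        cm = ModeConfig(scheme="CM")
        assert fm.forward_active and not fm.inverse_active
        assert im.inverse_active and not im.forward_active
        assert not im.replan_enabled    # no forward predictions, no replanning
        assert cm.forward_active and cm.inverse_active

    def test_offline_disables_replanning(self):
        mode = ModeConfig(scheme="CM", phase="offline")
        assert not mode.replan_enabled

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            ModeConfig(scheme="XX")


class TestApplyBias:
    def test_zero_bias_is_identity(self):
        pts = np.array([[0.1, 0.45], [0.0, 0.42]])
        assert np.array_equal(apply_bias(pts, 0.0, (0.0, 0.42)), pts)

    def test_rotation_about_centre(self):
        out = apply_bias(np.array([0.1, 0.0]), 90.0, (0.0, 0.0))
        assert out == pytest.approx([0.0, 0.1], abs=1e-12)


class TestRunTrajectory:
    def test_unbiased_frozen_run_tracks_the_plan(self, subject_factory):
        """With no bias and learning off, the feedforward chain brings the
        hand to the target with sub-millimetre accuracy and near-zero
        directional error."""
        subj, protocol = subject_factory(seed=21)
        mode = ModeConfig(scheme="FM", bias_deg=0.0, learning=False)
        rec, _ = run_trajectory(subj.arm_state, protocol.arm, subj.models,
                                mode, subj.targets[0], subj.centre,
                                plan=subj.base_plans[0], cfg=protocol.loop)
        m = trajectory_errors(rec.movement_path, subj.centre, subj.targets[0],
                              15.0, protocol.metric, velocity=rec.movement_vel)
        assert m.raw_distance_mm < 1.0
        assert m.raw_angle_deg < 0.75      # < 0.05 of the 15 deg normalization

    def test_unadapted_bias_15_scores_one(self, subject_factory):
        subj, protocol = subject_factory(seed=22)
        mode = ModeConfig(scheme="IM", bias_deg=15.0, learning=False)
        errs = []
        state = subj.arm_state
        for k in range(4):
            rec, state = run_trajectory(state, protocol.arm, subj.models,
                                        mode, subj.targets[k], subj.centre,
                                        plan=subj.base_plans[k], cfg=protocol.loop)
            m = trajectory_errors(rec.movement_path, subj.centre,
                                  subj.targets[k], 15.0, protocol.metric,
                                  velocity=rec.movement_vel)
            errs.append(m.directional)
        assert np.mean(errs) == pytest.approx(1.0, abs=0.05)

    def test_record_structure(self, subject_factory):
        subj, protocol = subject_factory(seed=23)
        mode = ModeConfig(scheme="CM", bias_deg=15.0)
        rec, state = run_trajectory(subj.arm_state, protocol.arm, subj.models,
                                    mode, subj.targets[2], subj.centre,
                                    plan=subj.base_plans[2], cfg=protocol.loop,
                                    record_full=True)
        n_total = protocol.loop.n_move + protocol.loop.n_reset
        assert rec.hand_path.shape == (n_total, 2)   # 0.7 s move + 0.3 s reset
        assert rec.movement_path.shape[0] == 700
        # reset window: hand repositioned at S
        assert np.allclose(rec.hand_path[-1], subj.centre, atol=1e-6)
        assert state.omega_s == 0.0 and state.omega_e == 0.0
        # hand path consistent with the actual joint states
        from cbmsim.arm import forward_kinematics
        i = 400
        th = rec.actual_theta[i]
        assert forward_kinematics((th[0], th[1]), protocol.arm) == \
            pytest.approx(tuple(rec.hand_path[i]), abs=1e-9)

    def test_fm_scheme_freezes_inverse_weights(self, subject_factory):
        subj, protocol = subject_factory(seed=24)
        before = subj.models.inv_bank.u.copy()
        mode = ModeConfig(scheme="FM", bias_deg=30.0)
        run_trajectory(subj.arm_state, protocol.arm, subj.models, mode,
                       subj.targets[0], subj.centre, plan=subj.base_plans[0],
                       cfg=protocol.loop)
        assert np.array_equal(subj.models.inv_bank.u, before)

    def test_im_scheme_freezes_forward_weights_and_never_replans(self, subject_factory):
        subj, protocol = subject_factory(seed=25)
        before = subj.models.fwd_bank.u.copy()
        mode = ModeConfig(scheme="IM", bias_deg=30.0)
        rec, _ = run_trajectory(subj.arm_state, protocol.arm, subj.models,
                                mode, subj.targets[0], subj.centre,
                                plan=subj.base_plans[0], cfg=protocol.loop)
        assert np.array_equal(subj.models.fwd_bank.u, before)
        assert rec.replan_count == 0

    def test_identical_seeds_give_identical_records(self, task_ranges):
        protocol = desk_scale_protocol()
        paths = []
        for _ in range(2):
            subj = Subject(protocol, 99, ranges=task_ranges)
            mode = ModeConfig(scheme="CM", bias_deg=30.0)
            rec, _ = run_trajectory(subj.arm_state, protocol.arm, subj.models,
                                    mode, subj.targets[3], subj.centre,
                                    plan=subj.base_plans[3], cfg=protocol.loop)
            paths.append(rec.hand_path.copy())
        assert np.array_equal(paths[0], paths[1])


class TestOfflineReplay:
    def test_counts_and_forward_freeze(self, subject_factory):
        subj, protocol = subject_factory(seed=26)
        # brief online phase so the stored-plan list is non-trivial
        subj.run_trial(15.0, "CM")
        fwd_before = subj.models.fwd_bank.u.copy()
        stored = [(subj.targets[k], subj.base_plans[k])
                  for k in subj.online_target_log]
        n = offline_replay(stored, 6, subj.arm_state, protocol.arm,
                           subj.models, subj.centre,
                           np.random.default_rng(5), "CM", protocol.loop)
        assert n == 6
        assert np.array_equal(subj.models.fwd_bank.u, fwd_before)

    def test_untrained_forward_gate_blocks_inverse_adaptation(self, subject_factory):
        """Replay with a naive (gate-closed) forward model leaves the
        correctors' weights exactly untouched: no teaching information."""
        subj, protocol = subject_factory(seed=27)
        inv_before = subj.models.inv_bank.u.copy()
        stored = [(subj.targets[k], subj.base_plans[k]) for k in range(8)]
        offline_replay(stored, 4, subj.arm_state, protocol.arm, subj.models,
                       subj.centre, np.random.default_rng(6), "CM",
                       protocol.loop)
        assert np.array_equal(subj.models.inv_bank.u, inv_before)

    def test_empty_plan_store_rejected(self, subject_factory):
        subj, protocol = subject_factory(seed=28)
        with pytest.raises(ValueError):
            offline_replay([], 5, subj.arm_state, protocol.arm, subj.models,
                           subj.centre, np.random.default_rng(0))
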