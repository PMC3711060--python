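"""Numba-compiled inner kernel for the batched microcomplex step.

Numerically identical to :meth:`MicrocomplexBank.step`'s numpy path
(same update order, same random-number consumption, and decay applied
as the same multiply sequence, so results are bit-exact); the numpy
path remains the reference and the fallback when numba is unavailable.

The granule layer is updated lazily: a GC's membrane potential,
refractory state and eligibility trace only change visibly when one of
its mossy-fibre afferents spikes (or when a climbing-fibre event needs
every trace), so the kernel walks the outgoing adjacency of the spiking
MFs instead of sweeping all 100x|MF| granule cells every step.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is an optional speedup
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _decay_to(value, steps, decay):
    # same multiply sequence as per-step dense decay (bit-exact)
    for _ in range(steps):
        value *= decay
    return value


@njit(cache=True)
def bank_step(t, mf_spk, dt,
              mf_indptr, mf_indices, w_mfgc,
              v_gc, gc_last, gc_ref_until, dec_gc, refsteps_gc,
              v_pc, ref_pc, dec_pc, refsteps_pc,
              v_dcn, ref_dcn, dec_dcn, refsteps_dcn,
              dcn_syn, dec_syn,
              u, trace, trace_last, alpha_ltp, trace_decay,
              pc_dcn, w_mfdcn,
              dcn_rate, rate_decay, rate_gain,
              cf_u, cf_excess, cf_deficit, alpha_ltd, w_min, w_max,
              apply_cf, lag, hist_idx, hist_cnt,
              cnt_scratch, touched_scratch, spk_scratch,
              pc_spk_out, dcn_spk_out):
    """One step (global step index ``t``) of all B nets."""
    B, n_mf = mf_spk.shape
    n_gc = v_gc.shape[1]
    n_pc = v_pc.shape[1]
    n_dcn = v_dcn.shape[1]

    for b in range(B):
        # ----- which GCs the spiking MFs touch ----------------------------
        n_mf_spk = 0
        n_touch = 0
        for m in range(n_mf):
            if mf_spk[b, m]:
                n_mf_spk += 1
                row = b * n_mf + m
                for k in range(mf_indptr[row], mf_indptr[row + 1]):
                    g = mf_indices[k]
                    if cnt_scratch[b, g] == 0:
                        touched_scratch[n_touch] = g
                        n_touch += 1
                    cnt_scratch[b, g] += 1

        # ----- granule layer (lazy) ---------------------------------------
        pc_in = np.zeros(n_pc)
        trace_spk_sum = 0.0
        n_spk = 0
        for i in range(n_touch):
            g = touched_scratch[i]
            cnt = cnt_scratch[b, g]
            cnt_scratch[b, g] = 0
            if t < gc_ref_until[b, g]:
                continue
            v = _decay_to(v_gc[b, g], t - gc_last[b, g], dec_gc)
            v += w_mfgc * cnt
            if v >= 1.0:
                # effective weight of the spiking PF is u + alpha_ltp*trace,
                # with the trace decayed to t-1 (pre-update value)
                tr = _decay_to(trace[b, g], (t - 1) - trace_last[b, g],
                               trace_decay)
                trace[b, g] = tr
                trace_last[b, g] = t - 1
                trace_spk_sum += tr
                for p_i in range(n_pc):
                    pc_in[p_i] += u[b, g, p_i]
                spk_scratch[n_spk] = g
                n_spk += 1
                v_gc[b, g] = 0.0
                gc_last[b, g] = t
                gc_ref_until[b, g] = t + refsteps_gc + 1
            else:
                v_gc[b, g] = v
                gc_last[b, g] = t

        # ----- plasticity spike ring: inject lagged spikes, store new ----
        if lag > 0:
            slot = t % lag
            for i in range(hist_cnt[slot, b]):
                g = hist_idx[slot, b, i]
                tr = _decay_to(trace[b, g], t - trace_last[b, g], trace_decay)
                trace[b, g] = tr + 1.0
                trace_last[b, g] = t
            hist_cnt[slot, b] = n_spk
            for i in range(n_spk):
                hist_idx[slot, b, i] = spk_scratch[i]
        else:
            for i in range(n_spk):
                g = spk_scratch[i]
                tr = _decay_to(trace[b, g], t - trace_last[b, g], trace_decay)
                trace[b, g] = tr + 1.0
                trace_last[b, g] = t

        # ----- Purkinje layer ----------------------------------------------
        for p_i in range(n_pc):
            v = v_pc[b, p_i] * dec_pc
            spiked = False
            if ref_pc[b, p_i] <= 0:
                v += pc_in[p_i] + alpha_ltp * trace_spk_sum
                if v >= 1.0:
                    spiked = True
                    v = 0.0
            else:
                v = 0.0
            v_pc[b, p_i] = v
            r = ref_pc[b, p_i] - 1
            if r < 0:
                r = 0
            if spiked:
                r = refsteps_pc
            ref_pc[b, p_i] = r
            pc_spk_out[b, p_i] = spiked

        # ----- deep nuclei --------------------------------------------------
        exc = w_mfdcn * n_mf_spk
        for d in range(n_dcn):
            inh = 0.0
            for p_i in range(n_pc):
                if pc_spk_out[b, p_i]:
                    inh += pc_dcn[b, p_i, d]
            syn = dcn_syn[b, d] + (1.0 - dec_syn) * ((exc - inh) - dcn_syn[b, d])
            dcn_syn[b, d] = syn
            v = v_dcn[b, d] * dec_dcn
            spiked = False
            if ref_dcn[b, d] <= 0:
                v += syn
                if v >= 1.0:
                    spiked = True
                    v = 0.0
            else:
                v = 0.0
            v_dcn[b, d] = v
            r = ref_dcn[b, d] - 1
            if r < 0:
                r = 0
            if spiked:
                r = refsteps_dcn
            ref_dcn[b, d] = r
            dcn_spk_out[b, d] = spiked
            nr = dcn_rate[b, d] * rate_decay
            if spiked:
                nr += rate_gain
            dcn_rate[b, d] = nr

        # ----- error-driven climbing-fibre LTD / suppression recovery ------
        if apply_cf:
            n_io = cf_excess.shape[1]
            for j in range(n_io):
                depress = cf_excess[b, j] > 0.0 and cf_u[b, j] < cf_excess[b, j] * dt
                recover = (not depress and cf_deficit[b, j] > 0.0
                           and cf_u[b, j] < cf_deficit[b, j] * dt)
                if depress or recover:
                    step_w = -alpha_ltd if depress else alpha_ltd
                    for g in range(n_gc):
                        tr = _decay_to(trace[b, g], t - trace_last[b, g],
                                       trace_decay)
                        trace[b, g] = tr
                        trace_last[b, g] = t
                        if tr > 0.0:
                            w = u[b, g, j] + step_w * tr
                            if w < w_min:
                                w = w_min
                            elif w > w_max:
                                w = w_max
                            u[b, g, j] = w
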