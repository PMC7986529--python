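"""Compiled fixed-step simulation kernel.

One call advances the full network by one scheduling block: synaptic input
gathering with conduction delays, twin-integrator membrane update, STDP
traces and weight updates, external bias generation (jittered correlated
column events plus uncorrelated per-unit drive), LFP/EMG synthesis, causal
band-pass filtering for closed-loop triggers, and stimulus delivery (both a
pre-computed open-loop schedule and triggers detected online).

The kernel mutates its state arrays in place and is deterministic given the
seed.  Layout conventions (fixed across the package):

* units 0..239 are cortical (three columns of 40 excitatory then 40
  inhibitory units), units 240..359 are motoneurons (three pools of 40);
* the weight matrix is *source-major* here: ``wt[j, i]`` is the connection
  from source ``j`` onto target ``i`` (the transpose of the target-major
  ``Network.w``), so spike propagation reads contiguous rows;
* ring buffers are indexed by absolute step modulo their length.

Semantics are identical to the reference implementation in
:mod:`ifnet.engine` / :mod:`ifnet.plasticity`; the test suite holds the two
paths to agreement spike-for-spike.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_block_kernel", "PROTO_NONE", "PROTO_SPIKE", "PROTO_THRESHOLD", "PROTO_CYCLE"]

N_CORT = 240
N_UNITS = 360
N_PER_COL = 80
PEND_LEN = 4096          # pending-stimulus horizon (steps)

PROTO_NONE = 0
PROTO_SPIKE = 1          # spike-triggered stimulation (incl. inhibition: negative amp)
PROTO_THRESHOLD = 2      # threshold crossing of a filtered signal (EMG or gamma LFP)
PROTO_CYCLE = 3          # beta-cycle phase-locked stimulation


@njit(cache=True)
def _sos_step(sos, zi, x):
    """One sample through a cascaded-biquad causal filter (direct form II transposed)."""
    y = x
    for s in range(sos.shape[0]):
        b0, b1, b2, _, a1, a2 = sos[s, 0], sos[s, 1], sos[s, 2], sos[s, 3], sos[s, 4], sos[s, 5]
        xin = y
        y = b0 * xin + zi[s, 0]
        zi[s, 0] = b1 * xin - a1 * y + zi[s, 1]
        zi[s, 1] = b2 * xin - a2 * y
    return y


@njit(cache=True)
def run_block_kernel(
    n_steps, t_abs0, seed,
    # membrane / timing
    h, cs, cf, theta, dc, dm, refr_steps,
    # weights (source-major) and plasticity
    wt, plastic, sign,
    wmin, wmax, r, c, plasticity_on,
    das, daf, dbs, dbf,
    # persistent state
    vs, vf, ring, next_allowed,
    s_slow, s_fast, t_slow, t_fast,
    # bias generation
    p_c, log1mp, unit_col, w_bias,
    jitter_sd_steps, lookahead, env, env_max,
    corr_ring, uncorr_count, bias_deliveries,
    # field potentials / EMG
    lfp_s, lfp_f, lfp2_s, lfp2_f, emg_s, emg_f, muap_w,
    lfp_out, lfp2_out, emg_out,
    # open-loop stimulus schedule (block-relative steps, sorted)
    stim_steps, stim_cols, stim_amps,
    # closed-loop protocol
    proto_id, trig_unit, trig_delay, stim_amp, train_n, train_interval,
    lockout, target_col, edge, thr_level,
    sos, zi, src_kind, src_idx, phase_offset, arm_window,
    cond_start, cond_end, proto_state,
    # pending stimuli (persistent, absolute-step ring over columns)
    pend,
    # recording
    spike_steps, spike_units, trig_log,
    v_record_unit, v_out,
    wtrack_j, wtrack_i, wtrack_interval, wtrack_out,
):
    np.random.seed(seed)
    n = N_UNITS
    nc = N_CORT
    ring_len = ring.shape[0]
    l2 = corr_ring.shape[0]
    spike_cap = spike_steps.shape[0]
    trig_cap = trig_log.shape[0]
    n_spikes = 0
    n_trigs = 0
    sp = 0                       # open-loop schedule pointer
    a = np.zeros(n)
    u_now = np.zeros(n, dtype=np.uint8)
    arr_list = np.empty(nc, dtype=np.int64)
    arrm_list = np.empty(nc, dtype=np.int64)
    wtrack_ptr = 0

    last_trig = proto_state[0]
    prev_filt = proto_state[1]
    armed_until = proto_state[2]

    for t in range(n_steps):
        t_abs = t_abs0 + t

        # ---- 1. external bias ------------------------------------------------
        # correlated column events, generated `lookahead` steps ahead
        for col in range(3):
            pc = p_c[col] * env[t + lookahead, col]
            if pc > 0.0 and np.random.random() < pc:
                base = t_abs + lookahead
                for u in range(col * N_PER_COL, (col + 1) * N_PER_COL):
                    jit = np.random.normal(0.0, 1.0) * jitter_sd_steps
                    if jit > lookahead:
                        jit = lookahead
                    elif jit < -lookahead:
                        jit = -lookahead
                    slot = (base + int(round(jit))) % l2
                    corr_ring[slot, u] += 1.0
        # single fused pass: zero A, uncorrelated countdowns, correlated deliveries
        slot0 = t_abs % l2
        for u in range(n):
            acc = 0.0
            uncorr_count[u] -= 1
            if uncorr_count[u] <= 0:
                colu = unit_col[u]
                accept = True
                if colu >= 0 and env_max[colu] > 1.0:
                    accept = np.random.random() < env[t, colu] / env_max[colu]
                if accept:
                    acc += w_bias
                    bias_deliveries[u] += 1.0
                if log1mp[u] < 0.0:
                    g = np.log(1.0 - np.random.random()) / log1mp[u]
                    uncorr_count[u] = 1 + int(g)
                else:
                    uncorr_count[u] = 1 << 60
            if u < nc:
                cnt = corr_ring[slot0, u]
                if cnt != 0.0:
                    acc += cnt * w_bias
                    bias_deliveries[u] += cnt
                    corr_ring[slot0, u] = 0.0
            a[u] = acc

        # ---- 2. delayed recurrent spikes ------------------------------------
        n_arr = 0
        lfp2_in0 = 0.0
        lfp2_in1 = 0.0
        lfp2_in2 = 0.0
        row_c = (t_abs - dc) % ring_len
        for j in range(nc):
            if ring[row_c, j] == 1:
                arr_list[n_arr] = j
                n_arr += 1
                wrow = wt[j]
                for i in range(N_PER_COL):
                    a[i] += wrow[i]
                    lfp2_in0 += wrow[i]
                for i in range(N_PER_COL, 2 * N_PER_COL):
                    a[i] += wrow[i]
                    lfp2_in1 += wrow[i]
                for i in range(2 * N_PER_COL, nc):
                    a[i] += wrow[i]
                    lfp2_in2 += wrow[i]
        n_arrm = 0
        row_m = (t_abs - dm) % ring_len
        for j in range(nc):
            if ring[row_m, j] == 1:
                arrm_list[n_arrm] = j
                n_arrm += 1
                wrow = wt[j]
                for i in range(nc, n):
                    a[i] += wrow[i]

        # per-column LFP input: all synaptic + bias PSP drive (stimuli excluded)
        lfp_in0 = 0.0
        lfp_in1 = 0.0
        lfp_in2 = 0.0
        for u in range(N_PER_COL):
            lfp_in0 += a[u]
            lfp_in1 += a[u + N_PER_COL]
            lfp_in2 += a[u + 2 * N_PER_COL]

        # ---- 3. threshold evaluation + accumulator advance (reset wins) ------
        if v_record_unit >= 0:
            v_out[t] = vs[v_record_unit] - vf[v_record_unit]
        row_now = t_abs % ring_len
        for i in range(n):
            v = vs[i] - vf[i]
            if v > theta[i] and (refr_steps == 0 or t_abs >= next_allowed[i]):
                u_now[i] = 1
                ring[row_now, i] = 1
                vs[i] = 0.0
                vf[i] = 0.0
                if refr_steps > 0:
                    next_allowed[i] = t_abs + refr_steps
                if n_spikes < spike_cap:
                    spike_steps[n_spikes] = t
                    spike_units[n_spikes] = i
                n_spikes += 1
            else:
                u_now[i] = 0
                ring[row_now, i] = 0
                vs[i] = cs * vs[i] + a[i]
                vf[i] = cf * vf[i] + a[i]

        # ---- 4. plasticity ---------------------------------------------------
        if plasticity_on == 1:
            # strengthening: post spike reads source traces (values before this
            # step's increments)
            for i in range(nc):
                if u_now[i] == 1:
                    for j in range(nc):
                        if plastic[j, i] == 1:
                            dwv = r * (s_slow[j] - s_fast[j])
                            wv = wt[j, i]
                            if sign[j] > 0:
                                wv += dwv
                                if wv > wmax:
                                    wv = wmax
                                elif wv < wmin:
                                    wv = wmin
                            else:
                                wv -= dwv
                                if wv < -wmax:
                                    wv = -wmax
                                elif wv > -wmin:
                                    wv = -wmin
                            wt[j, i] = wv
            # weakening: presynaptic arrival reads target traces
            for k in range(n_arr):
                j = arr_list[k]
                wrow = wt[j]
                for i in range(nc):
                    if plastic[j, i] == 1:
                        dwv = r * c * (t_slow[i] - t_fast[i])
                        wv = wrow[i]
                        if sign[j] > 0:
                            wv -= dwv
                            if wv > wmax:
                                wv = wmax
                            elif wv < wmin:
                                wv = wmin
                        else:
                            wv += dwv
                            if wv < -wmax:
                                wv = -wmax
                            elif wv > -wmin:
                                wv = -wmin
                        wrow[i] = wv
        # traces advance every step (decay then increment), plasticity on or off
        for j in range(nc):
            s_slow[j] *= das
            s_fast[j] *= daf
            t_slow[j] *= dbs
            t_fast[j] *= dbf
        for k in range(n_arr):
            j = arr_list[k]
            s_slow[j] += 1.0
            s_fast[j] += 1.0
        for i in range(nc):
            if u_now[i] == 1:
                t_slow[i] += 1.0
                t_fast[i] += 1.0

        # ---- 5. LFP / EMG integrators (no reset) -----------------------------
        lfp_s[0] = cs * lfp_s[0] + lfp_in0
        lfp_f[0] = cf * lfp_f[0] + lfp_in0
        lfp_s[1] = cs * lfp_s[1] + lfp_in1
        lfp_f[1] = cf * lfp_f[1] + lfp_in1
        lfp_s[2] = cs * lfp_s[2] + lfp_in2
        lfp_f[2] = cf * lfp_f[2] + lfp_in2
        lfp2_s[0] = cs * lfp2_s[0] + lfp2_in0
        lfp2_f[0] = cf * lfp2_f[0] + lfp2_in0
        lfp2_s[1] = cs * lfp2_s[1] + lfp2_in1
        lfp2_f[1] = cf * lfp2_f[1] + lfp2_in1
        lfp2_s[2] = cs * lfp2_s[2] + lfp2_in2
        lfp2_f[2] = cf * lfp2_f[2] + lfp2_in2
        for p in range(3):
            emg_in = 0.0
            for m in range(N_CORT + 40 * p, N_CORT + 40 * (p + 1)):
                if u_now[m] == 1:
                    emg_in += muap_w[m]
            emg_s[p] = cs * emg_s[p] + emg_in
            emg_f[p] = cf * emg_f[p] + emg_in
            lfp_out[t, p] = lfp_s[p] - lfp_f[p]
            lfp2_out[t, p] = lfp2_s[p] - lfp2_f[p]
            emg_out[t, p] = emg_s[p] - emg_f[p]

        # ---- 6. closed-loop trigger detection --------------------------------
        if proto_id != PROTO_NONE and cond_start <= t < cond_end:
            triggered = False
            if proto_id == PROTO_SPIKE:
                if u_now[trig_unit] == 1 and t_abs - last_trig >= lockout:
                    triggered = True
            elif proto_id == PROTO_THRESHOLD:
                if src_kind == 0:
                    x = emg_out[t, src_idx]
                elif src_kind == 1:
                    x = lfp_out[t, src_idx]
                else:
                    x = lfp2_out[t, src_idx]
                y = _sos_step(sos, zi, x)
                if t_abs - last_trig >= lockout:
                    if edge > 0:
                        if prev_filt < thr_level and y >= thr_level:
                            triggered = True
                    else:
                        if prev_filt > thr_level and y <= thr_level:
                            triggered = True
                prev_filt = y
            elif proto_id == PROTO_CYCLE:
                x = lfp_out[t, src_idx] if src_kind == 1 else lfp2_out[t, src_idx]
                y = _sos_step(sos, zi, x)
                if y >= thr_level:
                    armed_until = t_abs + arm_window
                if t_abs < armed_until and t_abs - last_trig >= lockout:
                    if edge > 0:
                        if prev_filt <= 0.0 and y > 0.0:
                            triggered = True
                    else:
                        if prev_filt >= 0.0 and y < 0.0:
                            triggered = True
                prev_filt = y
            if triggered:
                last_trig = t_abs
                if n_trigs < trig_cap:
                    trig_log[n_trigs] = t_abs
                n_trigs += 1
                base = t_abs + trig_delay + (phase_offset if proto_id == PROTO_CYCLE else 0)
                for k in range(train_n):
                    slot = (base + k * train_interval) % PEND_LEN
                    pend[slot, target_col] += stim_amp
        elif proto_id == PROTO_THRESHOLD or proto_id == PROTO_CYCLE:
            # keep the causal filter running outside the conditioning window
            if src_kind == 0:
                x = emg_out[t, src_idx]
            elif src_kind == 1:
                x = lfp_out[t, src_idx]
            else:
                x = lfp2_out[t, src_idx]
            prev_filt = _sos_step(sos, zi, x)

        # ---- 7. stimulus delivery (after reset, so steps are never swallowed) -
        while sp < stim_steps.shape[0] and stim_steps[sp] == t:
            colx = stim_cols[sp]
            amp = stim_amps[sp]
            for u in range(colx * N_PER_COL, (colx + 1) * N_PER_COL):
                vs[u] += amp
            sp += 1
        slotp = t_abs % PEND_LEN
        for colx in range(3):
            amp = pend[slotp, colx]
            if amp != 0.0:
                for u in range(colx * N_PER_COL, (colx + 1) * N_PER_COL):
                    vs[u] += amp
                pend[slotp, colx] = 0.0

        # ---- 8. tracked-weight snapshot --------------------------------------
        if wtrack_interval > 0 and (t + 1) % wtrack_interval == 0:
            acc = 0.0
            for k in range(wtrack_j.shape[0]):
                acc += abs(wt[wtrack_j[k], wtrack_i[k]])
            if wtrack_ptr < wtrack_out.shape[0]:
                wtrack_out[wtrack_ptr] = acc / wtrack_j.shape[0]
            wtrack_ptr += 1

    proto_state[0] = last_trig
    proto_state[1] = prev_filt
    proto_state[2] = armed_until
    return n_spikes, n_trigs
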