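"""Numba kernels for the lattice Gillespie engine.

State codes (shared with :mod:`colirange.params`): 0 FREE, 1 S, 2 R, 3 C,
4 LYSED.  The exact-stochastic loop keeps an active list of colonized patches
that have passed their lag and still see open neighbours; per-patch
colonization propensity is ``mu[strain] * n_open / 8``.  Lag expiries are
deterministic rate changes handled as time barriers: if the exponential
waiting time would jump past the next expiry, the clock is advanced to the
expiry and the waiting time redrawn (exact by memorylessness).

Sensitive (S) patches never colonize LYSED ground and their colonization
attempts into patches at colicin concentration >= threshold are rejected by
thinning (the clock still advances).  S patches at concentration >= threshold
lyse at a fixed rate.  The colicin field is cumulative: every toxic C patch
adds a truncated exponential kernel to the concentration grid when it
appears, and sources never decay (stationary source-degradation profile).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# 8-neighbour offsets (row, col)
_NBI = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
_NBJ = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)

# stop reasons
REASON_RADIUS = 0
REASON_STALLED = 1
REASON_TIME = 2
REASON_MAX_EVENTS = 3


@njit(cache=True)
def _count_open(state, i, j, s, lysed_recol):
    """Open (colonizable) neighbours of patch (i, j) for a strain s parent."""
    G = state.shape[0]
    n = 0
    for k in range(8):
        ii = i + _NBI[k]
        jj = j + _NBJ[k]
        if 0 <= ii < G and 0 <= jj < G:
            st = state[ii, jj]
            if st == 0 or (st == 4 and lysed_recol and s != 1):
                n += 1
    return n


@njit(cache=True)
def _heap_push(ht, hi, n, t, idx):
    ht[n] = t
    hi[n] = idx
    c = n
    while c > 0:
        p = (c - 1) // 2
        if ht[p] <= ht[c]:
            break
        ht[p], ht[c] = ht[c], ht[p]
        hi[p], hi[c] = hi[c], hi[p]
        c = p
    return n + 1


@njit(cache=True)
def _heap_pop(ht, hi, n):
    t = ht[0]
    idx = hi[0]
    n -= 1
    ht[0] = ht[n]
    hi[0] = hi[n]
    p = 0
    while True:
        l = 2 * p + 1
        r = l + 1
        sm = p
        if l < n and ht[l] < ht[sm]:
            sm = l
        if r < n and ht[r] < ht[sm]:
            sm = r
        if sm == p:
            break
        ht[p], ht[sm] = ht[sm], ht[p]
        hi[p], hi[sm] = hi[sm], hi[p]
        p = sm
    return t, idx, n


@njit(cache=True)
def add_source_kernel(conc, state, si, sj, kappa, lam_p, cutoff_p, thr,
                      lys_list, lys_pos, nlys, lyse_on):
    """Add one toxic source's exponential kernel to the concentration grid.

    Enqueues S patches whose concentration crosses the threshold for lysis.
    Returns the updated lysis-queue length.
    """
    G = conc.shape[0]
    w = int(cutoff_p) + 1
    ilo = max(0, si - w)
    ihi = min(G, si + w + 1)
    jlo = max(0, sj - w)
    jhi = min(G, sj + w + 1)
    for ii in range(ilo, ihi):
        for jj in range(jlo, jhi):
            di = float(ii - si)
            dj = float(jj - sj)
            d = math.sqrt(di * di + dj * dj)
            if d <= cutoff_p:
                old = conc[ii, jj]
                new = old + kappa * math.exp(-d / lam_p)
                conc[ii, jj] = new
                if lyse_on and state[ii, jj] == 1 and old < thr and new >= thr:
                    if lys_pos[ii, jj] < 0:
                        lys_pos[ii, jj] = nlys
                        lys_list[nlys] = ii * G + jj
                        nlys += 1
    return nlys


@njit(cache=True)
def run_core(state, act_time, col_time, conc, toxic, mu, new_lag, p_tox,
             kappa, lam_p, cutoff_p, thr, lysis_rate, stop_r_p, stop_time,
             record_times, record_area, seed, lysed_recol, lyse_on,
             max_events):
    """Run the Gillespie dynamics in place; returns run summary scalars.

    Arrays ``state``/``act_time``/``col_time``/``conc``/``toxic`` hold the
    seeded initial condition and are mutated to the final state.
    Returns (t_final, stop_reason, max_r2_patches, n_events, n_colonized).
    """
    np.random.seed(seed)
    G = state.shape[0]
    cy = G // 2
    cx = G // 2
    cap = G * G
    stop_r2 = stop_r_p * stop_r_p

    slot = np.full((G, G), -1, dtype=np.int64)
    eligible = np.zeros((G, G), dtype=np.uint8)
    act_idx = np.empty(cap, dtype=np.int64)
    act_nopen = np.empty(cap, dtype=np.int64)
    act_prop = np.empty(cap, dtype=np.float64)
    n_act = 0
    R_col = 0.0

    heap_t = np.empty(cap, dtype=np.float64)
    heap_i = np.empty(cap, dtype=np.int64)
    n_heap = 0

    lys_list = np.empty(cap, dtype=np.int64)
    lys_pos = np.full((G, G), -1, dtype=np.int64)
    nlys = 0

    t = 0.0
    max_r2 = 0.0
    n_col = 0

    # initial scan: classify seeded patches
    for i in range(G):
        for j in range(G):
            st = state[i, j]
            if st >= 1:
                n_col += 1
                di = float(i - cy)
                dj = float(j - cx)
                r2 = di * di + dj * dj
                if r2 > max_r2:
                    max_r2 = r2
            if 1 <= st <= 3:
                if act_time[i, j] <= t:
                    eligible[i, j] = 1
                    no = _count_open(state, i, j, st, lysed_recol)
                    if no > 0:
                        slot[i, j] = n_act
                        act_idx[n_act] = i * G + j
                        act_nopen[n_act] = no
                        p = mu[st] * no / 8.0
                        act_prop[n_act] = p
                        R_col += p
                        n_act += 1
                else:
                    n_heap = _heap_push(heap_t, heap_i, n_heap, act_time[i, j], i * G + j)
                if st == 1 and lyse_on and conc[i, j] >= thr:
                    lys_pos[i, j] = nlys
                    lys_list[nlys] = i * G + j
                    nlys += 1

    rec_i = 0
    nrec = record_times.shape[0]
    ev = 0
    reason = REASON_STALLED

    while True:
        if max_r2 >= stop_r2:
            reason = REASON_RADIUS
            break
        nxt = heap_t[0] if n_heap > 0 else math.inf
        tot = R_col + nlys * lysis_rate
        if tot <= 1e-300:
            if n_heap == 0:
                reason = REASON_STALLED
                break
            if nxt > stop_time:
                t = stop_time
                reason = REASON_TIME
                break
            t = nxt
            while rec_i < nrec and record_times[rec_i] <= t:
                record_area[rec_i] = n_col
                rec_i += 1
            _, fidx, n_heap = _heap_pop(heap_t, heap_i, n_heap)
            i = fidx // G
            j = fidx % G
            st = state[i, j]
            if 1 <= st <= 3 and eligible[i, j] == 0:
                eligible[i, j] = 1
                no = _count_open(state, i, j, st, lysed_recol)
                if no > 0:
                    slot[i, j] = n_act
                    act_idx[n_act] = fidx
                    act_nopen[n_act] = no
                    p = mu[st] * no / 8.0
                    act_prop[n_act] = p
                    R_col += p
                    n_act += 1
            continue

        dt = -math.log(np.random.random()) / tot
        tn = t + dt
        if tn >= nxt:
            # lag expiry barrier: advance clock, activate, redraw
            t = nxt
            if t > stop_time:
                t = stop_time
                reason = REASON_TIME
                break
            while rec_i < nrec and record_times[rec_i] <= t:
                record_area[rec_i] = n_col
                rec_i += 1
            _, fidx, n_heap = _heap_pop(heap_t, heap_i, n_heap)
            i = fidx // G
            j = fidx % G
            st = state[i, j]
            if 1 <= st <= 3 and eligible[i, j] == 0:
                eligible[i, j] = 1
                no = _count_open(state, i, j, st, lysed_recol)
                if no > 0:
                    slot[i, j] = n_act
                    act_idx[n_act] = fidx
                    act_nopen[n_act] = no
                    p = mu[st] * no / 8.0
                    act_prop[n_act] = p
                    R_col += p
                    n_act += 1
            continue
        if tn > stop_time:
            t = stop_time
            reason = REASON_TIME
            break
        t = tn
        while rec_i < nrec and record_times[rec_i] <= t:
            record_area[rec_i] = n_col
            rec_i += 1

        ev += 1
        if ev >= max_events:
            reason = REASON_MAX_EVENTS
            break
        if ev % 8192 == 0:
            # drift control: rebuild propensities from counts
            R_col = 0.0
            for a in range(n_act):
                fidx = act_idx[a]
                sa = state[fidx // G, fidx % G]
                p = mu[sa] * act_nopen[a] / 8.0
                act_prop[a] = p
                R_col += p

        x = np.random.random() * tot
        lys_tot = nlys * lysis_rate
        if x < lys_tot:
            # --- lysis of an inhibited S patch ---
            k = int(x / lysis_rate)
            if k >= nlys:
                k = nlys - 1
            fidx = lys_list[k]
            i = fidx // G
            j = fidx % G
            state[i, j] = 4
            eligible[i, j] = 0
            nlys -= 1
            lys_list[k] = lys_list[nlys]
            lys_pos[lys_list[k] // G, lys_list[k] % G] = k
            lys_pos[i, j] = -1
            a = slot[i, j]
            if a >= 0:
                R_col -= act_prop[a]
                n_act -= 1
                act_idx[a] = act_idx[n_act]
                act_nopen[a] = act_nopen[n_act]
                act_prop[a] = act_prop[n_act]
                slot[act_idx[a] // G, act_idx[a] % G] = a
                slot[i, j] = -1
            if lysed_recol:
                # cleared ground opens up for R and C neighbours
                for k2 in range(8):
                    ii = i + _NBI[k2]
                    jj = j + _NBJ[k2]
                    if 0 <= ii < G and 0 <= jj < G:
                        sn = state[ii, jj]
                        if sn == 2 or sn == 3:
                            a2 = slot[ii, jj]
                            if a2 >= 0:
                                act_nopen[a2] += 1
                                dp = mu[sn] / 8.0
                                act_prop[a2] += dp
                                R_col += dp
                            elif eligible[ii, jj] == 1:
                                no = _count_open(state, ii, jj, sn, lysed_recol)
                                if no > 0:
                                    slot[ii, jj] = n_act
                                    act_idx[n_act] = ii * G + jj
                                    act_nopen[n_act] = no
                                    p = mu[sn] * no / 8.0
                                    act_prop[n_act] = p
                                    R_col += p
                                    n_act += 1
        else:
            # --- colonization attempt ---
            x -= lys_tot
            acc = 0.0
            sel = -1
            for a in range(n_act):
                acc += act_prop[a]
                if x < acc:
                    sel = a
                    break
            if sel < 0:
                if n_act == 0:
                    continue
                sel = n_act - 1
            fidx = act_idx[sel]
            i = fidx // G
            j = fidx % G
            s = state[i, j]
            # gather open neighbours (must agree with act_nopen bookkeeping)
            m = 0
            opens = np.empty(8, dtype=np.int64)
            for k in range(8):
                ii = i + _NBI[k]
                jj = j + _NBJ[k]
                if 0 <= ii < G and 0 <= jj < G:
                    st2 = state[ii, jj]
                    if st2 == 0 or (st2 == 4 and lysed_recol and s != 1):
                        opens[m] = k
                        m += 1
            if m == 0:
                # stale entry: repair by removal
                R_col -= act_prop[sel]
                n_act -= 1
                act_idx[sel] = act_idx[n_act]
                act_nopen[sel] = act_nopen[n_act]
                act_prop[sel] = act_prop[n_act]
                slot[act_idx[sel] // G, act_idx[sel] % G] = sel
                slot[i, j] = -1
                continue
            kk = int(np.random.random() * m)
            if kk >= m:
                kk = m - 1
            k = opens[kk]
            ti = i + _NBI[k]
            tj = j + _NBJ[k]
            if s == 1 and conc[ti, tj] >= thr:
                continue  # thinned: S blocked by colicin, clock consumed
            was = state[ti, tj]
            state[ti, tj] = s
            col_time[ti, tj] = t
            if was == 0:
                n_col += 1
            di = float(ti - cy)
            dj = float(tj - cx)
            r2 = di * di + dj * dj
            if r2 > max_r2:
                max_r2 = r2
            # the claimed patch stops being open for its colonized neighbours
            for k2 in range(8):
                ii = ti + _NBI[k2]
                jj = tj + _NBJ[k2]
                if 0 <= ii < G and 0 <= jj < G:
                    a2 = slot[ii, jj]
                    if a2 >= 0:
                        sn = state[ii, jj]
                        counted = (was == 0) or (was == 4 and lysed_recol and sn != 1)
                        if counted:
                            act_nopen[a2] -= 1
                            dp = mu[sn] / 8.0
                            act_prop[a2] -= dp
                            R_col -= dp
                            if act_nopen[a2] <= 0:
                                R_col -= act_prop[a2]  # clear residual
                                act_prop[a2] = 0.0
                                n_act -= 1
                                act_idx[a2] = act_idx[n_act]
                                act_nopen[a2] = act_nopen[n_act]
                                act_prop[a2] = act_prop[n_act]
                                slot[act_idx[a2] // G, act_idx[a2] % G] = a2
                                slot[ii, jj] = -1
            # lag of the newly colonized patch
            al = new_lag[s]
            if al > 0.0:
                act_time[ti, tj] = t + al
                n_heap = _heap_push(heap_t, heap_i, n_heap, t + al, ti * G + tj)
            else:
                act_time[ti, tj] = t
                eligible[ti, tj] = 1
                no = _count_open(state, ti, tj, s, lysed_recol)
                if no > 0:
                    slot[ti, tj] = n_act
                    act_idx[n_act] = ti * G + tj
                    act_nopen[n_act] = no
                    p = mu[s] * no / 8.0
                    act_prop[n_act] = p
                    R_col += p
                    n_act += 1
            # toxic-site draw for C colonizations
            if s == 3 and p_tox > 0.0:
                if np.random.random() < p_tox:
                    toxic[ti, tj] = 1
                    if kappa > 0.0:
                        nlys = add_source_kernel(conc, state, ti, tj, kappa,
                                                 lam_p, cutoff_p, thr,
                                                 lys_list, lys_pos, nlys,
                                                 lyse_on)

    for a in range(rec_i, nrec):
        record_area[a] = n_col
    return t, reason, max_r2, ev, n_col
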