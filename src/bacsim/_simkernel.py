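"""Compiled event loop and sequence-evolution pass.

The backward-in-time coalescent/gene-conversion loop and the tip-ward
Jukes-Cantor pass are compiled whole; the surrounding package converts the
flat array outputs into the ARG/event/tree objects of the public API.  The
rejection-sampling oracle deliberately does not use this path: it exercises
the pure-Python event semantics, so the two simulators share no code beyond
the interval kernels.

Node kinds: 0 leaf, 1 coalescence, 2 recombination split, 3 external
import.  Child-port roles: 0 none, 1 donor, 2 recipient.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numba.typed import List as NList

from ._kernels import (counts_decrement_singles, counts_zero, iv_difference,
                       iv_intersect, iv_union, sample_external_k,
                       sample_within_k, weight_external, weight_within)

KIND_LEAF, KIND_COAL, KIND_SPLIT, KIND_EXT = 0, 1, 2, 3
ROLE_NONE, ROLE_DONOR, ROLE_RECIP = 0, 1, 2


@njit(cache=True)
def _grow(arr, newcap):
    out = np.empty(newcap, arr.dtype)
    out[:arr.size] = arr
    return out


@njit(cache=True)
def sim_loop(G, circular, mat0, n, rho_i, delta_i, rho_e, delta_e,
             dmin, dmax, seed, max_events, record_materials):
    """Run the full backward simulation; returns flat arrays.

    Output tuple:
      nd_kind, nd_time, nd_clonal, nd_c1, nd_r1, nd_c2, nd_r2, nd_div,
      nd_toff, nd_tlen, tpool            (per-node tract, boundary pairs)
      nd_moff, nd_mlen, mpool            (per-node material snapshot)
      mr_node, mr_s, mr_e                (MRCA records, per resolved run)
      ev_node, ev_rawlen                 (event nodes in chronological order)
      cf_t, cf_a, cf_b                   (clonal-frame joins)
      root_node, root_cf, ok
    """
    np.random.seed(seed)
    q_i = 1.0 - 1.0 / delta_i
    q_e = 1.0 - 1.0 / delta_e

    counts = np.zeros(G, dtype=np.int32)
    for ii in range(0, mat0.size, 2):
        for x in range(mat0[ii], mat0[ii + 1]):
            counts[x] = n

    # lineage state (parallel arrays + typed list of materials)
    cap = 256
    lin_node = np.empty(cap, np.int64)
    lin_role = np.empty(cap, np.int8)
    lin_clonal = np.empty(cap, np.bool_)
    lin_win = np.zeros(cap, np.float64)
    lin_wex = np.zeros(cap, np.float64)
    lin_cf = np.empty(cap, np.int64)
    mats = NList()

    # node output
    ncap = 1024
    nd_kind = np.empty(ncap, np.int8)
    nd_time = np.empty(ncap, np.float64)
    nd_clonal = np.empty(ncap, np.bool_)
    nd_c1 = np.full(ncap, -1, np.int64)
    nd_r1 = np.zeros(ncap, np.int8)
    nd_c2 = np.full(ncap, -1, np.int64)
    nd_r2 = np.zeros(ncap, np.int8)
    nd_div = np.full(ncap, np.nan, np.float64)
    nd_toff = np.full(ncap, -1, np.int64)
    nd_tlen = np.zeros(ncap, np.int64)
    nd_moff = np.full(ncap, -1, np.int64)
    nd_mlen = np.zeros(ncap, np.int64)
    n_nodes = 0

    tcap = 1024
    tpool = np.empty(tcap, np.int64)
    n_t = 0
    mcap = 4096
    mpool = np.empty(mcap, np.int64)
    n_m = 0

    mrcap = 1024
    mr_node = np.empty(mrcap, np.int64)
    mr_s = np.empty(mrcap, np.int64)
    mr_e = np.empty(mrcap, np.int64)
    n_mr = 0

    ecap = 1024
    ev_node = np.empty(ecap, np.int64)
    ev_rawlen = np.empty(ecap, np.int64)
    n_ev = 0

    ccap = 256
    cf_t = np.empty(ccap, np.float64)
    cf_a = np.empty(ccap, np.int64)
    cf_b = np.empty(ccap, np.int64)
    n_cf = 0

    sum_w = 0.0
    sum_e = 0.0
    use_w = rho_i > 0.0
    use_e = rho_e > 0.0

    # leaves
    k = 0
    for i in range(n):
        nd_kind[n_nodes] = KIND_LEAF
        nd_time[n_nodes] = 0.0
        nd_clonal[n_nodes] = True
        if record_materials:
            while n_m + mat0.size > mcap:
                mcap *= 2
                mpool = _grow(mpool, mcap)
            mpool[n_m:n_m + mat0.size] = mat0
            nd_moff[n_nodes] = n_m
            nd_mlen[n_nodes] = mat0.size
            n_m += mat0.size
        lin_node[k] = n_nodes
        lin_role[k] = ROLE_NONE
        lin_clonal[k] = True
        lin_cf[k] = i
        mats.append(mat0.copy())
        w = 0.5 * rho_i * weight_within(mat0, G, circular, q_i) \
            if use_w else 0.0
        lin_win[k] = w
        sum_w += w
        w = 0.5 * rho_e * weight_external(mat0, G, circular, q_e) \
            if use_e else 0.0
        lin_wex[k] = w
        sum_e += w
        k += 1
        n_nodes += 1

    t = 0.0
    n_iter = 0
    ok = True
    while k > 1:
        if n_ev > max_events:
            ok = False
            break
        n_iter += 1
        if n_iter % 4096 == 0:
            sum_w = 0.0
            sum_e = 0.0
            for i in range(k):
                sum_w += lin_win[i]
                sum_e += lin_wex[i]
        # capacity: each iteration adds at most one node / event / cf join
        if n_nodes + 1 > ncap:
            ncap *= 2
            nd_kind = _grow(nd_kind, ncap)
            nd_time = _grow(nd_time, ncap)
            nd_clonal = _grow(nd_clonal, ncap)
            c1 = np.full(ncap, -1, np.int64)
            c1[:n_nodes] = nd_c1[:n_nodes]
            nd_c1 = c1
            nd_r1 = _grow(nd_r1, ncap)
            c2 = np.full(ncap, -1, np.int64)
            c2[:n_nodes] = nd_c2[:n_nodes]
            nd_c2 = c2
            nd_r2 = _grow(nd_r2, ncap)
            nd_div = _grow(nd_div, ncap)
            to = np.full(ncap, -1, np.int64)
            to[:n_nodes] = nd_toff[:n_nodes]
            nd_toff = to
            nd_tlen = _grow(nd_tlen, ncap)
            mo = np.full(ncap, -1, np.int64)
            mo[:n_nodes] = nd_moff[:n_nodes]
            nd_moff = mo
            nd_mlen = _grow(nd_mlen, ncap)
        if k + 1 > cap:
            cap *= 2
            lin_node = _grow(lin_node, cap)
            lin_role = _grow(lin_role, cap)
            lin_clonal = _grow(lin_clonal, cap)
            lin_win = _grow(lin_win, cap)
            lin_wex = _grow(lin_wex, cap)
            lin_cf = _grow(lin_cf, cap)

        c_rate = k * (k - 1) / 2.0
        w_total = sum_w if sum_w > 0.0 else 0.0
        e_total = sum_e if sum_e > 0.0 else 0.0
        total = c_rate + w_total + e_total
        t += np.random.exponential(1.0 / total)
        u = np.random.random() * total

        if u < c_rate:
            # ----- coalescence ------------------------------------------
            i = np.random.randint(0, k)
            j = np.random.randint(0, k - 1)
            if j >= i:
                j += 1
            if i > j:
                i, j = j, i
            sum_w -= lin_win[i] + lin_win[j]
            sum_e -= lin_wex[i] + lin_wex[j]
            inter = iv_intersect(mats[i], mats[j])
            mat = iv_union(mats[i], mats[j])
            clonal = lin_clonal[i] or lin_clonal[j]
            nid = n_nodes
            nd_kind[nid] = KIND_COAL
            nd_time[nid] = t
            nd_clonal[nid] = clonal
            nd_c1[nid] = lin_node[i]
            nd_r1[nid] = lin_role[i]
            nd_c2[nid] = lin_node[j]
            nd_r2[nid] = lin_role[j]
            n_nodes += 1
            if inter.size > 0:
                prune = counts_decrement_singles(counts, inter)
                if prune.size > 0:
                    npairs = prune.size // 2
                    while n_mr + npairs > mrcap:
                        mrcap *= 2
                        mr_node = _grow(mr_node, mrcap)
                        mr_s = _grow(mr_s, mrcap)
                        mr_e = _grow(mr_e, mrcap)
                    for ii in range(npairs):
                        mr_node[n_mr] = nid
                        mr_s[n_mr] = prune[2 * ii]
                        mr_e[n_mr] = prune[2 * ii + 1]
                        n_mr += 1
                    mat = iv_difference(mat, prune)
                    counts_zero(counts, prune)
            if record_materials:
                while n_m + mat.size > mcap:
                    mcap *= 2
                    mpool = _grow(mpool, mcap)
                mpool[n_m:n_m + mat.size] = mat
                nd_moff[nid] = n_m
                nd_mlen[nid] = mat.size
                n_m += mat.size
            if lin_clonal[i] and lin_clonal[j]:
                if n_cf + 1 > ccap:
                    ccap *= 2
                    cf_t = _grow(cf_t, ccap)
                    cf_a = _grow(cf_a, ccap)
                    cf_b = _grow(cf_b, ccap)
                cf_t[n_cf] = t
                cf_a[n_cf] = lin_cf[i]
                cf_b[n_cf] = lin_cf[j]
                new_cf = n + n_cf
                n_cf += 1
            else:
                new_cf = lin_cf[i] if lin_clonal[i] else lin_cf[j]
            # remove j then i (swap-with-last)
            for idx in (j, i):
                last = k - 1
                lin_node[idx] = lin_node[last]
                lin_role[idx] = lin_role[last]
                lin_clonal[idx] = lin_clonal[last]
                lin_win[idx] = lin_win[last]
                lin_wex[idx] = lin_wex[last]
                lin_cf[idx] = lin_cf[last]
                mats[idx] = mats[last]
                mats.pop()
                k -= 1
            if clonal or mat.size > 0:
                lin_node[k] = nid
                lin_role[k] = ROLE_NONE
                lin_clonal[k] = clonal
                lin_cf[k] = new_cf
                mats.append(mat)
                w = 0.5 * rho_i * weight_within(mat, G, circular, q_i) \
                    if use_w and mat.size > 0 else 0.0
                lin_win[k] = w
                sum_w += w
                w = 0.5 * rho_e * weight_external(mat, G, circular, q_e) \
                    if use_e and mat.size > 0 else 0.0
                lin_wex[k] = w
                sum_e += w
                k += 1
            continue

        if u < c_rate + w_total:
            # ----- within-species recombination -------------------------
            r = u - c_rate
            idx = 0
            last_pos = -1
            while idx < k:
                w = lin_win[idx]
                if w > 0.0:
                    last_pos = idx
                    if r <= w:
                        break
                    r -= w
                idx += 1
            if last_pos < 0:
                sum_w = 0.0
                sum_e = 0.0
                for i in range(k):
                    sum_w += lin_win[i]
                    sum_e += lin_wex[i]
                continue
            if idx >= k:
                idx = last_pos
            mat = mats[idx]
            s, l = sample_within_k(mat, G, circular, q_i,
                                   np.random.random(), np.random.random(),
                                   np.random.random())
            l_fp = l if l < G or not circular else G
            if circular and s + l_fp > G:
                tract = np.empty(4, np.int64)
                tract[0] = 0
                tract[1] = s + l_fp - G
                tract[2] = s
                tract[3] = G
            else:
                e_ = s + l_fp if s + l_fp < G else G
                tract = np.empty(2, np.int64)
                tract[0] = s
                tract[1] = e_
            donor_mat = iv_intersect(mat, tract)
            recip_mat = iv_difference(mat, tract)
            nid = n_nodes
            nd_kind[nid] = KIND_SPLIT
            nd_time[nid] = t
            nd_clonal[nid] = lin_clonal[idx]
            nd_c1[nid] = lin_node[idx]
            nd_r1[nid] = lin_role[idx]
            while n_t + tract.size > tcap:
                tcap *= 2
                tpool = _grow(tpool, tcap)
            tpool[n_t:n_t + tract.size] = tract
            nd_toff[nid] = n_t
            nd_tlen[nid] = tract.size
            n_t += tract.size
            if record_materials:
                # pre-split material; donor/recipient derive from the tract
                while n_m + mat.size > mcap:
                    mcap *= 2
                    mpool = _grow(mpool, mcap)
                mpool[n_m:n_m + mat.size] = mat
                nd_moff[nid] = n_m
                nd_mlen[nid] = mat.size
                n_m += mat.size
            n_nodes += 1
            if n_ev + 1 > ecap:
                ecap *= 2
                ev_node = _grow(ev_node, ecap)
                ev_rawlen = _grow(ev_rawlen, ecap)
            ev_node[n_ev] = nid
            ev_rawlen[n_ev] = l
            n_ev += 1
            # recipient keeps the slot
            lin_node[idx] = nid
            lin_role[idx] = ROLE_RECIP
            mats[idx] = recip_mat
            w = 0.5 * rho_i * weight_within(recip_mat, G, circular, q_i)
            sum_w += w - lin_win[idx]
            lin_win[idx] = w
            if use_e:
                w = 0.5 * rho_e * weight_external(recip_mat, G, circular, q_e)
                sum_e += w - lin_wex[idx]
                lin_wex[idx] = w
            # donor lineage appended
            lin_node[k] = nid
            lin_role[k] = ROLE_DONOR
            lin_clonal[k] = False
            lin_cf[k] = -1
            mats.append(donor_mat)
            w = 0.5 * rho_i * weight_within(donor_mat, G, circular, q_i)
            lin_win[k] = w
            sum_w += w
            w = 0.5 * rho_e * weight_external(donor_mat, G, circular, q_e) \
                if use_e else 0.0
            lin_wex[k] = w
            sum_e += w
            k += 1
            continue

        # ----- between-species import -----------------------------------
        r = u - c_rate - w_total
        idx = 0
        last_pos = -1
        while idx < k:
            w = lin_wex[idx]
            if w > 0.0:
                last_pos = idx
                if r <= w:
                    break
                r -= w
            idx += 1
        if last_pos < 0:
            sum_w = 0.0
            sum_e = 0.0
            for i in range(k):
                sum_w += lin_win[i]
                sum_e += lin_wex[i]
            continue
        if idx >= k:
            idx = last_pos
        mat = mats[idx]
        s, l = sample_external_k(mat, G, circular, q_e,
                                 np.random.random(), np.random.random(),
                                 np.random.random())
        l_fp = l
        if circular and l_fp > G:
            l_fp = G
        if circular and l_fp == G:
            tract = np.empty(2, np.int64)
            tract[0] = 0
            tract[1] = G
        elif circular and s + l_fp > G:
            tract = np.empty(4, np.int64)
            tract[0] = 0
            tract[1] = s + l_fp - G
            tract[2] = s
            tract[3] = G
        else:
            e_ = s + l_fp if s + l_fp < G else G
            tract = np.empty(2, np.int64)
            tract[0] = s
            tract[1] = e_
        removed = iv_intersect(mat, tract)
        d = dmin + (dmax - dmin) * np.random.random()
        newmat = iv_difference(mat, removed)
        nid = n_nodes
        nd_kind[nid] = KIND_EXT
        nd_time[nid] = t
        nd_clonal[nid] = lin_clonal[idx]
        nd_c1[nid] = lin_node[idx]
        nd_r1[nid] = lin_role[idx]
        nd_div[nid] = d
        while n_t + tract.size > tcap:
            tcap *= 2
            tpool = _grow(tpool, tcap)
        tpool[n_t:n_t + tract.size] = tract
        nd_toff[nid] = n_t
        nd_tlen[nid] = tract.size
        n_t += tract.size
        if record_materials:
            while n_m + newmat.size > mcap:
                mcap *= 2
                mpool = _grow(mpool, mcap)
            mpool[n_m:n_m + newmat.size] = newmat
            nd_moff[nid] = n_m
            nd_mlen[nid] = newmat.size
            n_m += newmat.size
        n_nodes += 1
        if n_ev + 1 > ecap:
            ecap *= 2
            ev_node = _grow(ev_node, ecap)
            ev_rawlen = _grow(ev_rawlen, ecap)
        ev_node[n_ev] = nid
        ev_rawlen[n_ev] = l
        n_ev += 1
        lin_node[idx] = nid
        lin_role[idx] = ROLE_NONE
        mats[idx] = newmat
        if use_w:
            w = 0.5 * rho_i * weight_within(newmat, G, circular, q_i) \
                if newmat.size > 0 else 0.0
            sum_w += w - lin_win[idx]
            lin_win[idx] = w
        w = 0.5 * rho_e * weight_external(newmat, G, circular, q_e) \
            if newmat.size > 0 else 0.0
        sum_e += w - lin_wex[idx]
        lin_wex[idx] = w
        # pruning: freshly resolved runs move their MRCA anchor to the
        # remaining carrier's current node
        prune = counts_decrement_singles(counts, removed)
        if prune.size > 0:
            drop_any = False
            for li in range(k):
                if li == idx:
                    continue
                inter = iv_intersect(mats[li], prune)
                if inter.size > 0:
                    npairs = inter.size // 2
                    while n_mr + npairs > mrcap:
                        mrcap *= 2
                        mr_node = _grow(mr_node, mrcap)
                        mr_s = _grow(mr_s, mrcap)
                        mr_e = _grow(mr_e, mrcap)
                    for ii in range(npairs):
                        mr_node[n_mr] = lin_node[li]
                        mr_s[n_mr] = inter[2 * ii]
                        mr_e[n_mr] = inter[2 * ii + 1]
                        n_mr += 1
                    mats[li] = iv_difference(mats[li], inter)
                    if use_w:
                        w = 0.5 * rho_i * weight_within(
                            mats[li], G, circular, q_i) \
                            if mats[li].size > 0 else 0.0
                        sum_w += w - lin_win[li]
                        lin_win[li] = w
                    w = 0.5 * rho_e * weight_external(
                        mats[li], G, circular, q_e) \
                        if use_e and mats[li].size > 0 else 0.0
                    sum_e += w - lin_wex[li]
                    lin_wex[li] = w
                    if mats[li].size == 0 and not lin_clonal[li]:
                        drop_any = True
            counts_zero(counts, prune)
        # sweep out empty non-clonal lineages (the recipient included);
        # swap-with-last keeps indices dense
        li = 0
        while li < k:
            if mats[li].size == 0 and not lin_clonal[li]:
                last = k - 1
                sum_w -= lin_win[li]
                sum_e -= lin_wex[li]
                lin_node[li] = lin_node[last]
                lin_role[li] = lin_role[last]
                lin_clonal[li] = lin_clonal[last]
                lin_win[li] = lin_win[last]
                lin_wex[li] = lin_wex[last]
                lin_cf[li] = lin_cf[last]
                mats[li] = mats[last]
                mats.pop()
                k -= 1
            else:
                li += 1

    root_node = lin_node[0]
    root_cf = lin_cf[0]
    return (nd_kind[:n_nodes].copy(), nd_time[:n_nodes].copy(),
            nd_clonal[:n_nodes].copy(), nd_c1[:n_nodes].copy(),
            nd_r1[:n_nodes].copy(), nd_c2[:n_nodes].copy(),
            nd_r2[:n_nodes].copy(), nd_div[:n_nodes].copy(),
            nd_toff[:n_nodes].copy(), nd_tlen[:n_nodes].copy(),
            tpool[:n_t].copy(),
            nd_moff[:n_nodes].copy(), nd_mlen[:n_nodes].copy(),
            mpool[:n_m].copy(),
            mr_node[:n_mr].copy(), mr_s[:n_mr].copy(), mr_e[:n_mr].copy(),
            ev_node[:n_ev].copy(), ev_rawlen[:n_ev].copy(),
            cf_t[:n_cf].copy(), cf_a[:n_cf].copy(), cf_b[:n_cf].copy(),
            root_node, root_cf, ok)


@njit(cache=True)
def count_buffers(n_nodes, nd_kind, nd_c1, nd_r1, nd_c2, nd_r2):
    """Peak number of concurrently live sequence buffers in align_loop,
    by replaying its acquire/release pattern without any sequence data."""
    has_a = np.zeros(n_nodes, np.bool_)
    has_b = np.zeros(n_nodes, np.bool_)
    live = 0
    peak = 0
    for nid in range(n_nodes - 1, -1, -1):
        kind = nd_kind[nid]
        if not has_a[nid]:
            live += 1            # root-filled fresh buffer
            if live > peak:
                peak = live
        if kind == KIND_SPLIT and has_b[nid]:
            live -= 1            # donor buffer freed after splice
        if kind == KIND_LEAF:
            live -= 1
            continue
        if nd_c2[nid] >= 0:
            live += 1            # copy for the non-last child
            if live > peak:
                peak = live
        for ci in range(2):
            child = nd_c1[nid] if ci == 0 else nd_c2[nid]
            if child < 0:
                continue
            role = nd_r1[nid] if ci == 0 else nd_r2[nid]
            if role == ROLE_DONOR:
                has_b[child] = True
            else:
                has_a[child] = True
    return peak


@njit(cache=True)
def align_loop(n, L, col_map,
               nd_kind, nd_time, nd_c1, nd_r1, nd_c2, nd_r2, nd_div,
               nd_toff, nd_tlen, tpool,
               mr_off, mr_bounds,
               pool8, pool64, root8, root64, out8, out64,
               theta, seed):
    """Tip-ward Jukes-Cantor pass over the flat ARG arrays.

    ``col_map[site]`` is the alignment column of a genome site (-1 for gap
    sites); ``mr_off``/``mr_bounds`` give each node's MRCA runs in CSR form.
    Buffers are byte arrays with 64-bit aliases for fast whole-row copies;
    leaf rows are written into ``out8`` (bases coded 0..3).
    """
    np.random.seed(seed)
    n_nodes = nd_kind.size
    L8 = pool64.shape[1]
    cap = pool8.shape[0]
    free_stack = np.empty(cap, np.int64)
    n_free = 0
    n_rows = 0
    slot_a = np.full(n_nodes, -1, np.int64)   # role none/recipient
    slot_b = np.full(n_nodes, -1, np.int64)   # role donor

    for nid in range(n_nodes - 1, -1, -1):
        kind = nd_kind[nid]
        # --- acquire/assemble this node's row ---------------------------
        bi = slot_a[nid]
        if bi < 0:
            if n_free > 0:
                n_free -= 1
                bi = free_stack[n_free]
            else:
                bi = n_rows
                n_rows += 1
            for w in range(L8):
                pool64[bi, w] = root64[w]
        if kind == KIND_SPLIT:
            donor_bi = slot_b[nid]
            to, tl = nd_toff[nid], nd_tlen[nid]
            if donor_bi >= 0:
                for ii in range(0, tl, 2):
                    for x in range(tpool[to + ii], tpool[to + ii + 1]):
                        c = col_map[x]
                        if c >= 0:
                            pool8[bi, c] = pool8[donor_bi, c]
                free_stack[n_free] = donor_bi
                n_free += 1
            else:
                for ii in range(0, tl, 2):
                    for x in range(tpool[to + ii], tpool[to + ii + 1]):
                        c = col_map[x]
                        if c >= 0:
                            pool8[bi, c] = root8[c]
        elif kind == KIND_EXT:
            d = nd_div[nid]
            to, tl = nd_toff[nid], nd_tlen[nid]
            for ii in range(0, tl, 2):
                for x in range(tpool[to + ii], tpool[to + ii + 1]):
                    c = col_map[x]
                    if c >= 0:
                        base = root8[c]
                        if np.random.random() < d:
                            base = (base + 1 + np.random.randint(0, 3)) & 3
                        pool8[bi, c] = base
        # MRCA overwrites
        for mi in range(mr_off[nid], mr_off[nid + 1]):
            for x in range(mr_bounds[2 * mi], mr_bounds[2 * mi + 1]):
                c = col_map[x]
                if c >= 0:
                    pool8[bi, c] = root8[c]
        if kind == KIND_LEAF:
            for w in range(L8):
                out64[nid, w] = pool64[bi, w]
            free_stack[n_free] = bi
            n_free += 1
            continue
        # --- deliver to children ----------------------------------------
        n_children = 1 if nd_c2[nid] < 0 else 2
        for ci in range(n_children):
            child = nd_c1[nid] if ci == 0 else nd_c2[nid]
            role = nd_r1[nid] if ci == 0 else nd_r2[nid]
            if ci == n_children - 1:
                obi = bi
            else:
                if n_free > 0:
                    n_free -= 1
                    obi = free_stack[n_free]
                else:
                    obi = n_rows
                    n_rows += 1
                for w in range(L8):
                    pool64[obi, w] = pool64[bi, w]
            blen = nd_time[nid] - nd_time[child]
            nm = np.random.poisson(0.5 * theta * blen * L)
            for _ in range(nm):
                x = np.random.randint(0, L)
                pool8[obi, x] = (pool8[obi, x] + 1 +
                                 np.random.randint(0, 3)) & 3
            if role == ROLE_DONOR:
                slot_b[child] = obi
            else:
                slot_a[child] = obi
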