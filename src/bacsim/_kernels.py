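"""Compiled kernels for interval algebra, effective-rate closed forms,
tract sampling and carrier-count bookkeeping.

Interval sets are boundary arrays ``int64 [s1, e1, s2, e2, ...]`` in
canonical form (sorted, disjoint, non-adjacent).  The closed forms follow
from the geometric tract-length tail ``P(l >= k) = q**(k-1)`` with
``q = 1 - 1/delta``: for a tract starting at ``s`` the effective lengths
form one contiguous range, so each start contributes a difference of two
tails, and runs of starts sum to geometric series evaluated per material
interval and per gap.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "iv_union", "iv_intersect", "iv_difference",
    "weight_within", "weight_external",
    "sample_within_k", "sample_external_k",
    "counts_decrement_singles", "counts_zero", "counts_add",
]


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

@njit(cache=True)
def iv_union(a, b):
    na, nb = a.size, b.size
    out = np.empty(na + nb, np.int64)
    m = 0
    i = j = 0
    cur_s = np.int64(0)
    cur_e = np.int64(-1)
    while i < na or j < nb:
        if j >= nb or (i < na and a[i] <= b[j]):
            s, e = a[i], a[i + 1]
            i += 2
        else:
            s, e = b[j], b[j + 1]
            j += 2
        if cur_e < 0:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            if e > cur_e:
                cur_e = e
        else:
            out[m] = cur_s
            out[m + 1] = cur_e
            m += 2
            cur_s, cur_e = s, e
    if cur_e >= 0:
        out[m] = cur_s
        out[m + 1] = cur_e
        m += 2
    return out[:m].copy()


@njit(cache=True)
def iv_intersect(a, b):
    na, nb = a.size, b.size
    out = np.empty(na + nb, np.int64)
    m = 0
    i = j = 0
    while i < na and j < nb:
        lo = a[i] if a[i] > b[j] else b[j]
        hi = a[i + 1] if a[i + 1] < b[j + 1] else b[j + 1]
        if lo < hi:
            out[m] = lo
            out[m + 1] = hi
            m += 2
        if a[i + 1] <= b[j + 1]:
            i += 2
        else:
            j += 2
    return out[:m].copy()


@njit(cache=True)
def iv_difference(a, b):
    na, nb = a.size, b.size
    out = np.empty(na + nb + 2, np.int64)
    m = 0
    j = 0
    for ii in range(0, na, 2):
        s, e = a[ii], a[ii + 1]
        cur = s
        while j < nb and b[j + 1] <= cur:
            j += 2
        jj = j
        while jj < nb and b[jj] < e:
            bs, be = b[jj], b[jj + 1]
            if bs > cur:
                out[m] = cur
                out[m + 1] = bs
                m += 2
            if be > cur:
                cur = be
            if be >= e:
                break
            jj += 2
        if cur < e:
            out[m] = cur
            out[m + 1] = e
            m += 2
    return out[:m].copy()


# ---------------------------------------------------------------------------
# effective-rate closed forms (sum over starts of tail differences)
# ---------------------------------------------------------------------------

@njit(cache=True)
def weight_within(b, G, circular, q):
    """sum_s P(tract starting at s bipartitions the material)."""
    k = b.size // 2
    if k == 0:
        return 0.0
    m = np.int64(0)
    for i in range(k):
        m += b[2 * i + 1] - b[2 * i]
    if circular:
        if k == 1 and b[0] == 0 and b[1] == G:
            return G * (1.0 - q ** (G - 1))
        W = 0.0
        w_int = 1.0 - q ** (G - 1)
        for i in range(k):
            a, e = b[2 * i], b[2 * i + 1]
            pe = b[2 * ((i - 1) % k) + 1]
            l_prev = (a - pe) % G
            W += 1.0 - q ** (G - 1 - l_prev)
            W += (e - a - 1) * w_int
            nxt = b[2 * ((i + 1) % k)]
            l_gap = (nxt - e) % G
            if l_gap > 0 and q > 0.0:
                W += (1.0 - q ** l_gap) * (q - q ** (G - l_gap)) / (1.0 - q)
        return W
    a0 = b[0]
    m_last = b[2 * k - 1] - 1
    W = float(m - 1)
    w0 = 1.0 - q ** (m_last - a0)
    W += w0 * (1.0 - q ** (a0 + 1)) / (1.0 - q) if q > 0.0 else w0
    for i in range(1, k):
        l_gap = b[2 * i] - b[2 * i - 1]
        if l_gap > 0 and q > 0.0:
            W += q * (1.0 - q ** l_gap) / (1.0 - q)
    return W


@njit(cache=True)
def weight_external(b, G, circular, q):
    """sum_s P(tract starting at s touches the material)."""
    k = b.size // 2
    if k == 0:
        return 0.0
    m = np.int64(0)
    for i in range(k):
        m += b[2 * i + 1] - b[2 * i]
    W = float(m)
    if q == 0.0:
        return W
    if circular:
        if k == 1 and b[0] == 0 and b[1] == G:
            return W
        for i in range(k):
            e = b[2 * i + 1]
            nxt = b[2 * ((i + 1) % k)]
            l_gap = (nxt - e) % G
            if l_gap > 0:
                W += q * (1.0 - q ** l_gap) / (1.0 - q)
        return W
    if b[0] > 0:
        W += q * (1.0 - q ** b[0]) / (1.0 - q)
    for i in range(1, k):
        l_gap = b[2 * i] - b[2 * i - 1]
        if l_gap > 0:
            W += q * (1.0 - q ** l_gap) / (1.0 - q)
    return W


# ---------------------------------------------------------------------------
# start/length sampling
# ---------------------------------------------------------------------------

@njit(cache=True)
def _next_dist(b, G, circular, s):
    """Forward distance to the nearest material site; -1 if none (linear)."""
    k = b.size // 2
    lo, hi = 0, k
    while lo < hi:
        mid = (lo + hi) // 2
        if b[2 * mid + 1] <= s:
            lo = mid + 1
        else:
            hi = mid
    if lo < k:
        a = b[2 * lo]
        return np.int64(0) if a <= s else a - s
    if circular:
        return b[0] + G - s
    return np.int64(-1)


@njit(cache=True)
def _prev_dist(b, G, s):
    """Cyclic forward distance to the material site farthest ahead (the
    cyclic predecessor); circular genomes only."""
    k = b.size // 2
    t = s - 1
    if t < 0:
        p = b[2 * k - 1] - 1
        return (p - s) % G
    lo, hi = 0, k
    while lo < hi:
        mid = (lo + hi) // 2
        if b[2 * mid] <= t:
            lo = mid + 1
        else:
            hi = mid
    if lo == 0:
        p = b[2 * k - 1] - 1
    else:
        a, e = b[2 * (lo - 1)], b[2 * (lo - 1) + 1]
        p = t if t < e else e - 1
    return (p - s) % G


@njit(cache=True)
def _trunc_geom_offset(q, cnt, u):
    """Offset 0..cnt-1 with P(off) proportional to q**off."""
    if q == 0.0 or cnt <= 1:
        return np.int64(0)
    off = np.int64(math.log1p(-u * (1.0 - q ** cnt)) / math.log(q))
    if off > cnt - 1:
        off = np.int64(cnt - 1)
    return off


@njit(cache=True)
def _sample_len(q, lo, hi, u):
    """Geometric length conditioned on lo <= l (<= hi unless hi < 0)."""
    if q == 0.0:
        return np.int64(lo)
    if hi < 0:
        return np.int64(lo) + np.int64(math.log1p(-u) / math.log(q))
    span = hi - lo + 1
    if span <= 1:
        return np.int64(lo)
    l = np.int64(lo) + np.int64(
        math.log1p(-u * (1.0 - q ** span)) / math.log(q))
    if l > hi:
        l = np.int64(hi)
    return l


@njit(cache=True)
def sample_within_k(b, G, circular, q, u_run, u_off, u_len):
    """Sample (start, length) of an effective within-species tract."""
    k = b.size // 2
    W = weight_within(b, G, circular, q)
    r = u_run * W
    s = np.int64(-1)
    if circular:
        if k == 1 and b[0] == 0 and b[1] == G:
            w = 1.0 - q ** (G - 1)
            u = np.int64(r / w)
            if u > G - 1:
                u = np.int64(G - 1)
            s = u
        else:
            w_int = 1.0 - q ** (G - 1)
            for i in range(k):
                a, e = b[2 * i], b[2 * i + 1]
                pe = b[2 * ((i - 1) % k) + 1]
                l_prev = (a - pe) % G
                w = 1.0 - q ** (G - 1 - l_prev)
                if r <= w and w > 0.0:
                    s = a
                    break
                r -= w
                cnt = e - a - 1
                if cnt > 0:
                    if r <= cnt * w_int:
                        u = np.int64(r / w_int)
                        if u > cnt - 1:
                            u = np.int64(cnt - 1)
                        s = a + 1 + u
                        break
                    r -= cnt * w_int
                nxt = b[2 * ((i + 1) % k)]
                l_gap = (nxt - e) % G
                if l_gap > 0 and q > 0.0:
                    tot = (1.0 - q ** l_gap) * (q - q ** (G - l_gap)) \
                        / (1.0 - q)
                    if r <= tot and tot > 0.0:
                        u = _trunc_geom_offset(q, l_gap, u_off)
                        s = (nxt - 1 - u) % G
                        break
                    r -= tot
            if s < 0:
                s = b[0]  # float-spill fallback; always positive weight
        lo = _next_dist(b, G, True, s) + 1
        hi = _prev_dist(b, G, s)
        l = _sample_len(q, lo, hi, u_len)
        return s, l
    # linear genome
    a0 = b[0]
    m_last = b[2 * k - 1] - 1
    w0 = 1.0 - q ** (m_last - a0)
    tot = w0 * (1.0 - q ** (a0 + 1)) / (1.0 - q) if q > 0.0 else w0
    if r <= tot and tot > 0.0:
        u = _trunc_geom_offset(q, a0 + 1, u_off)
        s = a0 - u
    else:
        r -= tot
        cnt = b[1] - b[0] - 1
        if cnt > 0 and r <= cnt:
            u = np.int64(r)
            if u > cnt - 1:
                u = np.int64(cnt - 1)
            s = a0 + 1 + u
        else:
            if cnt > 0:
                r -= cnt
            for i in range(1, k):
                a, e = b[2 * i], b[2 * i + 1]
                l_gap = a - b[2 * i - 1]
                if l_gap > 0 and q > 0.0:
                    tot = q * (1.0 - q ** l_gap) / (1.0 - q)
                    if r <= tot:
                        u = _trunc_geom_offset(q, l_gap, u_off)
                        s = a - 1 - u
                        break
                    r -= tot
                cnt = e - a
                if r <= cnt:
                    u = np.int64(r)
                    if u > cnt - 1:
                        u = np.int64(cnt - 1)
                    s = a + u
                    break
                r -= cnt
            if s < 0:
                s = a0  # float-spill fallback
    d1 = _next_dist(b, G, False, s)
    lo = d1 + 1
    if b[0] < s:
        hi = np.int64(-1)        # material behind s: any length works
    else:
        hi = m_last - s
    l = _sample_len(q, lo, hi, u_len)
    return s, l


@njit(cache=True)
def sample_external_k(b, G, circular, q, u_run, u_off, u_len):
    """Sample (start, length) of a between-species tract touching the
    material; length is pre-truncation (cap/wrap applied by the caller)."""
    k = b.size // 2
    W = weight_external(b, G, circular, q)
    r = u_run * W
    s = np.int64(-1)
    if circular and k == 1 and b[0] == 0 and b[1] == G:
        u = np.int64(r)
        if u > G - 1:
            u = np.int64(G - 1)
        s = u
    elif circular:
        for i in range(k):
            a, e = b[2 * i], b[2 * i + 1]
            cnt = e - a
            if r <= cnt:
                u = np.int64(r)
                if u > cnt - 1:
                    u = np.int64(cnt - 1)
                s = a + u
                break
            r -= cnt
            nxt = b[2 * ((i + 1) % k)]
            l_gap = (nxt - e) % G
            if l_gap > 0 and q > 0.0:
                tot = q * (1.0 - q ** l_gap) / (1.0 - q)
                if r <= tot:
                    u = _trunc_geom_offset(q, l_gap, u_off)
                    s = (nxt - 1 - u) % G
                    break
                r -= tot
        if s < 0:
            s = b[0]
    else:
        a0 = b[0]
        if a0 > 0 and q > 0.0:
            tot = q * (1.0 - q ** a0) / (1.0 - q)
            if r <= tot:
                u = _trunc_geom_offset(q, a0, u_off)
                s = a0 - 1 - u
            else:
                r -= tot
        if s < 0:
            for i in range(k):
                a, e = b[2 * i], b[2 * i + 1]
                if i > 0:
                    l_gap = a - b[2 * i - 1]
                    if l_gap > 0 and q > 0.0:
                        tot = q * (1.0 - q ** l_gap) / (1.0 - q)
                        if r <= tot:
                            u = _trunc_geom_offset(q, l_gap, u_off)
                            s = a - 1 - u
                            break
                        r -= tot
                cnt = e - a
                if r <= cnt:
                    u = np.int64(r)
                    if u > cnt - 1:
                        u = np.int64(cnt - 1)
                    s = a + u
                    break
                r -= cnt
            if s < 0:
                s = b[0]
    d1 = _next_dist(b, G, circular, s)
    l = _sample_len(q, d1 + 1, np.int64(-1), u_len)
    return s, l


# ---------------------------------------------------------------------------
# carrier counts
# ---------------------------------------------------------------------------

@njit(cache=True)
def counts_decrement_singles(counts, region):
    """Decrement carrier counts over ``region``; return boundary array of
    the runs whose count just reached one (freshly resolved sites)."""
    n_runs = 0
    for ii in range(0, region.size, 2):
        prev = False
        for x in range(region[ii], region[ii + 1]):
            counts[x] -= 1
            single = counts[x] == 1
            if single and not prev:
                n_runs += 1
            prev = single
    out = np.empty(2 * n_runs, np.int64)
    m = 0
    for ii in range(0, region.size, 2):
        s, e = region[ii], region[ii + 1]
        prev = False
        for x in range(s, e):
            single = counts[x] == 1
            if single and not prev:
                out[m] = x
                m += 1
            if prev and not single:
                out[m] = x
                m += 1
            prev = single
        if prev:
            out[m] = e
            m += 1
    return out


@njit(cache=True)
def counts_zero(counts, region):
    for ii in range(0, region.size, 2):
        for x in range(region[ii], region[ii + 1]):
            counts[x] = 0


@njit(cache=True)
def counts_add(counts, region, v):
    for ii in range(0, region.size, 2):
        for x in range(region[ii], region[ii + 1]):
            counts[x] += v
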