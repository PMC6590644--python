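"""JIT-compiled inner loops for tree growth.

Two hot paths are compiled with numba: the fixed-effect best-split search
within a node, and the random-effects sequential step that scores every
candidate (parent, rule) by the whole-tree between-subgroups Q* after
re-pooling tau^2.  Pure-Python reference implementations of both live in
:mod:`metatree.tree` and the test suite cross-checks the two.

Conventions shared with :mod:`metatree.tree`:

* moderator columns are pre-encoded as floats (see ``EffectSizeSet.encoded``);
* threshold-type rules send ``code <= thr`` left;
* nominal rules are bitmasks over level codes (bit set -> level goes left),
  restricted to proper subsets of the levels observed in the node that
  contain the lowest observed level (so each bipartition appears once);
* candidate order is canonical -- moderator index ascending, then threshold
  ascending / mask ascending -- and ties keep the earliest candidate, which
  makes growth fully deterministic.
"""

import numpy as np
from numba import njit

# sentinel returned when a node admits no split
NO_SPLIT = -1


@njit(cache=True)
def fe_best_split(d, v, codes, type_codes, n_levels, members, min_size):
    """Best FE split of one node over all moderators.

    Maximises sum of child (sum w d)^2 / (sum w), which is equivalent to
    minimising Q_left + Q_right (and to maximising the local two-child Q_B).

    Returns (mod, thr, mask, score); mod == NO_SPLIT when nothing is
    admissible.  ``score`` is S1L^2/S0L + S1R^2/S0R for the winning rule.
    """
    n = members.size
    M = codes.shape[1]
    best_score = -1.0
    best_mod = NO_SPLIT
    best_thr = 0.0
    best_mask = 0

    t0 = 0.0
    t1 = 0.0
    for i in range(n):
        k = members[i]
        w = 1.0 / v[k]
        t0 += w
        t1 += w * d[k]

    vals = np.empty(n)
    for m in range(M):
        for i in range(n):
            vals[i] = codes[members[i], m]
        if type_codes[m] == 0:
            order = np.argsort(vals)
            s0 = 0.0
            s1 = 0.0
            for i in range(n - 1):
                k = members[order[i]]
                w = 1.0 / v[k]
                s0 += w
                s1 += w * d[k]
                lo = vals[order[i]]
                hi = vals[order[i + 1]]
                if lo < hi and i + 1 >= min_size and n - i - 1 >= min_size:
                    r0 = t0 - s0
                    r1 = t1 - s1
                    score = s1 * s1 / s0 + r1 * r1 / r0
                    if score > best_score:
                        best_score = score
                        best_mod = m
                        best_thr = 0.5 * (lo + hi)
                        best_mask = 0
        else:
            L = int(n_levels[m])
            c0 = np.zeros(L)
            c1 = np.zeros(L)
            cn = np.zeros(L, np.int64)
            for i in range(n):
                k = members[i]
                lv = int(vals[i])
                w = 1.0 / v[k]
                c0[lv] += w
                c1[lv] += w * d[k]
                cn[lv] += 1
            obs = 0
            l0 = -1
            for lv in range(L):
                if cn[lv] > 0:
                    obs |= 1 << lv
                    if l0 < 0:
                        l0 = lv
            if l0 >= 0:
                for mask in range(1, 1 << L):
                    if mask & ~obs:
                        continue
                    if not (mask >> l0) & 1:
                        continue
                    if mask == obs:
                        continue
                    ln = 0
                    s0 = 0.0
                    s1 = 0.0
                    for lv in range(L):
                        if (mask >> lv) & 1:
                            ln += cn[lv]
                            s0 += c0[lv]
                            s1 += c1[lv]
                    rn = n - ln
                    if ln >= min_size and rn >= min_size:
                        r0 = t0 - s0
                        r1 = t1 - s1
                        score = s1 * s1 / s0 + r1 * r1 / r0
                        if score > best_score:
                            best_score = score
                            best_mod = m
                            best_thr = 0.0
                            best_mask = mask
    return best_mod, best_thr, best_mask, best_score


@njit(cache=True)
def _qb_star(d, v, assign, n_terminal, parent, col, is_nominal, thr, mask,
             tau2, s0buf, s1buf):
    """Whole-tree between-subgroups Q* for one candidate split.

    Subgroups are the current terminal nodes with ``parent`` replaced by the
    two children of the candidate rule (right child occupies slot
    ``n_terminal``).  Uses Q*_B = sum_j S1_j^2/S0_j - S1^2/S0 with RE
    weights 1/(v + tau2).
    """
    for j in range(n_terminal + 1):
        s0buf[j] = 0.0
        s1buf[j] = 0.0
    K = d.size
    for k in range(K):
        j = assign[k]
        if j == parent:
            if is_nominal:
                if not (mask >> int(col[k])) & 1:
                    j = n_terminal
            else:
                if col[k] > thr:
                    j = n_terminal
        w = 1.0 / (v[k] + tau2)
        s0buf[j] += w
        s1buf[j] += w * d[k]
    qb = 0.0
    tot0 = 0.0
    tot1 = 0.0
    for j in range(n_terminal + 1):
        if s0buf[j] > 0.0:
            qb += s1buf[j] * s1buf[j] / s0buf[j]
            tot0 += s0buf[j]
            tot1 += s1buf[j]
    qb -= tot1 * tot1 / tot0
    return qb


@njit(cache=True)
def re_best_step(d, v, codes, type_codes, n_levels, assign, n_terminal,
                 node_q, node_c, node_n, min_size):
    """One sequential RE step: score every candidate (parent, rule).

    ``node_q``, ``node_c``, ``node_n`` cache each terminal node's FE
    within-Q, DL C component and size.  For every candidate the pooled DL
    tau^2 of the resulting partition is recomputed from the cached scalars,
    then the whole-tree Q*_B is evaluated at that tau^2.

    Returns (parent, mod, thr, mask, tau2, qb_star); parent == NO_SPLIT when
    no admissible candidate exists.
    """
    K = d.size
    M = codes.shape[1]
    sum_q = 0.0
    sum_c = 0.0
    sum_df = 0.0
    for j in range(n_terminal):
        sum_q += node_q[j]
        sum_c += node_c[j]
        sum_df += node_n[j] - 1

    best_qb = -np.inf
    best_parent = NO_SPLIT
    best_mod = -1
    best_thr = 0.0
    best_mask = 0
    best_tau2 = 0.0

    s0buf = np.empty(n_terminal + 1)
    s1buf = np.empty(n_terminal + 1)

    for p in range(n_terminal):
        n = int(node_n[p])
        if n < 2 * min_size:
            continue
        mem = np.empty(n, np.int64)
        c = 0
        for k in range(K):
            if assign[k] == p:
                mem[c] = k
                c += 1
        base_q = sum_q - node_q[p]
        base_c = sum_c - node_c[p]
        base_df = sum_df - (node_n[p] - 1)

        vals = np.empty(n)
        for m in range(M):
            for i in range(n):
                vals[i] = codes[mem[i], m]
            col = codes[:, m]
            if type_codes[m] == 0:
                order = np.argsort(vals)
                # prefix sums of w, wd, wd^2, w^2 in sorted order
                s0 = 0.0
                s1 = 0.0
                s2 = 0.0
                sq = 0.0
                t0 = 0.0
                t1 = 0.0
                t2 = 0.0
                tq = 0.0
                for i in range(n):
                    k = mem[order[i]]
                    w = 1.0 / v[k]
                    t0 += w
                    t1 += w * d[k]
                    t2 += w * d[k] * d[k]
                    tq += w * w
                for i in range(n - 1):
                    k = mem[order[i]]
                    w = 1.0 / v[k]
                    s0 += w
                    s1 += w * d[k]
                    s2 += w * d[k] * d[k]
                    sq += w * w
                    lo = vals[order[i]]
                    hi = vals[order[i + 1]]
                    if lo < hi and i + 1 >= min_size and n - i - 1 >= min_size:
                        r0 = t0 - s0
                        r1 = t1 - s1
                        r2 = t2 - s2
                        rq = tq - sq
                        q_l = max(s2 - s1 * s1 / s0, 0.0)
                        q_r = max(r2 - r1 * r1 / r0, 0.0)
                        c_l = s0 - sq / s0
                        c_r = r0 - rq / r0
                        num = (base_q + q_l + q_r) - (base_df + i + (n - i - 2))
                        den = base_c + c_l + c_r
                        tau2 = num / den if (den > 0.0 and num > 0.0) else 0.0
                        thr = 0.5 * (lo + hi)
                        qb = _qb_star(d, v, assign, n_terminal, p, col, 0,
                                      thr, 0, tau2, s0buf, s1buf)
                        if qb > best_qb:
                            best_qb = qb
                            best_parent = p
                            best_mod = m
                            best_thr = thr
                            best_mask = 0
                            best_tau2 = tau2
            else:
                L = int(n_levels[m])
                c0 = np.zeros(L)
                c1 = np.zeros(L)
                c2 = np.zeros(L)
                cq = np.zeros(L)
                cn = np.zeros(L, np.int64)
                for i in range(n):
                    k = mem[i]
                    lv = int(vals[i])
                    w = 1.0 / v[k]
                    c0[lv] += w
                    c1[lv] += w * d[k]
                    c2[lv] += w * d[k] * d[k]
                    cq[lv] += w * w
                    cn[lv] += 1
                obs = 0
                l0 = -1
                t0 = 0.0
                t1 = 0.0
                t2 = 0.0
                tq = 0.0
                for lv in range(L):
                    if cn[lv] > 0:
                        obs |= 1 << lv
                        if l0 < 0:
                            l0 = lv
                    t0 += c0[lv]
                    t1 += c1[lv]
                    t2 += c2[lv]
                    tq += cq[lv]
                if l0 < 0:
                    continue
                for mask in range(1, 1 << L):
                    if mask & ~obs:
                        continue
                    if not (mask >> l0) & 1:
                        continue
                    if mask == obs:
                        continue
                    ln = 0
                    s0 = 0.0
                    s1 = 0.0
                    s2 = 0.0
                    sq = 0.0
                    for lv in range(L):
                        if (mask >> lv) & 1:
                            ln += cn[lv]
                            s0 += c0[lv]
                            s1 += c1[lv]
                            s2 += c2[lv]
                            sq += cq[lv]
                    rn = n - ln
                    if ln >= min_size and rn >= min_size:
                        r0 = t0 - s0
                        r1 = t1 - s1
                        r2 = t2 - s2
                        rq = tq - sq
                        q_l = max(s2 - s1 * s1 / s0, 0.0)
                        q_r = max(r2 - r1 * r1 / r0, 0.0)
                        c_l = s0 - sq / s0
                        c_r = r0 - rq / r0
                        num = (base_q + q_l + q_r) - (base_df + (ln - 1) + (rn - 1))
                        den = base_c + c_l + c_r
                        tau2 = num / den if (den > 0.0 and num > 0.0) else 0.0
                        qb = _qb_star(d, v, assign, n_terminal, p, col, 1,
                                      0.0, mask, tau2, s0buf, s1buf)
                        if qb > best_qb:
                            best_qb = qb
                            best_parent = p
                            best_mod = m
                            best_thr = 0.0
                            best_mask = mask
                            best_tau2 = tau2
    return best_parent, best_mod, best_thr, best_mask, best_tau2, best_qb
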