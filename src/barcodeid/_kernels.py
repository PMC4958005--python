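"""Numba kernels for affine-gap local alignment.

All kernels operate on uint8-encoded sequences (A=0, C=1, G=2, T=3;
any code >= 4 is an ambiguity symbol that scores as a mismatch and never
counts as an identity).  Gap cost convention is BLAST-like: a gap of
length k costs gap_open + k * gap_extend.
"""

import numpy as np
from numba import njit

NEG_INF = np.int32(-(10**8))

# traceback pointers for the main (H) state
_STOP, _DIAG, _UP, _LEFT = 0, 1, 2, 3


@njit(cache=True)
def banded_affine_local(a, b, match, mismatch, gap_open, gap_extend, dlo, dhi):
    """Affine-gap Smith-Waterman restricted to diagonals d = i - j in [dlo, dhi].

    With dlo = -len(b) and dhi = len(a) this is the full (unbanded) algorithm.
    Returns (score, q0, q1, t0, t1, identities, aligned_columns) with half-open
    0-based spans on a (query) and b (target).  Returns score 0 when no
    positive-scoring cell exists.

    Co-optimal tie-break: diagonal > up (gap in target) > left (gap in query),
    and the best cell is the first encountered scanning i then k ascending.
    """
    n = a.shape[0]
    m = b.shape[0]
    W = dhi - dlo + 1
    H = np.full((n + 1, W + 2), np.int32(0), dtype=np.int32)
    E = np.full((n + 1, W + 2), NEG_INF, dtype=np.int32)
    F = np.full((n + 1, W + 2), NEG_INF, dtype=np.int32)
    P = np.zeros((n + 1, W + 2), dtype=np.uint8)
    PE = np.zeros((n + 1, W + 2), dtype=np.uint8)  # 1 = extend, 0 = open
    PF = np.zeros((n + 1, W + 2), dtype=np.uint8)
    # band index k maps to j = (i - dhi) + (k - 1); slot 0 and W+1 are sentinels
    go_ge = gap_open + gap_extend
    best = np.int32(0)
    bi = 0
    bk = 0
    for i in range(1, n + 1):
        jlo = i - dhi
        jhi = i - dlo
        if jlo < 1:
            jlo = 1
        if jhi > m:
            jhi = m
        for j in range(jlo, jhi + 1):
            k = j - (i - dhi) + 1
            # E: gap in b (consume a) -> from (i-1, j), band slot k+1
            e_open = H[i - 1, k + 1] - go_ge if H[i - 1, k + 1] > NEG_INF else NEG_INF
            e_ext = E[i - 1, k + 1] - gap_extend if E[i - 1, k + 1] > NEG_INF else NEG_INF
            if e_open >= e_ext:
                E[i, k] = e_open
                PE[i, k] = 0
            else:
                E[i, k] = e_ext
                PE[i, k] = 1
            # F: gap in a (consume b) -> from (i, j-1), band slot k-1
            f_open = H[i, k - 1] - go_ge if H[i, k - 1] > NEG_INF else NEG_INF
            f_ext = F[i, k - 1] - gap_extend if F[i, k - 1] > NEG_INF else NEG_INF
            if f_open >= f_ext:
                F[i, k] = f_open
                PF[i, k] = 0
            else:
                F[i, k] = f_ext
                PF[i, k] = 1
            ca = a[i - 1]
            cb = b[j - 1]
            s = match if (ca == cb and ca < 4) else mismatch
            diag = H[i - 1, k] + s if H[i - 1, k] > NEG_INF else NEG_INF
            val = np.int32(0)
            ptr = _STOP
            if diag > val:
                val = diag
                ptr = _DIAG
            if E[i, k] > val:
                val = E[i, k]
                ptr = _UP
            if F[i, k] > val:
                val = F[i, k]
                ptr = _LEFT
            H[i, k] = val
            P[i, k] = ptr
            if val > best:
                best = val
                bi = i
                bk = k
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback
    i = bi
    k = bk
    identities = 0
    columns = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    q1 = bi
    t1 = (bi - dhi) + (bk - 1)
    while True:
        if state == 0:
            p = P[i, k]
            if p == _STOP:
                break
            if p == _DIAG:
                j = (i - dhi) + (k - 1)
                ca = a[i - 1]
                cb = b[j - 1]
                if ca == cb and ca < 4:
                    identities += 1
                columns += 1
                i -= 1
                # j -= 1 keeps k constant
            elif p == _UP:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            ext = PE[i, k]
            i -= 1
            k += 1
            if ext == 0:
                state = 0
        else:
            columns += 1
            ext = PF[i, k]
            k -= 1
            if ext == 0:
                state = 0
    q0 = i
    t0 = (i - dhi) + (k - 1)
    return int(best), q0, q1, t0, t1, identities, columns


@njit(cache=True)
def ungapped_xdrop(a, b, qpos, tpos, wlen, match, mismatch, x_drop):
    """Extend an exact word seed un-gapped in both directions with X-drop.

    Returns (score, q0, q1) for the resulting HSP on the query (the target
    span follows from the shared diagonal).
    """
    n = a.shape[0]
    m = b.shape[0]
    score = wlen * match
    # right extension from end of word
    best = score
    cur = score
    q1 = qpos + wlen
    i = qpos + wlen
    j = tpos + wlen
    while i < n and j < m:
        ca = a[i]
        cb = b[j]
        cur += match if (ca == cb and ca < 4) else mismatch
        i += 1
        j += 1
        if cur > best:
            best = cur
            q1 = i
        elif best - cur > x_drop:
            break
    # left extension from start of word
    score = best
    cur = best
    q0 = qpos
    i = qpos - 1
    j = tpos - 1
    while i >= 0 and j >= 0:
        ca = a[i]
        cb = b[j]
        cur += match if (ca == cb and ca < 4) else mismatch
        if cur > score:
            score = cur
            q0 = i
        elif score - cur > x_drop:
            break
        i -= 1
        j -= 1
    return score, q0, q1


@njit(cache=True)
def best_seed_hsp(a, b, seed_q, seed_t, wlen, match, mismatch, x_drop):
    """Un-gapped X-drop extension of every seed; returns the best HSP.

    seed_q/seed_t are parallel arrays of word start positions.  Seeds on an
    already-extended diagonal reuse that diagonal's HSP (classic BLAST
    redundancy pruning).  Returns (score, diagonal) of the best HSP and the
    (min_diag, max_diag) over all seeds.
    """
    nseed = seed_q.shape[0]
    best_score = 0
    best_diag = 0
    dmin = seed_q[0] - seed_t[0]
    dmax = dmin
    # per-call diagonal bookkeeping: last extended q1 per diagonal
    seen_d = np.full(nseed, np.int64(2**62), dtype=np.int64)
    seen_q1 = np.zeros(nseed, dtype=np.int64)
    nseen = 0
    for s in range(nseed):
        d = seed_q[s] - seed_t[s]
        if d < dmin:
            dmin = d
        if d > dmax:
            dmax = d
        skip = False
        for t in range(nseen):
            if seen_d[t] == d and seed_q[s] < seen_q1[t]:
                skip = True
                break
        if skip:
            continue
        sc, q0, q1 = ungapped_xdrop(a, b, seed_q[s], seed_t[s], wlen, match, mismatch, x_drop)
        stored = False
        for t in range(nseen):
            if seen_d[t] == d:
                if q1 > seen_q1[t]:
                    seen_q1[t] = q1
                stored = True
                break
        if not stored:
            seen_d[nseen] = d
            seen_q1[nseen] = q1
            nseen += 1
        if sc > best_score:
            best_score = sc
            best_diag = d
    return best_score, best_diag, dmin, dmax
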