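"""Dynamic-programming alignment kernels (numba).

Two kernels: gapped local alignment of a position-specific score matrix
against an encoded subject sequence (Smith-Waterman with affine gaps), and
gapped global alignment over a precomputed column-pair score matrix (used for
profile-profile merges in the progressive aligner).

Gap cost convention is BLAST's: a gap of length k costs open + k * extend,
i.e. opening transitions pay open + extend and each further residue extend.

Tracebacks return aligned index pairs with -1 marking a gap on that side.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1_000_000_000


@njit(cache=False)
def sw_profile_local(scores, subj, gap_open, gap_extend):  # pragma: no cover - numba
    """Best local alignment of an (L, n_sym) score matrix against subj.

    Returns (best_score, n_pairs, profile_idx, subject_idx); the index arrays
    are length n_pairs, -1 where that side is gapped.  best_score <= 0 means
    no positive-scoring local alignment exists.
    """
    L = scores.shape[0]
    M = subj.shape[0]
    go = gap_open + gap_extend
    ge = gap_extend

    H = np.zeros((L + 1, M + 1), dtype=np.int64)
    E = np.full((L + 1, M + 1), NEG, dtype=np.int64)
    F = np.full((L + 1, M + 1), NEG, dtype=np.int64)
    ptrH = np.zeros((L + 1, M + 1), dtype=np.uint8)  # 0 diag-start, 1 diag, 2 E, 3 F
    ptrE = np.zeros((L + 1, M + 1), dtype=np.uint8)  # 0 from H, 1 from E
    ptrF = np.zeros((L + 1, M + 1), dtype=np.uint8)

    best = 0
    bi = 0
    bj = 0
    for i in range(1, L + 1):
        for j in range(1, M + 1):
            e_open = H[i - 1, j] - go
            e_ext = E[i - 1, j] - ge
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
                ptrE[i, j] = 0

            f_open = H[i, j - 1] - go
            f_ext = F[i, j - 1] - ge
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
                ptrF[i, j] = 0

            diag = H[i - 1, j - 1] + scores[i - 1, subj[j - 1]]
            h = diag
            p = 1 if H[i - 1, j - 1] > 0 else 0
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            if h < 0:
                h = 0
                p = 0
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j

    qi = np.empty(L + M, dtype=np.int64)
    sj = np.empty(L + M, dtype=np.int64)
    n = 0
    if best > 0:
        i = bi
        j = bj
        state = 0  # 0 H, 1 E, 2 F
        while True:
            if state == 0:
                p = ptrH[i, j]
                if p == 2:
                    state = 1
                    continue
                if p == 3:
                    state = 2
                    continue
                qi[n] = i - 1
                sj[n] = j - 1
                n += 1
                i -= 1
                j -= 1
                if p == 0:
                    break
            elif state == 1:
                qi[n] = i - 1
                sj[n] = -1
                n += 1
                nxt = ptrE[i, j]
                i -= 1
                state = 1 if nxt == 1 else 0
            else:
                qi[n] = -1
                sj[n] = j - 1
                n += 1
                nxt = ptrF[i, j]
                j -= 1
                state = 2 if nxt == 1 else 0
    return best, n, qi[:n][::-1].copy(), sj[:n][::-1].copy()


@njit(cache=False)
def nw_score_matrix_global(S, gap_open, gap_extend):  # pragma: no cover - numba
    """Global affine alignment over a precomputed (n1, n2) score matrix.

    End gaps are free (semi-global), so unshared terminal regions align as
    terminal gap blocks; interior gaps are affine.  Returns
    (score, n_pairs, idx1, idx2) with -1 marking gap columns; every index of
    both profiles appears exactly once.
    """
    n1 = S.shape[0]
    n2 = S.shape[1]
    go = float(gap_open + gap_extend)
    ge = float(gap_extend)

    H = np.zeros((n1 + 1, n2 + 1))
    E = np.full((n1 + 1, n2 + 1), float(NEG))
    F = np.full((n1 + 1, n2 + 1), float(NEG))
    ptrH = np.zeros((n1 + 1, n2 + 1), dtype=np.uint8)  # 0 border, 1 diag, 2 E, 3 F
    ptrE = np.zeros((n1 + 1, n2 + 1), dtype=np.uint8)
    ptrF = np.zeros((n1 + 1, n2 + 1), dtype=np.uint8)

    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            e_open = H[i - 1, j] - go
            e_ext = E[i - 1, j] - ge
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
                ptrE[i, j] = 0

            f_open = H[i, j - 1] - go
            f_ext = F[i, j - 1] - ge
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
                ptrF[i, j] = 0

            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p

    # free trailing gaps: best cell on the last row or column
    best = H[n1, n2]
    bi = n1
    bj = n2
    for i in range(n1 + 1):
        if H[i, n2] > best:
            best = H[i, n2]
            bi = i
            bj = n2
    for j in range(n2 + 1):
        if H[n1, j] > best:
            best = H[n1, j]
            bi = n1
            bj = j

    idx1 = np.empty(n1 + n2, dtype=np.int64)
    idx2 = np.empty(n1 + n2, dtype=np.int64)
    n = 0
    # trailing gap block
    for i in range(n1 - 1, bi - 1, -1):
        idx1[n] = i
        idx2[n] = -1
        n += 1
    for j in range(n2 - 1, bj - 1, -1):
        idx1[n] = -1
        idx2[n] = j
        n += 1
    i = bi
    j = bj
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 2:
                state = 1
                continue
            if p == 3:
                state = 2
                continue
            idx1[n] = i - 1
            idx2[n] = j - 1
            n += 1
            i -= 1
            j -= 1
        elif state == 1:
            idx1[n] = i - 1
            idx2[n] = -1
            n += 1
            nxt = ptrE[i, j]
            i -= 1
            state = 1 if nxt == 1 else 0
        else:
            idx1[n] = -1
            idx2[n] = j - 1
            n += 1
            nxt = ptrF[i, j]
            j -= 1
            state = 2 if nxt == 1 else 0
    # leading gap block
    for k in range(i - 1, -1, -1):
        idx1[n] = k
        idx2[n] = -1
        n += 1
    for k in range(j - 1, -1, -1):
        idx1[n] = -1
        idx2[n] = k
        n += 1
    return best, n, idx1[:n][::-1].copy(), idx2[:n][::-1].copy()
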