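"""Numba dynamic-programming kernels for affine-gap pairwise alignment.

Both kernels implement Gotoh's three-state recursion (M: substitution,
X: gap in b consuming a, Y: gap in a consuming b). Tie-breaking during
traceback is deterministic: diagonal before up (X) before left (Y), and
within each state the predecessor preference is M, then X, then Y. The
local kernel ends at the first maximal cell in row-major order.

Opening a gap costs ``gap_open + gap_extend`` for its first position and
``gap_extend`` for each further position.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int64(-(10**15))


@njit(cache=True)
def _gotoh_fill(a, b, S, go, ge, local):
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), NEG, np.int64)
    X = np.full((n + 1, m + 1), NEG, np.int64)
    Y = np.full((n + 1, m + 1), NEG, np.int64)
    pM = np.zeros((n + 1, m + 1), np.int8)
    pX = np.zeros((n + 1, m + 1), np.int8)
    pY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0
    if not local:
        for i in range(1, n + 1):
            X[i, 0] = go + ge * i
            pX[i, 0] = 1
        for j in range(1, m + 1):
            Y[0, j] = go + ge * j
            pY[0, j] = 2
    else:
        for i in range(1, n + 1):
            M[i, 0] = 0
            pM[i, 0] = 3
        for j in range(m + 1):
            M[0, j] = 0
            pM[0, j] = 3
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            # X: consume a (vertical, "up")
            vm = M[i - 1, j] + go + ge
            vx = X[i - 1, j] + ge
            vy = Y[i - 1, j] + go + ge
            if vm >= vx and vm >= vy:
                X[i, j] = vm
                pX[i, j] = 0
            elif vx >= vy:
                X[i, j] = vx
                pX[i, j] = 1
            else:
                X[i, j] = vy
                pX[i, j] = 2
            # Y: consume b (horizontal, "left")
            hm = M[i, j - 1] + go + ge
            hx = X[i, j - 1] + go + ge
            hy = Y[i, j - 1] + ge
            if hm >= hx and hm >= hy:
                Y[i, j] = hm
                pY[i, j] = 0
            elif hx >= hy:
                Y[i, j] = hx
                pY[i, j] = 1
            else:
                Y[i, j] = hy
                pY[i, j] = 2
            # M: substitution (diagonal)
            dm = M[i - 1, j - 1]
            dx = X[i - 1, j - 1]
            dy = Y[i - 1, j - 1]
            if dm >= dx and dm >= dy:
                dbest = dm
                dptr = 0
            elif dx >= dy:
                dbest = dx
                dptr = 1
            else:
                dbest = dy
                dptr = 2
            s = dbest + S[ai, b[j - 1]]
            if local and s < 0:
                M[i, j] = 0
                pM[i, j] = 3
            else:
                M[i, j] = s
                pM[i, j] = dptr
            if local and M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    return M, X, Y, pM, pX, pY, best, bi, bj


@njit(cache=True)
def _traceback(pM, pX, pY, i, j, state, local):
    # returns index arrays (-1 = gap) in reverse order, plus length
    cap = i + j + 1
    ai = np.empty(cap, np.int64)
    bi = np.empty(cap, np.int64)
    k = 0
    while True:
        if local:
            if state == 0 and pM[i, j] == 3:
                break
        else:
            if i == 0 and j == 0:
                break
        if state == 0:
            prev = pM[i, j]
            ai[k] = i - 1
            bi[k] = j - 1
            i -= 1
            j -= 1
        elif state == 1:
            prev = pX[i, j]
            ai[k] = i - 1
            bi[k] = -1
            i -= 1
        else:
            prev = pY[i, j]
            ai[k] = -1
            bi[k] = j - 1
            j -= 1
        k += 1
        state = prev
    return ai[:k][::-1].copy(), bi[:k][::-1].copy()


@njit(cache=True)
def semiglobal_matrix(a, b, S, go, ge):
    """Best-score matrix V[i, j] for aligning the prefix a[:i] so that the
    alignment ends exactly at subject position j, with the subject prefix
    before the alignment start free (query must start at a[0]).

    Used for junction anchoring: V peaks where a template prefix stops
    matching the subject (e.g. at an insertion junction).
    """
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), NEG, np.int64)
    X = np.full((n + 1, m + 1), NEG, np.int64)
    Y = np.full((n + 1, m + 1), NEG, np.int64)
    for j in range(m + 1):
        M[0, j] = 0
    for i in range(1, n + 1):
        X[i, 0] = go + ge * i
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            vm = M[i - 1, j] + go + ge
            vx = X[i - 1, j] + ge
            vy = Y[i - 1, j] + go + ge
            X[i, j] = max(vm, vx, vy)
            hm = M[i, j - 1] + go + ge
            hx = X[i, j - 1] + go + ge
            hy = Y[i, j - 1] + ge
            Y[i, j] = max(hm, hx, hy)
            d = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = d + S[ai, b[j - 1]]
    V = np.empty((n + 1, m + 1), np.int64)
    for i in range(n + 1):
        for j in range(m + 1):
            V[i, j] = max(M[i, j], X[i, j], Y[i, j])
    return V


def gotoh_align(a_codes, b_codes, S, gap_open, gap_extend, local):
    """Run the DP and traceback; returns (score, a_idx, b_idx).

    ``a_idx``/``b_idx`` are parallel arrays over alignment columns with
    sequence positions, -1 marking a gap. Empty arrays for a local
    alignment mean the empty alignment (score 0) is optimal.
    """
    M, X, Y, pM, pX, pY, best, bi, bj = _gotoh_fill(
        a_codes, b_codes, S, np.int64(gap_open), np.int64(gap_extend), local
    )
    n, m = a_codes.shape[0], b_codes.shape[0]
    if local:
        if best <= 0:
            return 0, np.empty(0, np.int64), np.empty(0, np.int64)
        ai, bix = _traceback(pM, pX, pY, bi, bj, np.int8(0), True)
        return int(best), ai, bix
    # global end state: prefer diagonal, then up, then left
    vals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(np.array(vals)))
    # argmax returns first max -> M preferred, then X, then Y
    ai, bix = _traceback(pM, pX, pY, n, m, np.int8(state), False)
    return int(vals[state]), ai, bix
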