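"""Compiled dynamic-programming kernels (numba).

Three primitives:

* ``gotoh_local`` -- affine-gap Smith-Waterman with traceback, used for
  gapped extension inside seeded candidate windows;
* ``lev_best`` / ``lev_pair`` -- plain Levenshtein distances, used in bulk
  for the sliding 36-mer scoring;
* ``profile_nw`` -- linear-gap Needleman-Wunsch on frequency profiles for
  the internal progressive multiple aligner.
"""
from __future__ import annotations

import numpy as np
from numba import njit

# alignment column op codes emitted by gotoh traceback
OP_DIAG = 0
OP_UP = 1  # consumes a, gap in b
OP_LEFT = 2  # consumes b, gap in a


@njit(cache=True)
def gotoh_local(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Affine-gap local alignment of uint8-coded sequences.

    Gap of length g costs gap_open + g*gap_extend (both negative).
    Returns (score, a_start, a_end, b_start, b_end, ops) where ops is the
    int8 op sequence of the best-scoring local path.
    """
    n, m = len(a), len(b)
    NEG = -10**9
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in a (left moves)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in b (up moves)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop,1 diag,2 up,3 left
    eptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 open, 0 extend
    fptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open + gap_extend
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                eptr[i, j] = 1
            else:
                E[i, j] = e_ext
                eptr[i, j] = 0
            f_open = H[i - 1, j] + gap_open + gap_extend
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                fptr[i, j] = 1
            else:
                F[i, j] = f_ext
                fptr[i, j] = 0
            # code 4 marks masked/ambiguous bases: never a match
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
            diag = H[i - 1, j - 1] + s
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = bi, bj
    state = 0  # 0 in H, 1 in F (up), 2 in E (left)
    while i > 0 and j > 0:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                ops[k] = OP_DIAG
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = fptr[i, j]
            ops[k] = OP_UP
            k += 1
            i -= 1
            if opened == 1:
                state = 0
        else:
            opened = eptr[i, j]
            ops[k] = OP_LEFT
            k += 1
            j -= 1
            if opened == 1:
                state = 0
    return best, i, bi, j, bj, ops[:k][::-1].copy()


@njit(cache=True)
def lev_pair(a, b):  # pragma: no cover
    """Levenshtein distance between two uint8 sequences (full DP)."""
    n, m = len(a), len(b)
    prev = np.empty(m + 1, dtype=np.int32)
    cur = np.empty(m + 1, dtype=np.int32)
    for j in range(m + 1):
        prev[j] = j
    for i in range(1, n + 1):
        cur[0] = i
        ai = a[i - 1]
        for j in range(1, m + 1):
            cost = 0 if ai == b[j - 1] else 1
            d = prev[j - 1] + cost
            if prev[j] + 1 < d:
                d = prev[j] + 1
            if cur[j - 1] + 1 < d:
                d = cur[j - 1] + 1
            cur[j] = d
        prev, cur = cur, prev
    return prev[m]


@njit(cache=True)
def lev_best_many(windows, motifs):  # pragma: no cover
    """For each row of ``windows`` (k x L uint8), the minimum Levenshtein
    distance to any row of ``motifs`` (m x L uint8)."""
    k = windows.shape[0]
    m = motifs.shape[0]
    out = np.empty(k, dtype=np.int32)
    for i in range(k):
        best = 1 << 30
        for j in range(m):
            d = lev_pair(windows[i], motifs[j])
            if d < best:
                best = d
                if best == 0:
                    break
        out[i] = best
    return out


@njit(cache=True)
def hamming_best_many(windows, motifs):  # pragma: no cover
    k = windows.shape[0]
    m = motifs.shape[0]
    L = windows.shape[1]
    out = np.empty(k, dtype=np.int32)
    for i in range(k):
        best = L + 1
        for j in range(m):
            d = 0
            for t in range(L):
                if windows[i, t] != motifs[j, t]:
                    d += 1
                    if d >= best:
                        break
            if d < best:
                best = d
    # note: best==0 early exit intentionally omitted; loop is cheap
        out[i] = best
    return out


@njit(cache=True)
def profile_nw(pa, pb, gap):  # pragma: no cover
    """Global alignment of two column-frequency profiles (L x 4 float32).

    Column score = 2 * <fa, fb> - 1 (expected match minus mismatch under
    independent draws); linear gap penalty ``gap`` (negative). Returns the
    int8 op sequence over (OP_DIAG, OP_UP, OP_LEFT).
    """
    n = pa.shape[0]
    m = pb.shape[0]
    H = np.empty((n + 1, m + 1), dtype=np.float32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for i in range(1, n + 1):
        H[i, 0] = H[i - 1, 0] + gap
        ptr[i, 0] = 1
    for j in range(1, m + 1):
        H[0, j] = H[0, j - 1] + gap
        ptr[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dot = (
                pa[i - 1, 0] * pb[j - 1, 0]
                + pa[i - 1, 1] * pb[j - 1, 1]
                + pa[i - 1, 2] * pb[j - 1, 2]
                + pa[i - 1, 3] * pb[j - 1, 3]
            )
            s = H[i - 1, j - 1] + 2.0 * dot - 1.0
            up = H[i - 1, j] + gap
            left = H[i, j - 1] + gap
            h = s
            p = 0
            if up > h:
                h = up
                p = 1
            if left > h:
                h = left
                p = 2
            H[i, j] = h
            ptr[i, j] = p
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0 and i > 0 and j > 0:
            ops[k] = OP_DIAG
            i -= 1
            j -= 1
        elif p == 1 or j == 0:
            ops[k] = OP_UP
            i -= 1
        else:
            ops[k] = OP_LEFT
            j -= 1
        k += 1
    return ops[:k][::-1].copy()
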