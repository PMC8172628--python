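"""Numba-compiled dynamic-programming kernels for local and global alignment.

All kernels take a generic score lookup ``mat[a[i], b[j]]`` so the same code
aligns sequence-vs-sequence (``a`` holds residue indices, ``mat`` is 21x21) and
profile-vs-sequence (``a`` is ``arange(n_columns)``, ``mat`` is the per-column
position-specific score matrix of shape (n_columns, 21)).

Gap convention: a gap of length k costs ``gap_open + (k-1)*gap_extend``
(both negative).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def sw_best_segment(a, b, mat, gap_open, gap_extend, b_mask):
    """Best local alignment score and segment coordinates (1-based inclusive).

    ``b_mask[j] == 0`` forbids aligning against position j of ``b`` (used to
    extract additional disjoint domains). Returns
    ``(score, a_start, a_end, b_start, b_end)``; all coordinates 0 when no
    positive-scoring cell exists.
    """
    n, m = len(a), len(b)
    H = np.zeros(m + 1)
    oHi = np.zeros(m + 1, np.int64)
    oHj = np.zeros(m + 1, np.int64)
    Hprev = np.zeros(m + 1)
    oHi_prev = np.zeros(m + 1, np.int64)
    oHj_prev = np.zeros(m + 1, np.int64)
    Fcol = np.full(m + 1, NEG)
    oFi = np.zeros(m + 1, np.int64)
    oFj = np.zeros(m + 1, np.int64)
    best = 0.0
    bi = 0
    bj = 0
    boi = 0
    boj = 0
    for i in range(1, n + 1):
        for j in range(m + 1):
            Hprev[j] = H[j]
            oHi_prev[j] = oHi[j]
            oHj_prev[j] = oHj[j]
        H[0] = 0.0
        Erow = NEG  # gap in a, consuming b (horizontal); reset per row
        oEri = 0
        oErj = 0
        for j in range(1, m + 1):
            open_e = H[j - 1] + gap_open
            ext_e = Erow + gap_extend
            if open_e >= ext_e:
                Erow = open_e
                oEri = oHi[j - 1]
                oErj = oHj[j - 1]
            else:
                Erow = ext_e
            open_f = Hprev[j] + gap_open  # gap in b, consuming a (vertical)
            ext_f = Fcol[j] + gap_extend
            if open_f >= ext_f:
                Fcol[j] = open_f
                oFi[j] = oHi_prev[j]
                oFj[j] = oHj_prev[j]
            else:
                Fcol[j] = ext_f
            if b_mask[j - 1] == 0:
                sub = NEG
            else:
                sub = mat[a[i - 1], b[j - 1]]
            diag = Hprev[j - 1] + sub
            h = 0.0
            ohi = 0
            ohj = 0
            if diag > h:
                h = diag
                if Hprev[j - 1] <= 0.0:
                    ohi = i  # fresh start: segment begins with this match
                    ohj = j
                else:
                    ohi = oHi_prev[j - 1]
                    ohj = oHj_prev[j - 1]
            if Erow > h:
                h = Erow
                ohi = oEri
                ohj = oErj
            if Fcol[j] > h:
                h = Fcol[j]
                ohi = oFi[j]
                ohj = oFj[j]
            if h <= 0.0:
                h = 0.0
                ohi = 0
                ohj = 0
            H[j] = h
            oHi[j] = ohi
            oHj[j] = ohj
            if h > best:
                best = h
                bi = i
                bj = j
                boi = ohi
                boj = ohj
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0
    return best, boi, bi, boj, bj


@njit(cache=True)
def sw_fill(a, b, mat, gap_open, gap_extend):
    """Full local-alignment DP fill with traceback pointers.

    Returns ``(score, end_i, end_j, ptrH, ptrE, ptrF)`` where pointer codes in
    ptrH are 0=restart, 1=diagonal, 2=from E (gap in a), 3=from F (gap in b);
    in ptrE/ptrF 0=opened from H, 1=extended.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    ptrH = np.zeros((n + 1, m + 1), np.uint8)
    ptrE = np.zeros((n + 1, m + 1), np.uint8)
    ptrF = np.zeros((n + 1, m + 1), np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            open_e = H[i, j - 1] + gap_open
            ext_e = E[i, j - 1] + gap_extend
            if open_e >= ext_e:
                E[i, j] = open_e
                ptrE[i, j] = 0
            else:
                E[i, j] = ext_e
                ptrE[i, j] = 1
            open_f = H[i - 1, j] + gap_open
            ext_f = F[i - 1, j] + gap_extend
            if open_f >= ext_f:
                F[i, j] = open_f
                ptrF[i, j] = 0
            else:
                F[i, j] = ext_f
                ptrF[i, j] = 1
            diag = H[i - 1, j - 1] + mat[a[i - 1], b[j - 1]]
            h = 0.0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptrH, ptrE, ptrF


@njit(cache=True)
def nw_fill(a, b, mat, gap_open, gap_extend):
    """Global (Needleman–Wunsch) affine alignment fill with pointers.

    Same pointer encoding as :func:`sw_fill` except code 0 is unused in ptrH
    (every cell must come from somewhere); boundary cells are encoded as gaps.
    Returns ``(score, ptrH, ptrE, ptrF)``.
    """
    n, m = len(a), len(b)
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    ptrH = np.zeros((n + 1, m + 1), np.uint8)
    ptrE = np.zeros((n + 1, m + 1), np.uint8)
    ptrF = np.zeros((n + 1, m + 1), np.uint8)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = gap_open + (j - 1) * gap_extend
        H[0, j] = E[0, j]
        ptrE[0, j] = 0 if j == 1 else 1
        ptrH[0, j] = 2
    for i in range(1, n + 1):
        F[i, 0] = gap_open + (i - 1) * gap_extend
        H[i, 0] = F[i, 0]
        ptrF[i, 0] = 0 if i == 1 else 1
        ptrH[i, 0] = 3
        for j in range(1, m + 1):
            open_e = H[i, j - 1] + gap_open
            ext_e = E[i, j - 1] + gap_extend
            if open_e >= ext_e:
                E[i, j] = open_e
                ptrE[i, j] = 0
            else:
                E[i, j] = ext_e
                ptrE[i, j] = 1
            open_f = H[i - 1, j] + gap_open
            ext_f = F[i - 1, j] + gap_extend
            if open_f >= ext_f:
                F[i, j] = open_f
                ptrF[i, j] = 0
            else:
                F[i, j] = ext_f
                ptrF[i, j] = 1
            diag = H[i - 1, j - 1] + mat[a[i - 1], b[j - 1]]
            h = diag
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
    return H[n, m], ptrH, ptrE, ptrF


def traceback_local(bi, bj, ptrH, ptrE, ptrF):
    """Walk local-alignment pointers back from (bi, bj).

    Returns aligned column lists ``(ai, bj)`` (0-based indices, -1 for a gap),
    ordered left to right.
    """
    cols_a: list[int] = []
    cols_b: list[int] = []
    i, j, state = bi, bj, "H"
    while i > 0 or j > 0:
        if state == "H":
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                cols_a.append(i - 1)
                cols_b.append(j - 1)
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols_a.append(-1)
            cols_b.append(j - 1)
            nxt = ptrE[i, j]
            j -= 1
            state = "E" if nxt == 1 else "H"
        else:
            cols_a.append(i - 1)
            cols_b.append(-1)
            nxt = ptrF[i, j]
            i -= 1
            state = "F" if nxt == 1 else "H"
    cols_a.reverse()
    cols_b.reverse()
    return cols_a, cols_b


def traceback_global(n, m, ptrH, ptrE, ptrF):
    """Walk global-alignment pointers back from (n, m)."""
    cols_a: list[int] = []
    cols_b: list[int] = []
    i, j, state = n, m, "H"
    while i > 0 or j > 0:
        if state == "H":
            p = ptrH[i, j]
            if p == 1:
                cols_a.append(i - 1)
                cols_b.append(j - 1)
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols_a.append(-1)
            cols_b.append(j - 1)
            nxt = ptrE[i, j]
            j -= 1
            state = "E" if nxt == 1 else "H"
        else:
            cols_a.append(i - 1)
            cols_b.append(-1)
            nxt = ptrF[i, j]
            i -= 1
            state = "F" if nxt == 1 else "H"
    cols_a.reverse()
    cols_b.reverse()
    return cols_a, cols_b
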