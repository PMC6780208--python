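"""Local profile alignment kernel.

Smith–Waterman dynamic programming of a position-specific scoring matrix
(profile rows) against a protein (columns), with affine gap penalties.  The
kernel returns the best local score together with the protein interval it
covers; masked protein positions (residue code < 0) are unalignable.
"""
from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=False)
def _sw_profile(pssm, codes, gap_open, gap_extend):  # pragma: no cover - jit
    L = pssm.shape[0]
    n = codes.shape[0]
    M = np.full((L + 1, n + 1), 0.0)
    Ix = np.full((L + 1, n + 1), NEG)   # gap in protein (profile row consumed)
    Iy = np.full((L + 1, n + 1), NEG)   # gap in profile (protein col consumed)
    # pointers: 0 = local start, 1 = from M, 2 = from Ix, 3 = from Iy
    ptr_m = np.zeros((L + 1, n + 1), dtype=np.uint8)
    ptr_x = np.zeros((L + 1, n + 1), dtype=np.uint8)
    ptr_y = np.zeros((L + 1, n + 1), dtype=np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, L + 1):
        for j in range(1, n + 1):
            c = codes[j - 1]
            s = NEG if c < 0 else pssm[i - 1, c]
            # match state
            prev = 0.0
            p = 0
            if M[i - 1, j - 1] > prev:
                prev = M[i - 1, j - 1]
                p = 1
            if Ix[i - 1, j - 1] > prev:
                prev = Ix[i - 1, j - 1]
                p = 2
            if Iy[i - 1, j - 1] > prev:
                prev = Iy[i - 1, j - 1]
                p = 3
            m = prev + s
            if m < NEG:
                m = NEG
            M[i, j] = m
            ptr_m[i, j] = p
            # gap states
            a = M[i - 1, j] - gap_open
            b = Ix[i - 1, j] - gap_extend
            if a >= b:
                Ix[i, j] = a
                ptr_x[i, j] = 1
            else:
                Ix[i, j] = b
                ptr_x[i, j] = 2
            a = M[i, j - 1] - gap_open
            b = Iy[i, j - 1] - gap_extend
            if a >= b:
                Iy[i, j] = a
                ptr_y[i, j] = 1
            else:
                Iy[i, j] = b
                ptr_y[i, j] = 3
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0
    # traceback from the best match cell to the local start
    i = bi
    j = bj
    state = 1
    start_i = i
    start_j = j
    while True:
        if state == 1:
            p = ptr_m[i, j]
            start_i = i
            start_j = j
            i -= 1
            j -= 1
            if p == 0:
                break
            state = p
        elif state == 2:
            p = ptr_x[i, j]
            i -= 1
            state = p
        else:
            p = ptr_y[i, j]
            j -= 1
            state = p
    return best, start_j - 1, bj, start_i - 1, bi


def sw_profile_best(pssm: np.ndarray, codes: np.ndarray,
                    gap_open: float, gap_extend: float):
    """Best local alignment of *pssm* against encoded protein *codes*.

    Returns ``(score, q_start, q_end, p_start, p_end)`` with 0-based half-open
    protein coordinates ``[q_start, q_end)`` and profile coordinates
    ``[p_start, p_end)``; score 0.0 with empty coordinates when nothing
    positive-scoring exists.
    """
    if codes.size == 0 or pssm.shape[0] == 0:
        return 0.0, 0, 0, 0, 0
    score, qs, qe, ps, pe = _sw_profile(
        np.ascontiguousarray(pssm, dtype=np.float64),
        np.ascontiguousarray(codes, dtype=np.int64),
        float(gap_open), float(gap_extend))
    return float(score), int(qs), int(qe), int(ps), int(pe)


@njit(cache=False)
def _sw_score_only(pssm, codes, gap_open, gap_extend):  # pragma: no cover
    L = pssm.shape[0]
    n = codes.shape[0]
    M_prev = np.zeros(n + 1)
    Ix_prev = np.full(n + 1, NEG)
    Iy_prev = np.full(n + 1, NEG)
    best = 0.0
    for i in range(1, L + 1):
        M_cur = np.zeros(n + 1)
        Ix_cur = np.full(n + 1, NEG)
        Iy_cur = np.full(n + 1, NEG)
        for j in range(1, n + 1):
            c = codes[j - 1]
            s = NEG if c < 0 else pssm[i - 1, c]
            prev = 0.0
            if M_prev[j - 1] > prev:
                prev = M_prev[j - 1]
            if Ix_prev[j - 1] > prev:
                prev = Ix_prev[j - 1]
            if Iy_prev[j - 1] > prev:
                prev = Iy_prev[j - 1]
            m = prev + s
            if m < NEG:
                m = NEG
            M_cur[j] = m
            a = M_prev[j] - gap_open
            b = Ix_prev[j] - gap_extend
            Ix_cur[j] = a if a >= b else b
            a = M_cur[j - 1] - gap_open
            b = Iy_cur[j - 1] - gap_extend
            Iy_cur[j] = a if a >= b else b
            if m > best:
                best = m
        M_prev = M_cur
        Ix_prev = Ix_cur
        Iy_prev = Iy_cur
    return best


def sw_profile_score(pssm: np.ndarray, codes: np.ndarray,
                     gap_open: float, gap_extend: float) -> float:
    """Best local score only (linear memory; used for shuffle nulls)."""
    if codes.size == 0 or pssm.shape[0] == 0:
        return 0.0
    return float(_sw_score_only(
        np.ascontiguousarray(pssm, dtype=np.float64),
        np.ascontiguousarray(codes, dtype=np.int64),
        float(gap_open), float(gap_extend)))
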