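"""Numba-jitted affine-gap Smith-Waterman (optionally banded).

Scores use the BLASTN-like convention: a gap of length k costs
``open + k * extend``, so the first gap symbol costs ``open + extend``.
With ``band >= max(len)`` the full dynamic-programming matrix is
computed and the score is exact; a finite band restricts the alignment
path to diagonals within +-band, which is exact whenever the optimal
path stays in the band (always the case for co-aligned, gap-free data).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**6)


@njit(cache=True)
def sw_scores_banded(q, refs, band, match, mismatch, gap_open1, gap_ext):
    """Best local-alignment score of ``q`` against each row of ``refs``.

    ``gap_open1`` is the cost of the first gap symbol (open + extend).
    """
    n = q.shape[0]
    nref = refs.shape[0]
    m = refs.shape[1]
    out = np.zeros(nref, dtype=np.int32)
    W = 2 * band + 1
    for r in range(nref):
        ref = refs[r]
        Hprev = np.zeros(W + 2, dtype=np.int32)
        Eprev = np.full(W + 2, NEG, dtype=np.int32)
        Hcur = np.zeros(W + 2, dtype=np.int32)
        Ecur = np.full(W + 2, NEG, dtype=np.int32)
        best = 0
        for i in range(1, n + 1):
            F = NEG
            for d in range(W):
                j = i - band + d
                if j < 1 or j > m:
                    Hcur[d + 1] = 0 if j <= m else NEG
                    Ecur[d + 1] = NEG
                    continue
                s = match if (q[i - 1] == ref[j - 1] and q[i - 1] < 4) else mismatch
                diag = Hprev[d + 1]
                up = Hprev[d + 2]
                e = Eprev[d + 2] - gap_ext
                e2 = up - gap_open1
                E = e if e > e2 else e2
                f2 = Hcur[d] - gap_open1
                F = F - gap_ext if F - gap_ext > f2 else f2
                h = diag + s
                if E > h:
                    h = E
                if F > h:
                    h = F
                if h < 0:
                    h = 0
                Hcur[d + 1] = h
                Ecur[d + 1] = E
                if h > best:
                    best = h
            tmp = Hprev
            Hprev = Hcur
            Hcur = tmp
            tmp = Eprev
            Eprev = Ecur
            Ecur = tmp
        out[r] = best
    return out


@njit(cache=True)
def sw_align_banded(q, ref, band, match, mismatch, gap_open1, gap_ext):
    """Full banded DP with traceback.

    Returns (score, matches, aligned_columns) of the best local alignment;
    aligned_columns counts matches + mismatches + gap positions.
    """
    n = q.shape[0]
    m = ref.shape[0]
    W = 2 * band + 1
    H = np.zeros((n + 1, W + 2), dtype=np.int32)
    E = np.full((n + 1, W + 2), NEG, dtype=np.int32)
    Fm = np.full((n + 1, W + 2), NEG, dtype=np.int32)
    best = 0
    bi = 0
    bd = 0
    for i in range(1, n + 1):
        F = NEG
        for d in range(W):
            j = i - band + d
            if j < 1 or j > m:
                H[i, d + 1] = 0 if j <= m else NEG
                E[i, d + 1] = NEG
                Fm[i, d + 1] = NEG
                continue
            s = match if (q[i - 1] == ref[j - 1] and q[i - 1] < 4) else mismatch
            diag = H[i - 1, d + 1]
            up = H[i - 1, d + 2]
            e = E[i - 1, d + 2] - gap_ext
            e2 = up - gap_open1
            Ev = e if e > e2 else e2
            f2 = H[i, d] - gap_open1
            F = F - gap_ext if F - gap_ext > f2 else f2
            h = diag + s
            if Ev > h:
                h = Ev
            if F > h:
                h = F
            if h < 0:
                h = 0
            H[i, d + 1] = h
            E[i, d + 1] = Ev
            Fm[i, d + 1] = F
            if h > best:
                best = h
                bi = i
                bd = d
    # traceback from (bi, bd)
    matches = 0
    cols = 0
    i = bi
    d = bd
    state = 0  # 0=H, 1=E (gap in ref / up), 2=F (gap in query / left)
    while i > 0:
        j = i - band + d
        if j < 1:
            break
        h = H[i, d + 1]
        if state == 0:
            if h == 0:
                break
            if h == E[i, d + 1]:
                state = 1
                continue
            if h == Fm[i, d + 1]:
                state = 2
                continue
            s = match if (q[i - 1] == ref[j - 1] and q[i - 1] < 4) else mismatch
            cols += 1
            if s == match:
                matches += 1
            i -= 1
            # d stays (diagonal move keeps j - i constant)
        elif state == 1:
            # came from (i-1, j): gap in ref
            cols += 1
            prevE = E[i - 1, d + 2] - gap_ext
            if E[i, d + 1] == prevE:
                state = 1
            else:
                state = 0
            i -= 1
            d += 1
        else:
            # came from (i, j-1): gap in query
            cols += 1
            prevF = Fm[i, d] - gap_ext
            if Fm[i, d + 1] == prevF:
                state = 2
            else:
                state = 0
            d -= 1
    return best, matches, cols
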