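"""Numba-compiled dynamic-programming kernels.

These are internal: the public surfaces live in :mod:`pairwise_similarity`
(Smith-Waterman) and :mod:`profile_hmm` (Viterbi / forward).  All kernels are
plain loops over preallocated arrays so they compile in nopython mode.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def sw_affine(a, b, scores, gap_open, gap_extend):
    """Best local alignment of integer-encoded ``a`` vs ``b`` (Gotoh).

    Gap of length L costs gap_open + L*gap_extend.  Returns
    ``(score, a_start, a_end, b_start, b_end)`` with 0-based half-open
    intervals; score 0 means no positive-scoring alignment exists.
    State preference on ties is M (diagonal), then X (gap in b, vertical),
    then Y (gap in a, horizontal) - the deterministic "high road".
    """
    n = a.shape[0]
    m = b.shape[0]
    BIGNEG = np.int64(-(10 ** 15))
    M = np.zeros((n + 1, m + 1), np.int64)
    X = np.full((n + 1, m + 1), BIGNEG, np.int64)
    Y = np.full((n + 1, m + 1), BIGNEG, np.int64)
    # pointer codes: M-cell 0=fresh start, 1=from M, 2=from X, 3=from Y
    #                X-cell 1=from M, 2=from X ; Y-cell 1=from M, 3=from Y
    pM = np.zeros((n + 1, m + 1), np.uint8)
    pX = np.zeros((n + 1, m + 1), np.uint8)
    pY = np.zeros((n + 1, m + 1), np.uint8)
    go = np.int64(gap_open + gap_extend)
    ge = np.int64(gap_extend)
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = scores[ai, b[j - 1]]
            # match state: best predecessor at (i-1, j-1), tie pref M>X>Y
            prev = M[i - 1, j - 1]
            code = 1
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
                code = 2
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
                code = 3
            if prev <= 0:  # starting fresh is at least as good
                prev = 0
                code = 0
            v = prev + s
            if v < 0:  # dead cell, never on a traceback path
                v = 0
                code = 0
            M[i, j] = v
            pM[i, j] = code
            # X: gap in b (consume a[i-1]); open from M or extend X
            vo = M[i - 1, j] - go
            ve = X[i - 1, j] - ge
            if vo >= ve:
                X[i, j] = vo
                pX[i, j] = 1
            else:
                X[i, j] = ve
                pX[i, j] = 2
            # Y: gap in a (consume b[j-1])
            vo = M[i, j - 1] - go
            ve = Y[i, j - 1] - ge
            if vo >= ve:
                Y[i, j] = vo
                pY[i, j] = 1
            else:
                Y[i, j] = ve
                pY[i, j] = 3
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    if best <= 0:
        return np.int64(0), 0, 0, 0, 0
    # traceback from (bi, bj) in M to the fresh-start cell
    i = bi
    j = bj
    st = 0  # 0=M, 1=X, 2=Y
    while True:
        if st == 0:
            c = pM[i, j]
            i -= 1
            j -= 1
            if c == 0:
                break
            st = 0 if c == 1 else (1 if c == 2 else 2)
        elif st == 1:
            c = pX[i, j]
            i -= 1
            st = 0 if c == 1 else 1
        else:
            c = pY[i, j]
            j -= 1
            st = 0 if c == 1 else 2
    return best, i, bi, j, bj


@njit(cache=True)
def sw_score_only(a, b, scores, gap_open, gap_extend):
    """Score-only Smith-Waterman (linear memory), same conventions."""
    n = a.shape[0]
    m = b.shape[0]
    BIGNEG = np.int64(-(10 ** 15))
    go = np.int64(gap_open + gap_extend)
    ge = np.int64(gap_extend)
    Mprev = np.zeros(m + 1, np.int64)
    Xprev = np.full(m + 1, BIGNEG, np.int64)
    Mcur = np.zeros(m + 1, np.int64)
    Xcur = np.empty(m + 1, np.int64)
    best = np.int64(0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mcur[0] = 0
        Xcur[0] = BIGNEG
        y = BIGNEG
        for j in range(1, m + 1):
            prev = Mprev[j - 1]
            if Xprev[j - 1] > prev:
                prev = Xprev[j - 1]
            yp = y  # Y[i, j-1]
            if yp > prev:
                prev = yp
            v = prev + scores[ai, b[j - 1]]
            if v < 0:
                v = 0
            x = Mprev[j] - go
            if Xprev[j] - ge > x:
                x = Xprev[j] - ge
            ynew = Mcur[j - 1] - go
            if y - ge > ynew:
                ynew = y - ge
            y = ynew
            Mcur[j] = v
            Xcur[j] = x
            if v > best:
                best = v
        tmp = Mprev
        Mprev = Mcur
        Mcur = tmp
        tmp = Xprev
        Xprev = Xcur
        Xcur = tmp
    return best


@njit(cache=True)
def pssm_best_window(seq, pssm):
    """Best ungapped window score of ``pssm`` (W x 21) along ``seq``.

    Returns (score, start).  Sequences shorter than the profile width get
    score -inf (no valid placement).
    """
    L = seq.shape[0]
    W = pssm.shape[0]
    if L < W:
        return NEG, -1
    best = NEG
    bs = 0
    for s in range(L - W + 1):
        tot = 0.0
        for k in range(W):
            tot += pssm[k, seq[s + k]]
        if tot > best:
            best = tot
            bs = s
    return best, bs


@njit(cache=True)
def hmm_viterbi(seq, me, tMM, tMI, tMD, tIM, tII, tDM, tDD,
                lp_nn, lp_nb, lp_cc, lp_ce):
    """Viterbi for the Plan-7-like profile (global model, local sequence).

    ``me`` is (K+1, 21) match emission log-odds with row 0 unused; transition
    arrays are indexed so tMM[k] is M_k -> M_{k+1} with M_0 = B and
    M_{K} -> E at k = K.  Flank states N and C emit at background (log-odds
    0) with per-residue loop cost lp_nn / lp_cc; N -> B costs lp_nb and
    C -> end costs lp_ce.  All parameters share one log base.

    Returns (score, start, end) where [start, end) is the residue interval
    emitted by core (match/insert) states, plus pointer arrays for path
    reconstruction.
    """
    L = seq.shape[0]
    K = me.shape[0] - 1
    vM = np.full((L + 1, K + 1), NEG)
    vI = np.full((L + 1, K + 1), NEG)
    vD = np.full((L + 1, K + 1), NEG)
    # pointer codes: M 0=from B, 1=M, 2=I, 3=D ; I 1=M, 2=I ; D 0=B, 1=M, 2=D
    pMp = np.zeros((L + 1, K + 1), np.uint8)
    pIp = np.zeros((L + 1, K + 1), np.uint8)
    pDp = np.zeros((L + 1, K + 1), np.uint8)
    for j in range(0, L + 1):
        vB = j * lp_nn + lp_nb  # N emitted j residues then entered B
        if j >= 1:
            x = seq[j - 1]
            for k in range(1, K + 1):
                # match state k consumes x
                bestv = NEG
                code = np.uint8(1)
                if k == 1:
                    bestv = (j - 1) * lp_nn + lp_nb + tMM[0]
                    code = np.uint8(0)
                else:
                    v = vM[j - 1, k - 1] + tMM[k - 1]
                    if v > bestv:
                        bestv = v
                        code = np.uint8(1)
                    v = vI[j - 1, k - 1] + tIM[k - 1]
                    if v > bestv:
                        bestv = v
                        code = np.uint8(2)
                if k >= 2:
                    v = vD[j - 1, k - 1] + tDM[k - 1]
                    if v > bestv:
                        bestv = v
                        code = np.uint8(3)
                vM[j, k] = bestv + me[k, x]
                pMp[j, k] = code
                # insert state k (1..K-1) consumes x at background odds 0
                if 1 <= k <= K - 1:
                    v1 = vM[j - 1, k] + tMI[k]
                    v2 = vI[j - 1, k] + tII[k]
                    if v1 >= v2:
                        vI[j, k] = v1
                        pIp[j, k] = 1
                    else:
                        vI[j, k] = v2
                        pIp[j, k] = 2
        # delete chain at this j (non-emitting), increasing k
        for k in range(1, K + 1):
            if k == 1:
                vD[j, 1] = vB + tMD[0]
                pDp[j, 1] = 0
            else:
                v1 = vM[j, k - 1] + tMD[k - 1]
                v2 = vD[j, k - 1] + tDD[k - 1]
                if v1 >= v2:
                    vD[j, k] = v1
                    pDp[j, k] = 1
                else:
                    vD[j, k] = v2
                    pDp[j, k] = 2
    # exit: E at position j, then C emits L-j residues
    best = NEG
    bj = 0
    from_d = False
    for j in range(0, L + 1):
        vE = vM[j, K] + tMM[K]
        d = vD[j, K] + tDM[K]
        fd = False
        if d > vE:
            vE = d
            fd = True
        tot = vE + (L - j) * lp_cc + lp_ce
        if tot > best:
            best = tot
            bj = j
            from_d = fd
    return best, bj, from_d, pMp, pIp, pDp, vM, vI, vD


@njit(cache=True)
def hmm_forward(seq, me, tMM, tMI, tMD, tIM, tII, tDM, tDD,
                lp_nn, lp_nb, lp_cc, lp_ce):
    """Forward log-odds score (same parameterisation as :func:`hmm_viterbi`).

    Log-sum-exp over all paths; parameters must be natural-log values.
    """
    L = seq.shape[0]
    K = me.shape[0] - 1
    fM = np.full((L + 1, K + 1), NEG)
    fI = np.full((L + 1, K + 1), NEG)
    fD = np.full((L + 1, K + 1), NEG)
    for j in range(0, L + 1):
        vB = j * lp_nn + lp_nb
        if j >= 1:
            x = seq[j - 1]
            for k in range(1, K + 1):
                if k == 1:
                    acc = (j - 1) * lp_nn + lp_nb + tMM[0]
                else:
                    acc = np.logaddexp(vM_term(fM[j - 1, k - 1], tMM[k - 1]),
                                       vM_term(fI[j - 1, k - 1], tIM[k - 1]))
                    acc = np.logaddexp(acc, vM_term(fD[j - 1, k - 1], tDM[k - 1]))
                fM[j, k] = acc + me[k, x]
                if 1 <= k <= K - 1:
                    fI[j, k] = np.logaddexp(vM_term(fM[j - 1, k], tMI[k]),
                                            vM_term(fI[j - 1, k], tII[k]))
        for k in range(1, K + 1):
            if k == 1:
                fD[j, 1] = vB + tMD[0]
            else:
                fD[j, k] = np.logaddexp(vM_term(fM[j, k - 1], tMD[k - 1]),
                                        vM_term(fD[j, k - 1], tDD[k - 1]))
    total = NEG
    for j in range(0, L + 1):
        vE = np.logaddexp(vM_term(fM[j, K], tMM[K]), vM_term(fD[j, K], tDM[K]))
        total = np.logaddexp(total, vE + (L - j) * lp_cc + lp_ce)
    return total


@njit(cache=True, inline="always")
def vM_term(v, t):
    if v <= NEG / 2:
        return NEG
    return v + t
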