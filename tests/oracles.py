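"""Independent reference implementations used only to check the package.

Each oracle is written from the mathematical definition with no shared code
paths: a plain-matrix affine-gap local alignment DP, breadth-first-search
connected components, and an exhaustive state-path enumerator for small
profile HMMs.
"""

from __future__ import annotations

import math

import numpy as np

from hoxclans.alphabet import encode

LOG0 = -1e30


def sw_score_plain(a: str, b: str, scores, gap_open: int, gap_extend: int) -> int:
    """Smith-Waterman best local score; gap of length L costs open + L*ext."""
    A, B = encode(a), encode(b)
    n, m = len(A), len(B)
    go = gap_open + gap_extend
    ge = gap_extend
    M = [[0] * (m + 1) for _ in range(n + 1)]
    X = [[-(10 ** 12)] * (m + 1) for _ in range(n + 1)]
    Y = [[-(10 ** 12)] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0)
            M[i][j] = max(0, prev + int(scores[A[i - 1], B[j - 1]]))
            X[i][j] = max(M[i - 1][j] - go, X[i - 1][j] - ge)
            Y[i][j] = max(M[i][j - 1] - go, Y[i][j - 1] - ge)
            best = max(best, M[i][j])
    return best


def bfs_components(nodes, edges):
    """Connected components via explicit breadth-first search."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = set()
    comps = []
    for n in nodes:
        if n in seen:
            continue
        queue = [n]
        seen.add(n)
        comp = {n}
        while queue:
            cur = queue.pop(0)
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


def _logsumexp2(vals):
    vals = [v for v in vals if v > LOG0 / 2]
    if not vals:
        return LOG0
    m = max(vals)
    return m + math.log2(sum(2.0 ** (v - m) for v in vals))


def enumerate_hmm_scores(hmm, seq: str):
    """Exhaustive path enumeration for a small profile HMM.

    Returns ``(forward_bits, viterbi_bits)``: log2 of the summed / maximal
    path odds P(x, path | model) / P(x | background), walking the exact
    state graph (N loop, B, M/I/D chain, E, C loop) by brute force.
    """
    x = encode(seq)
    L = len(x)
    K = hmm.n_match
    bg = hmm.background
    lg = lambda p: math.log2(p) if p > 0 else LOG0

    if hmm.flank_loop is None:
        lp_nn = lp_cc = LOG0
        lp_nb = lp_ce = 0.0
    elif hmm.flank_loop == "adaptive":
        p = L / (L + 2.0)
        lp_nn = lp_cc = math.log2(p)
        lp_nb = lp_ce = math.log2(1.0 - p)
    else:
        p = float(hmm.flank_loop)
        lp_nn = lp_cc = math.log2(p)
        lp_nb = lp_ce = math.log2(1.0 - p)

    em = np.log2(np.maximum(hmm.match_emissions, 1e-300)) - np.log2(bg)

    complete: list[float] = []

    def finish(pos: int, acc: float) -> None:
        # E reached having consumed pos residues; C emits the rest
        complete.append(acc + (L - pos) * lp_cc + lp_ce)

    def step(state: str, k: int, pos: int, acc: float) -> None:
        if acc <= LOG0 / 2:
            return
        if state == "M":
            if k == K:
                finish(pos, acc + lg(hmm.tMM[K]))
            else:
                if pos < L:
                    step("M", k + 1, pos + 1,
                         acc + lg(hmm.tMM[k]) + em[k + 1, x[pos]])
                    if 1 <= k <= K - 1:
                        step("I", k, pos + 1, acc + lg(hmm.tMI[k]))
                step("D", k + 1, pos, acc + lg(hmm.tMD[k]))
        elif state == "I":
            if pos < L:
                step("M", k + 1, pos + 1,
                     acc + lg(hmm.tIM[k]) + em[k + 1, x[pos]])
                step("I", k, pos + 1, acc + lg(hmm.tII[k]))
        elif state == "D":
            if k == K:
                finish(pos, acc + lg(hmm.tDM[K]))
            else:
                if pos < L:
                    step("M", k + 1, pos + 1,
                         acc + lg(hmm.tDM[k]) + em[k + 1, x[pos]])
                step("D", k + 1, pos, acc + lg(hmm.tDD[k]))

    for j in range(0, L + 1):
        entry = j * lp_nn + lp_nb
        if entry <= LOG0 / 2:
            continue
        # B -> M1 (consuming x[j]) or B -> D1
        if j < L:
            step("M", 1, j + 1, entry + lg(hmm.tMM[0]) + em[1, x[j]])
        step("D", 1, j, entry + lg(hmm.tMD[0]))

    forward = _logsumexp2(complete)
    viterbi = max(complete) if complete else LOG0
    return forward, viterbi
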