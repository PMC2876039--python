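"""Local pairwise alignment, alignment statistics and profile retrieval.

This module is the BLAST-like engine of the pipeline: exact Smith-Waterman
local alignment with affine gaps, Karlin-Altschul significance for the
resulting high-scoring segment pairs (HSPs), all-vs-all edge computation,
exact-duplicate removal, and an iterative PSSM homolog search that plays the
role of PSI-BLAST against a desk-scale database.

Statistics
----------
Ungapped Karlin-Altschul theory is used throughout: ``lambda`` is the unique
positive root of ``sum_ij p_i p_j exp(lambda * s_ij) = 1`` and
``E = K * m * n * exp(-lambda * S)`` with ``P = 1 - exp(-E)``.  Gapped
alignments reuse the ungapped parameters (a documented approximation; the
exact gapped values would require simulation).  Search-space sizes ``m, n``
are the raw sequence lengths with no edge-effect correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .alphabet import ProteinRecord, decode, encode, robinson_background
from .scoring import SubstitutionMatrix
from . import _kernels

__all__ = [
    "AlignmentStats", "HSP", "PSSM", "ProfileSearchResult",
    "karlin_altschul_params", "sw_align", "hsp_significance", "all_vs_all",
    "dedup", "build_pssm", "iterative_profile_search",
    "write_edges", "read_edges",
]


@dataclass(frozen=True)
class AlignmentStats:
    """Karlin-Altschul parameters for a scoring system."""

    lam: float          # scale, nats per score unit
    K: float            # search-space prefactor
    H: float            # relative entropy per aligned pair, nats
    background: np.ndarray


@dataclass(frozen=True)
class HSP:
    """A scored local alignment (high-scoring segment pair).

    Intervals are 0-based half-open on each sequence.  ``m`` and ``n`` are
    the search-space lengths used when significance was assigned.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    raw_score: int
    bit_score: float = float("nan")
    evalue: float = float("nan")
    pvalue: float = float("nan")
    m: int = 0
    n: int = 0


def _score_distribution(matrix: SubstitutionMatrix, background: np.ndarray):
    """Distribution of the per-pair score under the background model."""
    smin = int(matrix.scores.min())
    smax = int(matrix.scores.max())
    probs = np.zeros(smax - smin + 1)
    outer = np.outer(background, background)
    for s in range(smin, smax + 1):
        probs[s - smin] = outer[matrix.scores == s].sum()
    return smin, probs


def karlin_altschul_params(
    matrix: SubstitutionMatrix,
    background: np.ndarray | None = None,
    k_series_terms: int = 40,
) -> AlignmentStats:
    """Solve for the ungapped Karlin-Altschul parameters of a matrix.

    ``lambda`` is found by bisection to 1e-12.  ``K`` uses the classical
    renewal-series approximation

        K = delta * lambda * exp(-2*sigma) / (H * (1 - exp(-lambda*delta)))

    with ``sigma = sum_{k=1..k_series_terms} (1/k) * [P(S_k >= 0) +
    E(exp(lambda*S_k); S_k < 0)]`` where ``S_k`` is a sum of ``k``
    independent per-pair scores and ``delta`` the score-lattice span; the
    series is truncated at ``k_series_terms`` (default 40), by which point
    terms are negligible for any sensible matrix.

    Raises
    ------
    ValueError
        If the expected score is non-negative or no positive score is
        achievable (the Karlin-Altschul regime does not apply).
    """
    p = robinson_background() if background is None else np.asarray(background, float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("background must be a probability vector")
    exp_score = matrix.expected_score(p)
    if exp_score >= 0:
        raise ValueError("expected score must be negative for local statistics")
    if matrix.scores.max() <= 0:
        raise ValueError("a positive score must be achievable")

    smin, probs = _score_distribution(matrix, p)
    svals = np.arange(smin, smin + len(probs))

    def f(lam: float) -> float:
        return float(probs @ np.exp(lam * svals)) - 1.0

    lo, hi = 0.0, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e3:  # pragma: no cover - defensive
            raise ValueError("no positive lambda root found")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if hi - lo < 1e-12:
            break
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    lam = 0.5 * (lo + hi)

    q = probs * np.exp(lam * svals)
    H = float(lam * (q @ svals))

    support = svals[probs > 0]
    delta = int(np.gcd.reduce(np.abs(np.diff(support)).astype(int))) if len(support) > 1 else 1

    # sigma series via repeated self-convolution of the score distribution
    sigma = 0.0
    dist = probs.copy()
    lo_k = smin
    for k in range(1, k_series_terms + 1):
        sk = np.arange(lo_k, lo_k + len(dist))
        neg = sk < 0
        term = dist[~neg].sum() + float(dist[neg] @ np.exp(lam * sk[neg]))
        sigma += term / k
        dist = np.convolve(dist, probs)
        lo_k += smin
    K = delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * delta)))
    return AlignmentStats(lam=lam, K=K, H=H, background=p)


def _as_record(x, default_id: str) -> ProteinRecord:
    return x if isinstance(x, ProteinRecord) else ProteinRecord(default_id, str(x))


def sw_align(a, b, matrix: SubstitutionMatrix) -> HSP | None:
    """Best-scoring Smith-Waterman local alignment of two sequences.

    Accepts :class:`ProteinRecord` or plain strings.  Returns ``None`` when
    no positive-scoring local alignment exists (e.g. an empty sequence).
    Unknown residues raise ``ValueError`` naming the character and position.
    """
    ra, rb = _as_record(a, "query"), _as_record(b, "subject")
    if len(ra.seq) == 0 or len(rb.seq) == 0:
        return None
    ea, eb = encode(ra.seq), encode(rb.seq)
    score, a0, a1, b0, b1 = _kernels.sw_affine(
        ea, eb, matrix.scores, matrix.gap_open, matrix.gap_extend
    )
    if score <= 0:
        return None
    return HSP(ra.id, rb.id, int(a0), int(a1), int(b0), int(b1), int(score))


def hsp_significance(hsp: HSP, m: int, n: int, stats: AlignmentStats) -> HSP:
    """Fill E-value, P-value and bit score for an HSP.

    ``E = K*m*n*exp(-lambda*S)``, ``P = 1 - exp(-E)`` and
    ``bits = (lambda*S - ln K) / ln 2``.
    """
    E = stats.K * m * n * math.exp(-stats.lam * hsp.raw_score)
    P = -math.expm1(-E)
    bits = (stats.lam * hsp.raw_score - math.log(stats.K)) / math.log(2.0)
    return replace(hsp, evalue=E, pvalue=P, bit_score=bits, m=m, n=n)


def all_vs_all(
    records: Sequence[ProteinRecord],
    matrix: SubstitutionMatrix,
    stats: AlignmentStats,
    store_p_max: float = 1e-2,
) -> list[HSP]:
    """One significance-annotated edge per unordered pair of records.

    The substitution matrix is symmetric, so the single Smith-Waterman
    score is the better of the two search directions.  Edges are emitted in
    lexicographic (query_id, subject_id) order with query_id < subject_id;
    self-pairs are skipped and edges with ``P > store_p_max`` are dropped.
    """
    if len(records) < 2:
        raise ValueError("all_vs_all needs at least two records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record ids: {', '.join(dup)}")
    ordered = sorted(records, key=lambda r: r.id)
    encoded = {r.id: encode(r.seq) for r in ordered}
    out: list[HSP] = []
    for i, ra in enumerate(ordered):
        ea = encoded[ra.id]
        for rb in ordered[i + 1:]:
            eb = encoded[rb.id]
            if len(ea) == 0 or len(eb) == 0:
                continue
            score, a0, a1, b0, b1 = _kernels.sw_affine(
                ea, eb, matrix.scores, matrix.gap_open, matrix.gap_extend
            )
            if score <= 0:
                continue
            hsp = HSP(ra.id, rb.id, int(a0), int(a1), int(b0), int(b1), int(score))
            hsp = hsp_significance(hsp, len(ra.seq), len(rb.seq), stats)
            if hsp.pvalue <= store_p_max:
                out.append(hsp)
    return out


def dedup(records: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    """Remove exact full-sequence duplicates, keeping first occurrences.

    The criterion is exact string equality of the residue sequence; input
    order is otherwise preserved.
    """
    seen: set[str] = set()
    out = []
    for r in records:
        if r.seq not in seen:
            seen.add(r.seq)
            out.append(r)
    return out


@dataclass(frozen=True)
class PSSM:
    """Position-specific scoring matrix in natural-log odds.

    ``scores`` is (width, 21); column 20 (mask sentinel) scores 0 so masked
    residues are neutral.  ``included_ids`` records which sequences beyond
    the seeds contributed to the profile.
    """

    width: int
    scores: np.ndarray
    alpha: float
    included_ids: frozenset


def build_pssm(
    segments: Sequence[str],
    background: np.ndarray,
    alpha: float = 1.0,
    included_ids: frozenset = frozenset(),
) -> PSSM:
    """Pseudocounted log-odds profile from equal-length ungapped segments.

    Column frequencies are ``(counts + alpha * background) / (n + alpha)``
    (background-mixed Laplace smoothing with total weight ``alpha``).
    """
    widths = {len(s) for s in segments}
    if len(widths) != 1:
        raise ValueError("profile segments must share a single width")
    W = widths.pop()
    n = len(segments)
    counts = np.zeros((W, 20))
    for s in segments:
        idx = encode(s)
        counts[np.arange(W), idx] += 1.0
    freqs = (counts + alpha * background) / (n + alpha)
    scores = np.zeros((W, 21))
    scores[:, :20] = np.log(freqs / background)
    return PSSM(W, scores, alpha, frozenset(included_ids))


@dataclass
class ProfileSearchResult:
    """Outcome of :func:`iterative_profile_search`."""

    hits: dict            # record_id -> best E ever observed (E < gather_e)
    iterations: int
    converged: bool
    included_history: list  # frozenset of included ids per iteration
    gathered_history: list  # frozenset of ids gathered so far, per iteration
    final_pssm: PSSM


def iterative_profile_search(
    seed_records: Sequence[ProteinRecord],
    database: Sequence[ProteinRecord],
    background: np.ndarray | None = None,
    inclusion_e: float = 1e-5,
    gather_e: float = 10.0,
    max_iters: int = 50,
    alpha: float = 1.0,
    K: float = 0.1,
) -> ProfileSearchResult:
    """PSI-BLAST-like iterative homolog retrieval against a database.

    The seeds are the rows of a gapless seed-region alignment (all one
    length W).  Each iteration scores every database sequence with the best
    ungapped W-residue window of the current pseudocounted log-odds
    profile; hits with ``E < inclusion_e`` contribute their best window to
    the next profile.  Iteration stops at a fixed point of the included id
    set ("convergence") or after ``max_iters`` passes.  Every database
    record that ever achieves ``E < gather_e`` is returned with its best E.

    Because profile scores are natural-log odds, the Karlin-Altschul scale
    is ``lambda = 1`` and ``E = K * n_windows * exp(-S)`` with ``n_windows``
    the total number of W-windows in the database and ``K`` a fixed
    prefactor (default 0.1).
    """
    if inclusion_e >= gather_e:
        raise ValueError("inclusion_e must be stricter (smaller) than gather_e")
    if not seed_records or not database:
        raise ValueError("seeds and database must be non-empty")
    bg = robinson_background() if background is None else background
    seed_rows = [r.seq for r in seed_records]
    W = len(seed_rows[0])
    encoded = [(r.id, encode(r.seq)) for r in database]
    n_windows = sum(max(len(e) - W + 1, 0) for _, e in encoded)

    included: dict[str, str] = {}
    hits: dict[str, float] = {}
    history: list[frozenset] = []
    gathered_history: list[frozenset] = []
    converged = False
    it = 0
    pssm = build_pssm(seed_rows, bg, alpha)
    for it in range(1, max_iters + 1):
        pssm = build_pssm(
            seed_rows + [included[i] for i in sorted(included)], bg, alpha,
            included_ids=frozenset(included),
        )
        new_included: dict[str, str] = {}
        for rid, eseq in encoded:
            S, start = _kernels.pssm_best_window(eseq, pssm.scores)
            if start < 0:
                continue
            E = K * n_windows * math.exp(-S)
            if E < gather_e:
                hits[rid] = min(hits.get(rid, math.inf), E)
            if E < inclusion_e:
                new_included[rid] = decode(eseq[start:start + W])
        history.append(frozenset(new_included))
        gathered_history.append(frozenset(hits))
        if set(new_included) == set(included):
            converged = True
            included = new_included
            break
        included = new_included
    return ProfileSearchResult(hits, it, converged, history,
                               gathered_history, pssm)


_EDGE_COLUMNS = ("query_id", "subject_id", "raw_score", "bit_score",
                 "evalue", "pvalue", "q_start", "q_end", "s_start", "s_end")


def write_edges(hsps: Sequence[HSP], path, header_comment: str | None = None) -> None:
    """Tab-separated edge list (one HSP per line)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(_EDGE_COLUMNS) + "\n")
        for h in hsps:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.raw_score}\t{h.bit_score:.4f}"
                f"\t{h.evalue:.6e}\t{h.pvalue:.6e}\t{h.q_start}\t{h.q_end}"
                f"\t{h.s_start}\t{h.s_end}\n"
            )


def read_edges(path) -> list[HSP]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("query_id"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 10:
                raise ValueError(f"malformed edge line: {line!r}")
            out.append(HSP(f[0], f[1], int(f[6]), int(f[7]), int(f[8]), int(f[9]),
                           int(f[2]), float(f[3]), float(f[4]), float(f[5])))
    return out
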