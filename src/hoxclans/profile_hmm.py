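"""Profile hidden Markov models for homeodomain-style region extraction.

The architecture is Plan-7-like: match/insert/delete core states estimated
from a seed alignment, flanked by background self-loop states (N before, C
after) so a model that is *global over the model* can still be placed
*locally within a longer sequence*.  Scores are log-odds against the
background composition, reported in bits.

Calibration follows classic HMMER-2 semantics: Viterbi scores of random
background sequences are fitted to a Gumbel (extreme-value) distribution by
maximum likelihood, and ``E(score, N) = N * SF_Gumbel(score)`` converts a
score into an expected number of chance hits in a database of N sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .alphabet import MASK_INDEX, ProteinRecord, encode, robinson_background
from . import _kernels

GAP_CHARS = set("-.")
_LN2 = math.log(2.0)

__all__ = [
    "ProfileHMM", "HMMCalibration", "RegionHit",
    "build_hmm", "forward_score", "viterbi_search", "calibrate",
    "find_domains", "multi_domain_filter", "extract_region",
    "save_hmm", "load_hmm", "write_region_hits", "read_region_hits",
]


@dataclass(frozen=True)
class RegionHit:
    """A model placement on a sequence (0-based half-open residue interval)."""

    record_id: str
    start: int
    end: int
    score_bits: float
    evalue: float = float("nan")


@dataclass
class ProfileHMM:
    """Plan-7-like profile with background flank loops.

    Transition arrays are indexed with the begin state as a virtual match
    state M_0 and the end state reached from M_K / D_K:

    - ``tMM[k]``: M_k -> M_{k+1} for k = 0..K (k = K is M_K -> E)
    - ``tMI[k]``, ``tIM[k]``, ``tII[k]``: defined for k = 1..K-1
    - ``tMD[k]``: M_k -> D_{k+1} for k = 0..K-1
    - ``tDM[k]``: D_k -> M_{k+1} for k = 1..K (k = K is D_K -> E)
    - ``tDD[k]``: defined for k = 1..K-1

    ``flank_loop`` is the self-loop probability of N and C: a float fixes
    it, ``None`` disables the flanks (the whole sequence must be emitted
    by the core) and the default ``"adaptive"`` sets it per target to
    ``L/(L+2)`` so the total flank cost is essentially independent of
    sequence length (the HMMER convention, which keeps null scores
    length-stable up to the Gumbel ln L drift).
    """

    n_match: int
    match_emissions: np.ndarray      # (K+1, 20), row 0 unused
    insert_emissions: np.ndarray     # (20,) == background
    tMM: np.ndarray
    tMI: np.ndarray
    tMD: np.ndarray
    tIM: np.ndarray
    tII: np.ndarray
    tDM: np.ndarray
    tDD: np.ndarray
    background: np.ndarray
    flank_loop: object = "adaptive"
    name: str = "profile"

    def __post_init__(self) -> None:
        K = self.n_match
        em = self.match_emissions
        if em.shape != (K + 1, 20):
            raise ValueError("match_emissions must be (n_match+1, 20)")
        if not np.allclose(em[1:].sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("match emissions must sum to 1")
        if not math.isclose(self.insert_emissions.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("insert emissions must sum to 1")
        # outgoing transition distributions must sum to 1 per state
        checks = [self.tMM[0] + self.tMD[0] - 1.0, self.tMM[K] - 1.0]
        if K >= 1:
            checks.append(self.tDM[K] - 1.0)
        for k in range(1, K):
            checks.append(self.tMM[k] + self.tMI[k] + self.tMD[k] - 1.0)
            checks.append(self.tIM[k] + self.tII[k] - 1.0)
            checks.append(self.tDM[k] + self.tDD[k] - 1.0)
        if np.max(np.abs(checks)) > 1e-9:
            raise ValueError("state transition distributions must sum to 1")
        self._prepare_log()

    def _prepare_log(self) -> None:
        """Natural-log parameter arrays consumed by the DP kernels."""
        NEG = _kernels.NEG
        K = self.n_match
        me = np.full((K + 1, 21), NEG)
        with np.errstate(divide="ignore"):
            me[1:, :20] = np.log(self.match_emissions[1:] / self.background)
        me[np.isneginf(me)] = NEG
        me[:, MASK_INDEX] = NEG  # masked residues can never be matched

        def safelog(v):
            a = np.asarray(v, dtype=float)
            out = np.full(a.shape, NEG)
            np.log(a, out=out, where=a > 0)
            return out

        self._me = me
        self._ltMM = safelog(self.tMM)
        self._ltMI = safelog(self.tMI)
        self._ltMD = safelog(self.tMD)
        self._ltIM = safelog(self.tIM)
        self._ltII = safelog(self.tII)
        self._ltDM = safelog(self.tDM)
        self._ltDD = safelog(self.tDD)
        if self.flank_loop is None:
            self._lp_nn = NEG
            self._lp_nb = 0.0
        elif self.flank_loop == "adaptive":
            self._lp_nn = None  # computed per target in _kernel_args
            self._lp_nb = None
        else:
            p = float(self.flank_loop)
            if not (0.0 < p < 1.0):
                raise ValueError("flank_loop must be in (0, 1), None or 'adaptive'")
            self._lp_nn = math.log(p)
            self._lp_nb = math.log(1.0 - p)

    def _kernel_args(self, eseq: np.ndarray):
        if self.flank_loop == "adaptive":
            L = max(int(eseq.shape[0]), 1)
            lp_nn = math.log(L / (L + 2.0))
            lp_nb = math.log(2.0 / (L + 2.0))
        else:
            lp_nn, lp_nb = self._lp_nn, self._lp_nb
        return (eseq, self._me, self._ltMM, self._ltMI, self._ltMD,
                self._ltIM, self._ltII, self._ltDM, self._ltDD,
                lp_nn, lp_nb, lp_nn, lp_nb)


def _rows_of(alignment) -> list[tuple[str, str]]:
    rows = []
    for i, row in enumerate(alignment):
        if isinstance(row, tuple):
            rows.append((row[0], row[1].upper()))
        else:
            rows.append((f"row{i}", str(row).upper()))
    return rows


def build_hmm(
    alignment,
    match_column_gap_frac: float = 0.5,
    pseudocount_alpha: float = 1.0,
    background: np.ndarray | None = None,
    flank_loop: object = "adaptive",
    transition_pseudocount: float = 1.0,
    name: str = "profile",
) -> ProfileHMM:
    """Estimate a profile HMM from a (possibly gapped) seed alignment.

    Columns whose gap fraction is <= ``match_column_gap_frac`` become match
    states.  Match emissions are background-mixed pseudocounted column
    frequencies ``(counts + alpha*b) / (n_obs + alpha)``.  Transitions are
    counted from each row's match/insert/delete state path and smoothed
    with an informative Dirichlet prior of total weight
    ``transition_pseudocount`` per state (match: 0.90/0.05/0.05 over
    M/I/D, insert: 0.8/0.2 over M/I, delete: 0.85/0.15 over M/D): states
    never observed in the alignment therefore still make gap opening and
    especially gap extension expensive, which keeps domain boundaries
    sharp on diverged targets.  Residues in insert columns before the
    first or after the last match column belong to the flanks and are
    ignored; the rare illegal Plan-7 adjacencies (I->D, D->I) observed in
    a row are skipped when counting.
    """
    rows = _rows_of(alignment)
    if not rows:
        raise ValueError("empty alignment")
    width = len(rows[0][1])
    if width == 0 or any(len(r) != width for _, r in rows):
        raise ValueError("alignment rows must share a single positive width")
    bg = robinson_background() if background is None else background
    n_rows = len(rows)

    gap_frac = np.array(
        [sum(r[c] in GAP_CHARS for _, r in rows) / n_rows for c in range(width)]
    )
    match_cols = [c for c in range(width) if gap_frac[c] <= match_column_gap_frac]
    K = len(match_cols)
    if K == 0:
        raise ValueError("no match columns at this gap threshold")
    col_of = {c: k + 1 for k, c in enumerate(match_cols)}

    # --- emissions -------------------------------------------------------
    em = np.zeros((K + 1, 20))
    for c in match_cols:
        k = col_of[c]
        counts = np.zeros(20)
        for _, r in rows:
            if r[c] not in GAP_CHARS:
                counts[encode(r[c])[0]] += 1.0
        n_obs = counts.sum()
        em[k] = (counts + pseudocount_alpha * bg) / (n_obs + pseudocount_alpha)

    # --- transitions -----------------------------------------------------
    cMM = np.zeros(K + 1)
    cMI = np.zeros(K + 1)
    cMD = np.zeros(K + 1)
    cIM = np.zeros(K + 1)
    cII = np.zeros(K + 1)
    cDM = np.zeros(K + 1)
    cDD = np.zeros(K + 1)
    first_mc, last_mc = match_cols[0], match_cols[-1]
    for _, r in rows:
        path: list[tuple[str, int]] = [("M", 0)]  # begin state
        for c in range(first_mc, last_mc + 1):
            if c in col_of:
                k = col_of[c]
                path.append(("M", k) if r[c] not in GAP_CHARS else ("D", k))
            elif r[c] not in GAP_CHARS:
                path.append(("I", path[-1][1]))
        path.append(("M", K + 1))  # end state
        for (s1, k1), (s2, k2) in zip(path, path[1:]):
            if s1 in ("M",) and s2 == "M" and k2 == k1 + 1:
                cMM[k1] += 1
            elif s1 == "M" and s2 == "I" and k2 == k1:
                cMI[k1] += 1
            elif s1 == "M" and s2 == "D" and k2 == k1 + 1:
                cMD[k1] += 1
            elif s1 == "I" and s2 == "M" and k2 == k1 + 1:
                cIM[k1] += 1
            elif s1 == "I" and s2 == "I" and k2 == k1:
                cII[k1] += 1
            elif s1 == "D" and s2 == "M" and k2 == k1 + 1:
                cDM[k1] += 1
            elif s1 == "D" and s2 == "D" and k2 == k1 + 1:
                cDD[k1] += 1
            # anything else (I->D, D->I) is an illegal Plan-7 adjacency

    tMM = np.zeros(K + 1)
    tMI = np.zeros(K + 1)
    tMD = np.zeros(K + 1)
    tIM = np.zeros(K + 1)
    tII = np.zeros(K + 1)
    tDM = np.zeros(K + 1)
    tDD = np.zeros(K + 1)
    tp = transition_pseudocount
    # Dirichlet prior means per state family
    pMM, pMI, pMD = 0.90, 0.05, 0.05
    pIM, pII = 0.80, 0.20
    pDM, pDD = 0.85, 0.15
    # begin state: {M1, D1} (no insert before the first match state)
    tot = cMM[0] + cMD[0] + tp
    tMM[0] = (cMM[0] + tp * 0.95) / tot
    tMD[0] = (cMD[0] + tp * 0.05) / tot
    for k in range(1, K):
        tot = cMM[k] + cMI[k] + cMD[k] + tp
        tMM[k] = (cMM[k] + tp * pMM) / tot
        tMI[k] = (cMI[k] + tp * pMI) / tot
        tMD[k] = (cMD[k] + tp * pMD) / tot
        tot = cIM[k] + cII[k] + tp
        tIM[k] = (cIM[k] + tp * pIM) / tot
        tII[k] = (cII[k] + tp * pII) / tot
        tot = cDM[k] + cDD[k] + tp
        tDM[k] = (cDM[k] + tp * pDM) / tot
        tDD[k] = (cDD[k] + tp * pDD) / tot
    tMM[K] = 1.0  # M_K -> E
    tDM[K] = 1.0  # D_K -> E
    return ProfileHMM(K, em, bg.copy(), tMM, tMI, tMD, tIM, tII, tDM, tDD,
                      bg, flank_loop, name)


def forward_score(hmm: ProfileHMM, sequence) -> float:
    """Log-odds forward score in bits (sum over all state paths)."""
    seq = sequence.seq if isinstance(sequence, ProteinRecord) else sequence
    eseq = seq if isinstance(seq, np.ndarray) else encode(seq)
    if len(eseq) == 0:
        raise ValueError("sequence must be non-empty")
    return float(_kernels.hmm_forward(*hmm._kernel_args(eseq))) / _LN2


def viterbi_search(hmm: ProfileHMM, sequence):
    """Best local placement of the model within a sequence.

    Returns ``(RegionHit, path)`` where the hit interval delimits the
    residues emitted by core match/insert states (flank-emitted residues
    are excluded) and ``path`` is the core state sequence as
    ``(state, k, seq_pos)`` tuples (``seq_pos`` is None for deletes).
    """
    if isinstance(sequence, ProteinRecord):
        rid, seq = sequence.id, sequence.seq
    else:
        rid, seq = "query", sequence
    eseq = seq if isinstance(seq, np.ndarray) else encode(seq)
    if len(eseq) == 0:
        raise ValueError("sequence must be non-empty")
    score, bj, from_d, pM, pI, pD, vM, vI, vD = _kernels.hmm_viterbi(
        *hmm._kernel_args(eseq)
    )
    K = hmm.n_match
    j, k = int(bj), K
    st = "D" if from_d else "M"
    path: list[tuple[str, int, int | None]] = []
    start = 0
    while True:
        if st == "M":
            code = pM[j, k]
            path.append(("M", k, j - 1))
            j -= 1
            if code == 0:
                start = j
                break
            st = {1: "M", 2: "I", 3: "D"}[int(code)]
            k -= 1
        elif st == "I":
            code = pI[j, k]
            path.append(("I", k, j - 1))
            j -= 1
            st = "M" if code == 1 else "I"
        else:
            code = pD[j, k]
            path.append(("D", k, None))
            if code == 0:
                start = j
                break
            st = "M" if code == 1 else "D"
            k -= 1
    path.reverse()
    hit = RegionHit(rid, start, int(bj), float(score) / _LN2)
    return hit, path


@dataclass(frozen=True)
class HMMCalibration:
    """Extreme-value fit to the null (background) Viterbi score distribution.

    The null law is a generalized extreme-value (GEV) distribution with
    location ``mu``, scale ``1/lambda_evd`` and shape ``shape`` (scipy
    convention; ``shape = 0`` is the classical Gumbel).  Glocal Viterbi
    maxima have a slightly lighter-than-Gumbel tail, which the shape
    parameter absorbs.  Max-stability propagates the parameters to other
    sequence lengths: with ``r = (L/length_ref)^(-shape)``,
    ``mu(L) = mu + (r - 1)/(lambda_evd * (-shape))`` and
    ``scale(L) = r / lambda_evd`` (with the usual ``ln L`` drift in the
    Gumbel limit).
    """

    mu: float
    lambda_evd: float   # 1 / scale, per bit
    n_replicates: int
    length_ref: int | None = None
    shape: float = 0.0

    def _params_at(self, length: int | None):
        scale = 1.0 / self.lambda_evd
        if length is None or self.length_ref is None or length == self.length_ref:
            return self.mu, scale
        lr = length / self.length_ref
        if abs(self.shape) < 1e-12:
            return self.mu + scale * math.log(lr), scale
        xi = -self.shape  # scipy c -> standard xi
        r = lr ** xi
        return self.mu + scale * (r - 1.0) / xi, scale * r

    def survival(self, score_bits: float, length: int | None = None) -> float:
        """P(null score >= score_bits) under the fitted law."""
        mu, scale = self._params_at(length)
        if abs(self.shape) < 1e-12:
            z = (score_bits - mu) / scale
            return -math.expm1(-math.exp(-z))
        return float(sps.genextreme.sf(score_bits, self.shape, mu, scale))

    def evalue(self, score_bits: float, db_size: int,
               length: int | None = None) -> float:
        """Expected chance hits >= score in a database of db_size sequences.

        For high scores this is approximately
        ``db_size * exp(-lambda_evd * (score - mu(length)))`` (Gumbel
        limit of the fitted tail).
        """
        return db_size * self.survival(score_bits, length)


def calibrate(
    hmm: ProfileHMM,
    n_replicates: int = 5000,
    length_law=350,
    rng: np.random.Generator | int | None = 0,
) -> HMMCalibration:
    """Fit the null score distribution on random background sequences.

    ``length_law`` is either a fixed integer length or an array of lengths
    (e.g. the empirical database lengths) sampled with replacement.  Scores
    are Viterbi bits.  A generalized extreme-value law is fitted by
    maximum likelihood; with mixed replicate lengths each score is first
    standardised to the reference (median) length through the
    max-stability transform, and the transform/fit cycle is iterated
    until the parameters stabilise.
    """
    if n_replicates < 100:
        raise ValueError("n_replicates must be >= 100")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if np.isscalar(length_law):
        lengths = np.full(n_replicates, int(length_law))
    else:
        lengths = gen.choice(np.asarray(length_law, dtype=int), size=n_replicates)
    scores = np.empty(n_replicates)
    p = hmm.background
    for i, L in enumerate(lengths):
        eseq = gen.choice(20, size=int(L), p=p).astype(np.int8)
        s, *_ = _kernels.hmm_viterbi(*hmm._kernel_args(eseq))
        scores[i] = s / _LN2
    if float(np.std(scores)) < 1e-9:
        raise ValueError("degenerate null score variance; cannot calibrate")
    length_ref = int(np.median(lengths))
    mixed = bool((lengths != length_ref).any())
    adj = scores
    c = loc = scale = None
    for _ in range(4 if mixed else 1):
        c, loc, scale = sps.genextreme.fit(adj)
        if not mixed:
            break
        cal = HMMCalibration(float(loc), 1.0 / float(scale), n_replicates,
                             length_ref, float(c))
        mus, scs = zip(*(cal._params_at(int(L)) for L in lengths))
        adj = loc + (scores - np.array(mus)) * scale / np.array(scs)
    return HMMCalibration(mu=float(loc), lambda_evd=1.0 / float(scale),
                          n_replicates=n_replicates, length_ref=length_ref,
                          shape=float(c))


def find_domains(
    hmm: ProfileHMM,
    calibration: HMMCalibration,
    record: ProteinRecord,
    e_cutoff: float = 10.0,
    db_size: int = 1,
) -> list[RegionHit]:
    """All non-overlapping model placements with E below the cutoff.

    Iterative best-hit-then-mask: the best Viterbi placement is accepted if
    its E-value beats ``e_cutoff``, its interval is replaced by a
    non-matchable mask sentinel, and the search repeats until no acceptable
    hit remains.  Hits are returned sorted by start coordinate.
    ``db_size`` is the number of sequences in the searched database.
    """
    eseq = encode(record.seq)
    if len(eseq) == 0:
        return []
    hits: list[RegionHit] = []
    work = eseq.copy()
    for _ in range(len(eseq)):  # hard bound; loop exits long before
        hit, _ = _viterbi_on_encoded(hmm, record.id, work)
        E = calibration.evalue(hit.score_bits, db_size, length=len(eseq))
        if E >= e_cutoff or hit.end <= hit.start:
            break
        hits.append(RegionHit(record.id, hit.start, hit.end, hit.score_bits, E))
        work[hit.start:hit.end] = MASK_INDEX
    return sorted(hits, key=lambda h: h.start)


def _viterbi_on_encoded(hmm: ProfileHMM, rid: str, eseq: np.ndarray):
    score, bj, from_d, pM, pI, pD, vM, vI, vD = _kernels.hmm_viterbi(
        *hmm._kernel_args(eseq)
    )
    K = hmm.n_match
    j, k = int(bj), K
    st = "D" if from_d else "M"
    start = 0
    while True:
        if st == "M":
            code = pM[j, k]
            j -= 1
            if code == 0:
                start = j
                break
            st = {1: "M", 2: "I", 3: "D"}[int(code)]
            k -= 1
        elif st == "I":
            code = pI[j, k]
            j -= 1
            st = "M" if code == 1 else "I"
        else:
            code = pD[j, k]
            if code == 0:
                start = j
                break
            st = "M" if code == 1 else "D"
            k -= 1
    return RegionHit(rid, start, int(bj), float(score) / _LN2), None


def multi_domain_filter(records, hits_per_record):
    """Split records into (kept, removed) by their region-hit count.

    Records with two or more hits are mis-annotations (e.g. concatemers of
    several family genes fused into one database entry) and are removed.
    """
    kept, removed = [], []
    for r in records:
        n = len(hits_per_record.get(r.id, []))
        if n >= 2:
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed


def extract_region(record: ProteinRecord, hit: RegionHit | None,
                   region_type: str) -> ProteinRecord:
    """Cut the analysis region out of a full-length record.

    ``full`` returns the record unchanged (new id suffix only is *not*
    added in that case); ``core60`` and ``extended`` slice the hit interval
    of the corresponding region HMM and append a region suffix to the id.
    """
    if region_type == "full":
        return record
    if region_type not in ("core60", "extended"):
        raise ValueError(f"unknown region_type: {region_type}")
    if hit is None:
        raise ValueError("core60/extended extraction requires a region hit")
    if not (0 <= hit.start < hit.end <= len(record.seq)):
        raise ValueError(
            f"hit [{hit.start},{hit.end}) out of bounds for {record.id}"
            f" (length {len(record.seq)})"
        )
    return ProteinRecord(f"{record.id}|{region_type}",
                         record.seq[hit.start:hit.end], record.description)


# ---------------------------------------------------------------------------
# plain-text serialization

def save_hmm(hmm: ProfileHMM, path) -> None:
    """Serialize as a key-value text file; probabilities stored in log2."""
    def l2(v):
        return " ".join("-inf" if x <= 0 else f"{math.log2(x):.10e}" for x in np.atleast_1d(v))

    with open(path, "w") as fh:
        fh.write("format hoxclans-hmm 1\n")
        fh.write(f"name {hmm.name}\n")
        fh.write(f"n_match {hmm.n_match}\n")
        fl = "none" if hmm.flank_loop is None else str(hmm.flank_loop)
        fh.write(f"flank_loop {fl}\n")
        fh.write(f"background {l2(hmm.background)}\n")
        fh.write(f"insert_emissions {l2(hmm.insert_emissions)}\n")
        for k in range(1, hmm.n_match + 1):
            fh.write(f"match_emissions {k} {l2(hmm.match_emissions[k])}\n")
        for nm in ("tMM", "tMI", "tMD", "tIM", "tII", "tDM", "tDD"):
            fh.write(f"{nm} {l2(getattr(hmm, nm))}\n")


def load_hmm(path) -> ProfileHMM:
    def unl2(tokens):
        return np.array([0.0 if t == "-inf" else 2.0 ** float(t) for t in tokens])

    fields: dict[str, object] = {}
    em_rows: dict[int, np.ndarray] = {}
    with open(path) as fh:
        first = fh.readline().split()
        if first[:2] != ["format", "hoxclans-hmm"]:
            raise ValueError(f"not a hoxclans HMM file: {path}")
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0]
            if key == "match_emissions":
                em_rows[int(parts[1])] = unl2(parts[2:])
            elif key in ("name",):
                fields[key] = parts[1]
            elif key == "n_match":
                fields[key] = int(parts[1])
            elif key == "flank_loop":
                if parts[1] == "none":
                    fields[key] = None
                elif parts[1] == "adaptive":
                    fields[key] = "adaptive"
                else:
                    fields[key] = float(parts[1])
            else:
                fields[key] = unl2(parts[1:])
    K = fields["n_match"]
    em = np.zeros((K + 1, 20))
    for k, row in em_rows.items():
        em[k] = row
    return ProfileHMM(
        K, em, fields["insert_emissions"], fields["tMM"], fields["tMI"],
        fields["tMD"], fields["tIM"], fields["tII"], fields["tDM"],
        fields["tDD"], fields["background"], fields["flank_loop"],
        str(fields.get("name", "profile")),
    )


def write_region_hits(hits, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("record_id\tstart\tend\tscore_bits\tevalue\n")
        for h in hits:
            fh.write(f"{h.record_id}\t{h.start}\t{h.end}\t{h.score_bits:.4f}"
                     f"\t{h.evalue:.6e}\n")


def read_region_hits(path) -> list[RegionHit]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("record_id"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(RegionHit(f[0], int(f[1]), int(f[2]), float(f[3]), float(f[4])))
    return out
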