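"""Synthetic Hox-like protein family benchmark with known ground truth.

The generator emulates the statistical structure a homeodomain-family
classification has to cope with, so that every pipeline stage can be tested
without downloading anything:

* ``n_groups`` protein groups, each present in every clade, all sharing a
  60-residue core (the homeodomain analog);
* a designated *central triplet* of groups whose cores are nearly
  identical (the classically unresolvable central-group problem) while the
  group-discriminating signal is concentrated in the short motif+linker
  region directly N-terminal of the core;
* clade-discriminating signal placed exclusively in the flanks, so
  full-length similarity tends to sort sequences by clade, not by group;
* related decoy families (NK/ParaHox-like sister groups), unrelated
  background proteins, concatemer mis-annotations carrying several cores in
  one record, and hyper-diverged outlier sequences.

Sequence evolution is a site-independent point-substitution model: the
number of mutated sites is Binomial(L, 1 - exp(-rate)) and a replacement
residue is drawn with probability proportional to exp(score row) of the
substitution matrix, excluding the original residue.  Everything is
deterministic given ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import ProteinRecord, decode, encode, robinson_background
from .scoring import SubstitutionMatrix, blosum62

MOTIFS = ("YPWM", "W")

__all__ = [
    "GeneratorConfig", "SyntheticTruth", "Benchmark",
    "evolve_sequence", "assemble_hox_like", "make_seed_alignment",
    "generate_benchmark", "pairwise_identity", "write_truth", "read_truth",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the benchmark generator (defaults are the study design).

    Divergences are expected substitutions per site along the indicated
    branch of the fixed generation tree:

    - ``core_divergence``: group-ancestor core -> member core (within group)
    - ``group_core_divergence``: master core -> group-ancestor core
    - ``central_triplet_core_divergence``: triplet ancestor -> central-group
      core; near zero so the central groups' cores are near-identical
    - ``linker_signal_divergence``: master linker -> group linker (between
      groups); large, so the motif+linker carries the group signal
    - ``flank_divergence``: master flank -> clade flank (between clades)
    - ``flank_member_divergence`` / ``linker_member_divergence``: ancestor
      -> member noise within groups and clades
    """

    rng_seed: int = 0
    background_freqs: np.ndarray = field(default_factory=robinson_background)
    n_groups: int = 7
    clades: tuple = ("Protostomia", "Deuterostomia")
    seqs_per_group_per_clade: int = 10
    core_divergence: float = 0.10
    group_core_divergence: float = 0.65
    central_groups: tuple = (2, 3, 4)
    central_triplet_core_divergence: float = 0.005
    linker_signal_divergence: float = math.inf
    linker_member_divergence: float = 0.02
    flank_divergence: float = math.inf
    flank_member_divergence: float = 0.10
    linker_length_range: tuple = (22, 28)
    flank_length_range: tuple = (30, 60)
    n_decoy_families: int = 2
    decoy_seqs_per_family: int = 10
    decoy_core_divergence: float = 0.65
    n_background: int = 50
    background_length_range: tuple = (80, 300)
    n_concatemers: int = 3
    concatemer_units_range: tuple = (2, 5)
    n_outliers: int = 2
    outlier_divergence_multiplier: float = 3.0
    flank_core_screen: float = 30.0
    flank_domain_screen_e: float = 20.0

    def __post_init__(self) -> None:
        bg = np.asarray(self.background_freqs, dtype=float)
        if bg.shape != (20,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-12:
            raise ValueError("background_freqs must be 20 positive values summing to 1")
        object.__setattr__(self, "background_freqs", bg)
        if self.central_triplet_core_divergence > self.core_divergence:
            raise ValueError(
                "central_triplet_core_divergence must not exceed core_divergence"
            )
        if any(g < 0 or g >= self.n_groups for g in self.central_groups):
            raise ValueError("central_groups must be valid group indices")

    @property
    def group_names(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_groups)]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated record.

    Coordinates are 0-based half-open; ``-1`` marks a missing interval
    (background records).  ``cores`` lists every planted core interval --
    a single one for family members, two or more for concatemers.
    """

    record_id: str
    group: str       # G1..Gn or DECOY / BACKGROUND / OUTLIER / CONCATEMER
    clade: str       # clade name or "-"
    core_start: int
    core_end: int
    ext_start: int
    ext_end: int
    flags: tuple = ()
    cores: tuple = ()


@dataclass
class Benchmark:
    """A generated database plus its truth table and seed definitions."""

    config: GeneratorConfig
    records: list
    truth: dict
    seed_ids: list

    def seed_alignment(self, region_type: str) -> list[tuple[str, str]]:
        """Pre-aligned seed rows for a region definition.

        core60 rows are the gapless 60-residue cores.  extended rows run
        from the motif through the linker to the core end; motifs are
        right-justified into a 4-column block and shorter linkers are
        padded with gaps between linker and core, giving the common width
        ``4 + max_linker + 60``.
        """
        if region_type not in ("core60", "extended"):
            raise ValueError(f"no seed alignment for region_type {region_type!r}")
        by_id = {r.id: r for r in self.records}
        rows = []
        if region_type == "core60":
            for sid in self.seed_ids:
                t = self.truth[sid]
                rows.append((sid, by_id[sid].seq[t.core_start:t.core_end]))
            return rows
        max_linker = 0
        parts = []
        for sid in self.seed_ids:
            t = self.truth[sid]
            seq = by_id[sid].seq
            motif = next(m for m in MOTIFS
                         if seq[t.ext_start:t.ext_start + len(m)] == m)
            linker = seq[t.ext_start + len(motif):t.core_start]
            core = seq[t.core_start:t.core_end]
            parts.append((sid, motif, linker, core))
            max_linker = max(max_linker, len(linker))
        for sid, motif, linker, core in parts:
            row = (motif.rjust(4, "-") + linker
                   + "-" * (max_linker - len(linker)) + core)
            rows.append((sid, row))
        return rows

    def truth_rows(self) -> list[SyntheticTruth]:
        return [self.truth[r.id] for r in self.records]


def _substitution_sampler(matrix: SubstitutionMatrix) -> np.ndarray:
    """P(replacement b | original a) ~ exp(s_ab), b != a; rows sum to 1."""
    w = np.exp(matrix.scores.astype(float))
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def evolve_sequence(
    parent: str,
    subs_per_site: float,
    matrix: SubstitutionMatrix,
    rng: np.random.Generator,
) -> str:
    """Apply the point-substitution model to a parent sequence.

    The number of mutated sites is Binomial(L, 1 - exp(-subs_per_site));
    sites are chosen without replacement and each replacement residue is
    drawn with probability proportional to ``exp(score(a, b))`` over
    ``b != a``, so chemically conservative changes dominate.
    """
    if subs_per_site < 0:
        raise ValueError("subs_per_site must be non-negative")
    if not parent:
        raise ValueError("parent sequence must be non-empty")
    if subs_per_site == 0:
        return parent
    probs = _substitution_sampler(matrix)
    eseq = encode(parent).astype(int)
    L = len(eseq)
    p_change = -np.expm1(-subs_per_site)
    n_mut = rng.binomial(L, p_change)
    if n_mut == 0:
        return parent
    sites = rng.choice(L, size=n_mut, replace=False)
    for s in sites:
        eseq[s] = rng.choice(20, p=probs[eseq[s]])
    return decode(eseq)


def assemble_hox_like(
    core: str,
    motif: str,
    linker: str,
    n_flank: str,
    c_flank: str,
    record_id: str = "assembled",
    group: str = "G?",
    clade: str = "-",
    flags: tuple = (),
) -> tuple[ProteinRecord, SyntheticTruth]:
    """Concatenate the region parts and derive the truth coordinates.

    sequence = n_flank + motif + linker + core + c_flank with
    ext = [len(n_flank), core_end) and core exactly 60 residues long.
    """
    if len(core) != 60:
        raise ValueError(f"core must be exactly 60 residues, got {len(core)}")
    if motif not in MOTIFS:
        raise ValueError(f"motif must be one of {MOTIFS}")
    seq = n_flank + motif + linker + core + c_flank
    ext_start = len(n_flank)
    core_start = ext_start + len(motif) + len(linker)
    core_end = core_start + 60
    truth = SyntheticTruth(
        record_id, group, clade, core_start, core_end, ext_start, core_end,
        flags=tuple(flags), cores=((core_start, core_end),),
    )
    return ProteinRecord(record_id, seq, f"group={group} clade={clade}"), truth


def _random_seq(rng: np.random.Generator, length: int, bg: np.ndarray) -> str:
    return decode(rng.choice(20, size=length, p=bg).astype(int))


def _screened_flank(length: int, core: str, mat, rng, bg,
                    max_score: float, max_tries: int = 100) -> str:
    """Draw a random flank with no chance core-like region.

    The benchmark guarantees that non-artifact records carry exactly one
    core-like region, so flank ancestors are rejection-sampled until their
    best local alignment against the master core stays at chance level.
    """
    from .alphabet import encode as _enc
    from . import _kernels

    ecore = _enc(core)
    cand = _random_seq(rng, length, bg)
    for _ in range(max_tries):
        s = _kernels.sw_score_only(_enc(cand), ecore, mat.scores,
                                   mat.gap_open, mat.gap_extend)
        if s < max_score:
            break
        cand = _random_seq(rng, length, bg)
    return cand


def _derive(parent: str, rate: float, mat, rng, bg) -> str:
    """Evolve at a finite rate; an infinite rate means an independent draw."""
    if math.isinf(rate):
        return _random_seq(rng, len(parent), bg)
    return evolve_sequence(parent, rate, mat, rng)


def _screened_evolve(parent: str, rate: float, core: str, mat, rng,
                     max_score: float, max_tries: int = 50) -> str:
    """Evolve a flank, re-drawing if mutation creates a core-like region."""
    from .alphabet import encode as _enc
    from . import _kernels

    ecore = _enc(core)
    cand = evolve_sequence(parent, rate, mat, rng)
    for _ in range(max_tries):
        s = _kernels.sw_score_only(_enc(cand), ecore, mat.scores,
                                   mat.gap_open, mat.gap_extend)
        if s < max_score:
            break
        cand = evolve_sequence(parent, rate, mat, rng)
    return cand


def generate_benchmark(
    config: GeneratorConfig,
    matrix: SubstitutionMatrix | None = None,
) -> Benchmark:
    """Generate the full benchmark database (deterministic under rng_seed)."""
    if config.n_groups < 1 or config.seqs_per_group_per_clade < 1:
        raise ValueError("need at least one group and one sequence per group")
    if not config.clades:
        raise ValueError("need at least one clade")
    mat = blosum62() if matrix is None else matrix
    rng = np.random.default_rng(config.rng_seed)
    bg = config.background_freqs
    cfg = config

    lo, hi = cfg.linker_length_range
    master_core = _random_seq(rng, 60, bg)
    master_linker = _random_seq(rng, hi, bg)
    flo, fhi = cfg.flank_length_range
    master_nflank = _random_seq(rng, fhi, bg)
    master_cflank = _random_seq(rng, fhi, bg)

    # clade-level flank ancestors (the only place clade signal lives)
    clade_flanks = {}
    for clade in cfg.clades:
        nlen = int(rng.integers(flo, fhi + 1))
        clen = int(rng.integers(flo, fhi + 1))
        if math.isinf(cfg.flank_divergence):
            clade_flanks[clade] = (
                _screened_flank(nlen, master_core, mat, rng, bg,
                                cfg.flank_core_screen),
                _screened_flank(clen, master_core, mat, rng, bg,
                                cfg.flank_core_screen),
            )
        else:
            clade_flanks[clade] = (
                _derive(master_nflank[:nlen], cfg.flank_divergence, mat, rng, bg),
                _derive(master_cflank[:clen], cfg.flank_divergence, mat, rng, bg),
            )

    # group-level core / motif / linker ancestors
    triplet_core = evolve_sequence(master_core, cfg.group_core_divergence, mat, rng)
    group_parts = {}
    for g, gname in enumerate(cfg.group_names):
        if g in cfg.central_groups:
            core = evolve_sequence(
                triplet_core, cfg.central_triplet_core_divergence, mat, rng
            )
        else:
            core = evolve_sequence(master_core, cfg.group_core_divergence, mat, rng)
        motif = "YPWM" if g < cfg.n_groups - 2 else "W"
        llen = int(rng.integers(lo, hi + 1))
        linker = _derive(master_linker[:llen], cfg.linker_signal_divergence,
                         mat, rng, bg)
        group_parts[gname] = (core, motif, linker)

    records: list[ProteinRecord] = []
    truth: dict[str, SyntheticTruth] = {}
    seed_ids: list[str] = []
    members: list[ProteinRecord] = []
    flank_ancestry: dict[str, tuple] = {}

    def add(rec: ProteinRecord, t: SyntheticTruth) -> None:
        records.append(rec)
        truth[rec.id] = t

    for gname in cfg.group_names:
        core_a, motif, linker_a = group_parts[gname]
        for clade in cfg.clades:
            nfl_a, cfl_a = clade_flanks[clade]
            for i in range(cfg.seqs_per_group_per_clade):
                core = evolve_sequence(core_a, cfg.core_divergence, mat, rng)
                linker = evolve_sequence(
                    linker_a, cfg.linker_member_divergence, mat, rng
                )
                nfl = _screened_evolve(nfl_a, cfg.flank_member_divergence,
                                       master_core, mat, rng,
                                       cfg.flank_core_screen)
                cfl = _screened_evolve(cfl_a, cfg.flank_member_divergence,
                                       master_core, mat, rng,
                                       cfg.flank_core_screen)
                rid = f"{gname}_{clade}_{i:02d}"
                rec, t = assemble_hox_like(core, motif, linker, nfl, cfl,
                                           record_id=rid, group=gname, clade=clade)
                add(rec, t)
                members.append(rec)
                flank_ancestry[rid] = (nfl_a, cfl_a, cfg.flank_member_divergence)
                if clade == cfg.clades[0] and i == 0:
                    seed_ids.append(rid)

    decoy_names = ["NK", "ParaHox", "TALE", "Paired"]
    for d in range(cfg.n_decoy_families):
        fam = decoy_names[d % len(decoy_names)] + (str(d) if d >= 4 else "")
        core_a = evolve_sequence(master_core, cfg.decoy_core_divergence,
                                 mat, rng)
        llen = int(rng.integers(lo, hi + 1))
        linker_a = _derive(master_linker[:llen], cfg.linker_signal_divergence,
                           mat, rng, bg)
        nfl_a = _screened_flank(int(rng.integers(flo, fhi + 1)), master_core,
                                mat, rng, bg, cfg.flank_core_screen)
        cfl_a = _screened_flank(int(rng.integers(flo, fhi + 1)), master_core,
                                mat, rng, bg, cfg.flank_core_screen)
        for i in range(cfg.decoy_seqs_per_family):
            core = evolve_sequence(core_a, cfg.core_divergence, mat, rng)
            linker = evolve_sequence(linker_a, cfg.linker_member_divergence, mat, rng)
            nfl = _screened_evolve(nfl_a, cfg.flank_member_divergence,
                                   master_core, mat, rng, cfg.flank_core_screen)
            cfl = _screened_evolve(cfl_a, cfg.flank_member_divergence,
                                   master_core, mat, rng, cfg.flank_core_screen)
            rid = f"{fam}_{i:02d}"
            rec, t = assemble_hox_like(core, "YPWM", linker, nfl, cfl,
                                       record_id=rid, group="DECOY", clade="-",
                                       flags=(f"family:{fam}",))
            add(rec, t)
            flank_ancestry[rid] = (nfl_a, cfl_a, cfg.flank_member_divergence)

    non_central = [g for g in range(cfg.n_groups)
                   if g not in cfg.central_groups] or list(range(cfg.n_groups))
    outlier_recs: list[ProteinRecord] = []
    for i in range(cfg.n_outliers):
        g = non_central[i % len(non_central)]
        gname = cfg.group_names[g]
        core_a, motif, linker_a = group_parts[gname]
        clade = cfg.clades[i % len(cfg.clades)]
        nfl_a, cfl_a = clade_flanks[clade]
        mult = cfg.outlier_divergence_multiplier
        core = evolve_sequence(core_a, mult * cfg.core_divergence, mat, rng)
        linker = evolve_sequence(linker_a, mult * cfg.linker_member_divergence,
                                 mat, rng)
        nfl = _screened_evolve(nfl_a, mult * cfg.flank_member_divergence,
                               master_core, mat, rng, cfg.flank_core_screen)
        cfl = _screened_evolve(cfl_a, mult * cfg.flank_member_divergence,
                               master_core, mat, rng, cfg.flank_core_screen)
        rid = f"OUTLIER_{i:02d}"
        rec, t = assemble_hox_like(core, motif, linker, nfl, cfl,
                                   record_id=rid, group="OUTLIER", clade=clade,
                                   flags=(f"src:{gname}",))
        truth[rid] = t
        outlier_recs.append(rec)
        flank_ancestry[rid] = (nfl_a, cfl_a, mult * cfg.flank_member_divergence)

    # single-core guarantee: the generator's contract is that every
    # non-concatemer family-like record carries exactly one core-like
    # region.  Chance flank mutations can occasionally fake a second weak
    # one, so the generator scans with the same core profile it emits
    # seeds for and re-evolves the flanks of any offender (lengths, and
    # therefore all truth coordinates, are unchanged).
    from .profile_hmm import build_hmm as _gb, calibrate as _gc, \
        find_domains as _gf

    scan = records + outlier_recs   # members + decoys + outliers
    seed_rows = [(sid, next(r for r in members if r.id == sid)
                  .seq[truth[sid].core_start:truth[sid].core_end])
                 for sid in seed_ids]
    ghmm = _gb(seed_rows)
    gcal = _gc(ghmm, 500, np.array([len(r.seq) for r in scan]),
               rng=np.random.default_rng(cfg.rng_seed + 987))
    dbz = len(scan) + cfg.n_background + cfg.n_concatemers
    for idx, rec in enumerate(scan):
        nfl_a, cfl_a, rate = flank_ancestry[rec.id]
        t = truth[rec.id]
        cur = rec
        for _ in range(20):
            if len(_gf(ghmm, gcal, cur, cfg.flank_domain_screen_e, dbz)) <= 1:
                break
            nfl = _screened_evolve(nfl_a, rate, master_core, mat, rng,
                                   cfg.flank_core_screen)
            cfl = _screened_evolve(cfl_a, rate, master_core, mat, rng,
                                   cfg.flank_core_screen)
            cur = ProteinRecord(
                rec.id, nfl + rec.seq[t.ext_start:t.core_end] + cfl,
                rec.description)
        scan[idx] = cur
    family_recs = scan[:len(records)]
    outlier_recs = scan[len(records):]
    members = [r for r in family_recs if truth[r.id].group in cfg.group_names]

    bg_recs: list[ProteinRecord] = []
    blo, bhi = cfg.background_length_range
    for i in range(cfg.n_background):
        L = int(rng.integers(blo, bhi + 1))
        rid = f"BG_{i:02d}"
        truth[rid] = SyntheticTruth(rid, "BACKGROUND", "-", -1, -1, -1, -1)
        bg_recs.append(ProteinRecord(rid, _random_seq(rng, L, bg), "background"))

    concat_recs: list[ProteinRecord] = []
    clo, chi = cfg.concatemer_units_range
    for i in range(cfg.n_concatemers):
        k = int(rng.integers(clo, chi + 1))
        picks = rng.choice(len(members), size=k, replace=False)
        segs, cores = [], []
        offset = 0
        for p in picks:
            m = members[int(p)]
            t = truth[m.id]
            segs.append(m.seq)
            cores.append((offset + t.core_start, offset + t.core_end))
            offset += len(m.seq)
        rid = f"CONCAT_{i:02d}"
        truth[rid] = SyntheticTruth(rid, "CONCATEMER", "-", -1, -1, -1, -1,
                                    flags=(f"units:{k}",), cores=tuple(cores))
        concat_recs.append(
            ProteinRecord(rid, "".join(segs), f"concatemer of {k} members"))

    records = family_recs + bg_recs + concat_recs + outlier_recs
    return Benchmark(cfg, records, truth, seed_ids)


def make_seed_alignment(config: GeneratorConfig, region_type: str):
    """Seed alignment for a region, regenerating the benchmark from config."""
    return generate_benchmark(config).seed_alignment(region_type)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions of two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


_TRUTH_HEADER = "record_id\tgroup\tclade\tcore_start\tcore_end\text_start\text_end\tflags"


def write_truth(truths, path, header_comment: str | None = None) -> None:
    """Tab-separated truth table; extra concatemer cores go in flags."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(_TRUTH_HEADER + "\n")
        for t in truths:
            flags = list(t.flags)
            if len(t.cores) > 1:
                flags.append("cores=" + ",".join(f"{a}-{b}" for a, b in t.cores))
            fh.write(
                f"{t.record_id}\t{t.group}\t{t.clade}\t{t.core_start}"
                f"\t{t.core_end}\t{t.ext_start}\t{t.ext_end}"
                f"\t{';'.join(flags) if flags else '-'}\n"
            )


def read_truth(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("record_id"):
                continue
            f = line.rstrip("\n").split("\t")
            flags = tuple(x for x in f[7].split(";") if x and x != "-")
            cores = ()
            for fl in flags:
                if fl.startswith("cores="):
                    cores = tuple(tuple(int(v) for v in c.split("-"))
                                  for c in fl[6:].split(","))
            cs, ce = int(f[3]), int(f[4])
            if not cores and cs >= 0:
                cores = ((cs, ce),)
            out[f[0]] = SyntheticTruth(
                f[0], f[1], f[2], cs, ce, int(f[5]), int(f[6]),
                flags=tuple(x for x in flags if not x.startswith("cores=")),
                cores=cores,
            )
    return out
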