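"""Profile HMM construction, scoring, calibration and region extraction."""

import math

import numpy as np
import pytest

from hoxclans.alphabet import AMINO_ACIDS, ProteinRecord, robinson_background
from hoxclans.profile_hmm import (
    ProfileHMM, build_hmm, calibrate, extract_region, find_domains,
    forward_score, load_hmm, multi_domain_filter, save_hmm, viterbi_search,
)

from oracles import enumerate_hmm_scores

AA = list(AMINO_ACIDS)
BG = robinson_background()


def single_w_model():
    """One match state emitting W with probability 1, flanks disabled."""
    em = np.zeros((2, 20))
    em[1, AMINO_ACIDS.index("W")] = 1.0
    z = np.zeros(2)
    return ProfileHMM(1, em, BG, np.array([1.0, 1.0]), z, np.array([0.0, 0.0]),
                      z, z, np.array([0.0, 1.0]), z, BG, None)


def random_alignment(rng, n_rows, width, gap_frac=0.2):
    rows = []
    for _ in range(n_rows):
        row = "".join(
            "-" if rng.random() < gap_frac else rng.choice(AA)
            for _ in range(width)
        )
        rows.append(row)
    # ensure at least one gapless row so every column can be a match column
    rows[0] = "".join(rng.choice(AA) for _ in range(width))
    return rows


class TestBuild:
    def test_gapless_alignment_all_columns_match(self):
        rng = np.random.default_rng(0)
        cons = "".join(rng.choice(AA, 60))
        hmm = build_hmm([cons] * 8)
        assert hmm.n_match == 60
        assert (hmm.tMM[1:60] > hmm.tMD[1:60]).all()

    def test_pseudocount_column_frequency(self):
        hmm = build_hmm(["W" * 5] * 8, pseudocount_alpha=1.0)
        bw = BG[AMINO_ACIDS.index("W")]
        assert hmm.match_emissions[1, AMINO_ACIDS.index("W")] == pytest.approx(
            (8 + bw) / 9, abs=1e-12)

    def test_majority_gap_column_is_not_match(self):
        rows = ["AW", "AW", "AW", "A-", "A-", "A-", "A-", "A-"]
        hmm = build_hmm(rows, match_column_gap_frac=0.5)
        assert hmm.n_match == 1  # 5/8 gaps in column 2 > 0.5

    def test_ragged_and_empty_rejected(self):
        with pytest.raises(ValueError):
            build_hmm([])
        with pytest.raises(ValueError):
            build_hmm(["AC", "ACD"])

    def test_distributions_sum_to_one(self, core_hmm):
        assert np.allclose(core_hmm.match_emissions[1:].sum(axis=1), 1.0,
                           atol=1e-9)
        K = core_hmm.n_match
        for k in range(1, K):
            assert core_hmm.tMM[k] + core_hmm.tMI[k] + core_hmm.tMD[k] == \
                pytest.approx(1.0, abs=1e-9)
            assert core_hmm.tIM[k] + core_hmm.tII[k] == pytest.approx(1.0, abs=1e-9)
            assert core_hmm.tDM[k] + core_hmm.tDD[k] == pytest.approx(1.0, abs=1e-9)


class TestScoring:
    def test_single_state_forced_path(self):
        hmm = single_w_model()
        expected = -math.log2(BG[AMINO_ACIDS.index("W")])
        assert forward_score(hmm, "W") == pytest.approx(expected, abs=1e-12)
        hit, path = viterbi_search(hmm, "W")
        assert (hit.start, hit.end) == (0, 1)
        assert hit.score_bits == pytest.approx(expected, abs=1e-12)
        assert [s for s, _, _ in path] == ["M"]

    @pytest.mark.parametrize("model_seed", [1, 2, 3])
    @pytest.mark.parametrize("flank", ["adaptive", 0.9, None])
    def test_forward_and_viterbi_match_exhaustive_enumeration(
            self, model_seed, flank):
        """Tiny models (<=4 match states) against brute-force enumeration
        of every state path, for sequences of length <= 6."""
        rng = np.random.default_rng(model_seed)
        width = int(rng.integers(2, 5))
        hmm = build_hmm(random_alignment(rng, 4, width, gap_frac=0.25),
                        flank_loop=flank)
        assert hmm.n_match <= 4
        for ls in range(1, 7):
            seq = "".join(rng.choice(AA, ls))
            fwd_o, vit_o = enumerate_hmm_scores(hmm, seq)
            fwd = forward_score(hmm, seq)
            hit, _ = viterbi_search(hmm, seq)
            if vit_o > -1e29:
                assert fwd == pytest.approx(fwd_o, abs=1e-9)
                assert hit.score_bits == pytest.approx(vit_o, abs=1e-9)

    def test_forward_at_least_viterbi(self, core_hmm):
        rng = np.random.default_rng(5)
        for _ in range(10):
            seq = "".join(rng.choice(AA, int(rng.integers(60, 150))))
            hit, _ = viterbi_search(core_hmm, seq)
            assert forward_score(core_hmm, seq) >= hit.score_bits - 1e-9

    def test_consensus_spans_whole_model(self, core_hmm):
        cons = "".join(AMINO_ACIDS[int(i)]
                       for i in core_hmm.match_emissions[1:].argmax(axis=1))
        hit, _ = viterbi_search(core_hmm, cons)
        assert (hit.start, hit.end) == (0, 60)


class TestCalibration:
    def test_evalue_monotone_decreasing_in_score(self, core_cal):
        # strictly decreasing across the null support; the fitted
        # extreme-value law may have a finite upper endpoint beyond which
        # E is exactly 0, so overall it is non-increasing
        lo = core_cal.mu - 3.0 / core_cal.lambda_evd
        if core_cal.shape > 0:
            hi = core_cal.mu + 0.95 / (core_cal.lambda_evd * core_cal.shape)
        else:
            hi = core_cal.mu + 20.0 / core_cal.lambda_evd
        inside = [core_cal.evalue(s, 100) for s in np.linspace(lo, hi, 40)]
        assert all(a > b for a, b in zip(inside, inside[1:]))
        wide = [core_cal.evalue(s, 100) for s in np.linspace(lo, hi + 100, 60)]
        assert all(a >= b for a, b in zip(wide, wide[1:]))

    def test_replicate_floor_enforced(self, core_hmm):
        with pytest.raises(ValueError):
            calibrate(core_hmm, n_replicates=50)

    def test_consensus_score_is_overwhelming(self, core_hmm, core_cal):
        cons = "".join(AMINO_ACIDS[int(i)]
                       for i in core_hmm.match_emissions[1:].argmax(axis=1))
        hit, _ = viterbi_search(core_hmm, cons)
        assert core_cal.evalue(hit.score_bits, 1000) < 1e-3


class TestDomains:
    def test_benchmark_single_core_records_have_one_hit(self, benchmark,
                                                        core_hits):
        for rid, hits in core_hits.items():
            t = benchmark.truth[rid]
            if t.group.startswith("G"):
                assert len(hits) == 1, rid

    def test_concatemers_have_disjoint_hits_per_planted_core(self, benchmark,
                                                             core_hits):
        for rid, t in benchmark.truth.items():
            if t.group != "CONCATEMER":
                continue
            hits = core_hits.get(rid, [])
            assert len(hits) >= 2
            for a, b in zip(hits, hits[1:]):
                assert a.end <= b.start  # sorted and disjoint

    def test_hits_within_bounds_and_disjoint_everywhere(self, database,
                                                        core_hits):
        for r in database:
            hits = core_hits[r.id]
            for h in hits:
                assert 0 <= h.start < h.end <= len(r.seq)
            for a, b in zip(hits, hits[1:]):
                assert a.end <= b.start

    def test_background_hit_rate_matches_calibration(self, core_hmm, core_cal,
                                                     database):
        """At E<10 against 215 sequences the calibrated chance-hit rate per
        record is 10/215; at a realistically large database size chance
        hits essentially vanish."""
        rng = np.random.default_rng(123)
        n_desk = n_big = 0
        for i in range(100):
            seq = "".join(rng.choice(AA, int(rng.integers(80, 300))))
            rec = ProteinRecord(f"null{i}", seq)
            if find_domains(core_hmm, core_cal, rec, 10.0, len(database)):
                n_desk += 1
            if find_domains(core_hmm, core_cal, rec, 10.0, 50000):
                n_big += 1
        assert n_big <= 5          # >=95 of 100 clean at realistic scale
        expected = 100 * 10 / len(database)
        assert abs(n_desk - expected) <= 3 * math.sqrt(expected)

    def test_multi_domain_filter_on_empty_input(self):
        assert multi_domain_filter([], {}) == ([], [])


class TestExtraction:
    def test_full_region_is_identity(self, database):
        rec = database[0]
        assert extract_region(rec, None, "full") is rec

    def test_out_of_bounds_hit_rejected(self, database, core_hits):
        from hoxclans.profile_hmm import RegionHit

        rec = database[0]
        bad = RegionHit(rec.id, 0, len(rec.seq) + 5, 0.0)
        with pytest.raises(ValueError):
            extract_region(rec, bad, "core60")

    def test_core60_extraction_is_60_residues_on_members(self, benchmark,
                                                         database, core_hits):
        for r in database:
            t = benchmark.truth[r.id]
            if not t.group.startswith("G"):
                continue
            sub = extract_region(r, core_hits[r.id][0], "core60")
            assert abs(len(sub.seq) - 60) <= 4
            assert sub.id.endswith("|core60")


class TestSerialization:
    def test_save_load_round_trip_preserves_scores(self, core_hmm, tmp_path):
        path = tmp_path / "core.hmm"
        save_hmm(core_hmm, path)
        back = load_hmm(path)
        rng = np.random.default_rng(9)
        for _ in range(5):
            seq = "".join(rng.choice(AA, 120))
            h1, _ = viterbi_search(core_hmm, seq)
            h2, _ = viterbi_search(back, seq)
            assert h1.score_bits == pytest.approx(h2.score_bits, abs=1e-6)
            assert (h1.start, h1.end) == (h2.start, h2.end)

    def test_load_rejects_foreign_files(self, tmp_path):
        p = tmp_path / "x.hmm"
        p.write_text("not an hmm\n")
        with pytest.raises(ValueError):
            load_hmm(p)
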