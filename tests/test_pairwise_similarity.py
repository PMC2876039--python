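"""Alignment engine, Karlin-Altschul statistics and profile retrieval."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hoxclans.alphabet import AMINO_ACIDS, ProteinRecord
from hoxclans.scoring import SubstitutionMatrix, blosum62
from hoxclans.pairwise_similarity import (
    all_vs_all, build_pssm, dedup, hsp_significance,
    iterative_profile_search, karlin_altschul_params, sw_align,
)

from oracles import sw_score_plain

AA = list(AMINO_ACIDS)


def random_protein(rng, lo, hi):
    return "".join(rng.choice(AA, size=rng.integers(lo, hi + 1)))


# --- Karlin-Altschul ------------------------------------------------------

class TestKarlinAltschul:
    def test_uniform_pm1_lambda_is_ln3(self):
        """Match +1 / mismatch -1 over 4 equiprobable letters: the scale
        solves (1/4)e^l + (3/4)e^-l = 1, whose positive root is ln 3."""
        tab = -np.ones((20, 20), int)
        np.fill_diagonal(tab, 1)
        bg = np.zeros(20)
        bg[:4] = 0.25
        stats = karlin_altschul_params(SubstitutionMatrix(tab, 1, 1), bg)
        assert abs(stats.lam - math.log(3)) < 1e-9

    def test_blosum62_lambda_matches_published_ungapped_value(self, ka_stats):
        # independent check: solve the defining equation with scipy brentq
        from scipy.optimize import brentq

        from hoxclans.alphabet import robinson_background

        m = blosum62()
        p = robinson_background()
        outer = np.outer(p, p)

        def f(lam):
            return float((outer * np.exp(lam * m.scores)).sum()) - 1.0

        lam_oracle = brentq(f, 1e-6, 2.0, xtol=1e-12)
        assert abs(ka_stats.lam - lam_oracle) < 1e-9
        assert abs(ka_stats.lam - 0.3176) / 0.3176 < 0.05  # published value
        assert 0.8 * 0.134 < ka_stats.K < 1.2 * 0.134

    @pytest.mark.parametrize("c", [2, 3])
    def test_matrix_scaling_scales_lambda_inversely(self, c):
        m1 = blosum62()
        m2 = SubstitutionMatrix(m1.scores * c, m1.gap_open, m1.gap_extend)
        s1 = karlin_altschul_params(m1)
        s2 = karlin_altschul_params(m2)
        assert abs(s2.lam - s1.lam / c) < 1e-9

    def test_nonnegative_expectation_rejected(self):
        tab = np.ones((20, 20), int)
        with pytest.raises(ValueError):
            karlin_altschul_params(SubstitutionMatrix(tab, 1, 1))


# --- Smith-Waterman -------------------------------------------------------

class TestSmithWaterman:
    def test_identity_alignment(self, matrix):
        hsp = sw_align("A" * 10, "A" * 10, matrix)  # BLOSUM62 A/A = +4
        assert hsp.raw_score == 40
        assert (hsp.q_start, hsp.q_end, hsp.s_start, hsp.s_end) == (0, 10, 0, 10)

    def test_empty_sequence_gives_none(self, matrix):
        assert sw_align("", "ACDE", matrix) is None

    def test_unknown_residue_names_character_and_position(self, matrix):
        with pytest.raises(ValueError, match=r"'B' at position 2"):
            sw_align("AAB", "AAA", matrix)

    def test_agrees_with_plain_matrix_oracle(self, matrix):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = random_protein(rng, 1, 30)
            b = random_protein(rng, 1, 30)
            got = sw_align(a, b, matrix)
            want = sw_score_plain(a, b, matrix.scores,
                                  matrix.gap_open, matrix.gap_extend)
            assert (got.raw_score if got else 0) == want

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=25),
           st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=25))
    def test_score_symmetric_under_swap(self, a, b):
        m = blosum62()
        ha = sw_align(a, b, m)
        hb = sw_align(b, a, m)
        assert (ha.raw_score if ha else 0) == (hb.raw_score if hb else 0)


# --- significance ---------------------------------------------------------

class TestSignificance:
    def test_p_from_e_identity_and_linearity(self, matrix, ka_stats):
        hsp = sw_align("W" * 20, "W" * 20, matrix)
        h1 = hsp_significance(hsp, 100, 200, ka_stats)
        assert abs(h1.pvalue - (1 - math.exp(-h1.evalue))) < 1e-12
        h2 = hsp_significance(hsp, 100, 400, ka_stats)
        assert abs(h2.evalue - 2 * h1.evalue) < 1e-12 * h1.evalue

    def test_small_e_equals_p(self, matrix, ka_stats):
        # pick m, n so that E lands near 1e-6: then P ~ E to 1e-12 relative
        hsp = sw_align("W" * 10, "W" * 10, matrix)
        E_unit = ka_stats.K * math.exp(-ka_stats.lam * hsp.raw_score)
        mn = 1e-6 / E_unit
        m = int(math.sqrt(mn))
        h = hsp_significance(hsp, m, int(mn / m), ka_stats)
        assert h.evalue == pytest.approx(1e-6, rel=0.1)
        assert h.pvalue == pytest.approx(h.evalue * (1 - h.evalue / 2), rel=1e-9)

    def test_e_strictly_decreasing_in_score(self, matrix, ka_stats):
        evs = []
        for k in (5, 10, 15, 20):
            h = hsp_significance(sw_align("W" * k, "W" * k, matrix),
                                 100, 100, ka_stats)
            evs.append(h.evalue)
        assert all(a > b for a, b in zip(evs, evs[1:]))


# --- all-vs-all -----------------------------------------------------------

class TestAllVsAll:
    def test_identical_triplet_forms_clique_with_equal_scores(self, matrix, ka_stats):
        seq = "WLKHGFDEYACWLKHGFDEYAC"
        recs = [ProteinRecord(f"s{i}", seq) for i in range(3)]
        edges = all_vs_all(recs, matrix, ka_stats)
        assert len(edges) == 3
        assert len({h.raw_score for h in edges}) == 1

    def test_duplicate_ids_rejected(self, matrix, ka_stats):
        recs = [ProteinRecord("x", "ACDEF"), ProteinRecord("x", "ACDEG")]
        with pytest.raises(ValueError, match="duplicate"):
            all_vs_all(recs, matrix, ka_stats)

    def test_edge_count_bounded_and_order_lexicographic(self, matrix, ka_stats):
        rng = np.random.default_rng(0)
        recs = [ProteinRecord(f"r{i:02d}", random_protein(rng, 40, 60))
                for i in range(12)]
        edges = all_vs_all(recs, matrix, ka_stats, store_p_max=1.0)
        assert len(edges) <= 12 * 11 // 2
        pairs = [(h.query_id, h.subject_id) for h in edges]
        assert pairs == sorted(pairs)
        assert all(q < s for q, s in pairs)

    def test_unrelated_pairs_rarely_stored_at_default_threshold(self, matrix, ka_stats):
        rng = np.random.default_rng(7)
        none_count = 0
        for _ in range(100):
            recs = [ProteinRecord("a", "".join(rng.choice(AA, 50))),
                    ProteinRecord("b", "".join(rng.choice(AA, 50)))]
            if not all_vs_all(recs, matrix, ka_stats, store_p_max=1e-2):
                none_count += 1
        assert none_count >= 95


# --- dedup ----------------------------------------------------------------

class TestDedup:
    def test_first_occurrence_kept_in_order(self):
        recs = [ProteinRecord("a", "AAA"), ProteinRecord("b", "AAA"),
                ProteinRecord("c", "CCC")]
        assert [r.id for r in dedup(recs)] == ["a", "c"]

    def test_all_distinct_unchanged(self):
        recs = [ProteinRecord(f"r{i}", "A" * (i + 1)) for i in range(5)]
        assert dedup(recs) == recs

    def test_planted_duplicates_match_set_oracle(self):
        rng = np.random.default_rng(3)
        base = ["".join(rng.choice(AA, 30)) for _ in range(900)]
        seqs = base + [base[i] for i in rng.integers(0, 900, size=100)]
        rng.shuffle(seqs)
        recs = [ProteinRecord(f"r{i}", s) for i, s in enumerate(seqs)]
        out = dedup(recs)
        assert len(out) == len(set(seqs))
        assert len({r.seq for r in out}) == len(out)


# --- iterative profile search --------------------------------------------

class TestProfileSearch:
    def _seeds_and_db(self, benchmark):
        seeds = [ProteinRecord(rid, row)
                 for rid, row in benchmark.seed_alignment("core60")]
        return seeds, dedup(benchmark.records)

    def test_seeds_in_database_are_immediate_strong_hits(self, benchmark):
        seeds, db = self._seeds_and_db(benchmark)
        res = iterative_profile_search(seeds, db)
        for s in benchmark.seed_ids:
            assert s in res.hits
            assert res.hits[s] < 1e-30       # self-hits are overwhelming
            assert s in res.included_history[0]  # included from iteration 1

    def test_gathered_set_monotone_across_iterations(self, benchmark):
        seeds, db = self._seeds_and_db(benchmark)
        res = iterative_profile_search(seeds, db)
        for a, b in zip(res.gathered_history, res.gathered_history[1:]):
            assert a <= b

    def test_max_iters_one_means_one_pass(self, benchmark):
        seeds, db = self._seeds_and_db(benchmark)
        res = iterative_profile_search(seeds, db, max_iters=1)
        assert res.iterations == 1
        assert len(res.included_history) == 1

    def test_inclusion_must_be_stricter_than_gather(self, benchmark):
        seeds, db = self._seeds_and_db(benchmark)
        with pytest.raises(ValueError):
            iterative_profile_search(seeds, db, inclusion_e=10, gather_e=10)

    def test_pssm_columns_are_distributions(self, benchmark):
        from hoxclans.alphabet import robinson_background

        bg = robinson_background()
        rows = [row for _, row in benchmark.seed_alignment("core60")]
        pssm = build_pssm(rows, bg, alpha=1.0)
        freqs = bg * np.exp(pssm.scores[:, :20])
        assert np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9)
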