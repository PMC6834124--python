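import numpy as np
import pytest

from oracles import naive_scan

from mirfunc.sequence_io import DnaSequence, RnaSequence
from mirfunc.synthetic_data import make_triplex_promoter
from mirfunc.triplex_search import (
    TriplexHit,
    background_scores,
    best_register_score,
    dinucleotide_shuffle,
    find_triplex_sites,
    grade_hits,
    score_percentile,
    summarize_matrix,
)

# mixed-composition, orientation-asymmetric third strands
THIRD = RnaSequence(id="m", seq="GAGGAAGGAGUGAGGAAGAGGA")


def _hit(score, orientation="direct"):
    return TriplexHit(
        mirna_id="m", gene_id="g", orientation=orientation,
        target_start=0, target_end=22, purine_strand="given",
        hit_score=score, hit_energy=-score,
    )


class TestFindTriplexSites:
    def test_poly_u_against_a_tract(self):
        third = RnaSequence(id="u", seq="U" * 22)
        duplex = DnaSequence(id="d", seq="C" * 30 + "A" * 22 + "C" * 30)
        hits = find_triplex_sites(third, duplex)
        # the perfect register sits at the tract, on the A-carrying strand;
        # U.A:T is canonical in both orientations, and offsets by one or two
        # bases still clear the thresholds (>= 20 canonical triplets)
        assert all(h.purine_strand == "given" for h in hits)
        assert all(28 <= h.target_start <= 32 for h in hits)
        perfect = [h for h in hits if h.target_start == 30]
        assert {h.orientation for h in perfect} == {"direct", "indirect"}
        assert all(h.hit_score == pytest.approx(22 * 8.0) for h in perfect)
        assert all(h.hit_energy == pytest.approx(-22 * 8.0) for h in perfect)

    def test_pyrimidine_duplex_has_no_hits(self):
        third = RnaSequence(id="u", seq="U" * 22)
        duplex = DnaSequence(id="d", seq="C" * 100)
        assert find_triplex_sites(third, duplex) == []

    def test_third_longer_than_duplex_errors(self):
        with pytest.raises(ValueError, match="longer than duplex"):
            find_triplex_sites(THIRD, DnaSequence(id="d", seq="ACGT"))

    def test_matches_naive_rescoring(self, rng):
        for _ in range(5):
            t = "".join(rng.choice("ACGU") for _ in range(22))
            d = "".join(rng.choice("ACGT") for _ in range(300))
            hits = find_triplex_sites(
                RnaSequence(id="m", seq=t), DnaSequence(id="g", seq=d),
                score_threshold=-1000, energy_threshold=1000,
            )
            got = sorted(
                (h.target_start, h.orientation, h.purine_strand, h.hit_score, h.hit_energy)
                for h in hits
            )
            assert got == naive_scan(t, d, -1000, 1000)

    def test_registers_with_n_skipped(self):
        third = RnaSequence(id="u", seq="U" * 22)
        duplex = DnaSequence(id="d", seq="A" * 10 + "N" + "A" * 11 + "C" * 20 + "A" * 22)
        hits = find_triplex_sites(third, duplex)
        # every register containing the N (starts 0-10) is skipped even though
        # the A-run before the C block would otherwise score; only registers
        # over the final tract (starts 40-42, <= 2 C mismatches) survive
        assert {h.target_start for h in hits} == {40, 41, 42}

    def test_monotone_damage_from_noncanonical_triplet(self):
        """Perturbing one canonical triplet strictly lowers the score and
        raises the energy of that register."""
        third = RnaSequence(id="u", seq="U" * 22)
        perfect = DnaSequence(id="d", seq="A" * 22)
        damaged = DnaSequence(id="d", seq="A" * 10 + "C" + "A" * 11)
        h0 = find_triplex_sites(third, perfect, score_threshold=0, energy_threshold=0)
        h1 = find_triplex_sites(third, damaged, score_threshold=0, energy_threshold=0)
        best0 = max(h.hit_score for h in h0)
        best1 = max(h.hit_score for h in h1)
        assert best1 < best0
        assert min(h.hit_energy for h in h1) > min(h.hit_energy for h in h0)

    def test_score_additivity_over_disjoint_subregisters(self):
        """Ungapped scoring is additive: the register score equals the sum of
        the two halves scored independently."""
        t = THIRD.seq
        d = "A" * 5 + "GAGG" + "T" * 30
        full = naive_scan(t[:8], d, -1000, 1000)
        left = naive_scan(t[:4], d, -1000, 1000)
        right = naive_scan(t[4:8], d, -1000, 1000)
        f = {(s, o, st): sc for s, o, st, sc, _ in full}
        l = {(s, o, st): sc for s, o, st, sc, _ in left}
        # direct/given: third[k] aligns at s+k, so the right half at s+4
        r = {(s, o, st): sc for s, o, st, sc, _ in right}
        for s in range(len(d) - 8 + 1):
            key = (s, "direct", "given")
            assert f[key] == l[key] + r[(s + 4, "direct", "given")]


class TestThresholds:
    def test_perfect_22mer_passes_printed_thresholds(self):
        prom, _ = make_triplex_promoter(THIRD, [(100, "direct")], seed=1)
        hits = find_triplex_sites(THIRD, prom)
        (h,) = [h for h in hits if h.target_start == 100]
        assert h.hit_score == pytest.approx(176.0) and h.hit_score > 140
        assert h.hit_energy == pytest.approx(-176.0) and h.hit_energy < -140

    def test_three_noncanonical_triplets_fail(self):
        third = RnaSequence(id="u", seq="U" * 22)
        duplex = DnaSequence(id="d", seq="A" * 9 + "CCC" + "A" * 10)
        assert find_triplex_sites(third, duplex) == []
        # two non-canonical triplets still pass (22-mer: 144 > 140, -152 < -140)
        duplex2 = DnaSequence(id="d", seq="A" * 10 + "CC" + "A" * 10)
        hits = find_triplex_sites(third, duplex2)
        assert hits and hits[0].hit_score == pytest.approx(144.0)


class TestShuffleAndGrading:
    def test_shuffle_preserves_dinucleotide_counts(self, rng):
        from collections import Counter

        g = np.random.default_rng(5)
        for _ in range(20):
            s = "".join(rng.choice("ACGU") for _ in range(22))
            sh = dinucleotide_shuffle(s, g)
            assert Counter(zip(sh, sh[1:])) == Counter(zip(s, s[1:]))
            assert sh[0] == s[0] and sh[-1] == s[-1]

    def test_background_is_deterministic_given_seed(self):
        prom, _ = make_triplex_promoter(THIRD, [(50, "direct")], seed=2)
        a = background_scores(THIRD, prom, n=50, seed=9)
        b = background_scores(THIRD, prom, n=50, seed=9)
        assert np.array_equal(a, b)

    def test_grade_above_background_max_is_5(self):
        bg = np.arange(1000, dtype=float)
        (h,) = grade_hits([_hit(2000.0)], bg)
        assert h.grade == 5

    def test_grade_below_background_min_is_1(self):
        bg = np.arange(1000, dtype=float)
        (h,) = grade_hits([_hit(-5.0)], bg)
        assert h.grade == 1

    def test_constant_background_equal_score_is_grade_5(self):
        bg = np.full(1000, 176.0)
        (h,) = grade_hits([_hit(176.0)], bg)
        assert score_percentile(bg, 176.0) == 1.0
        assert h.grade == 5

    def test_intermediate_grades_match_direct_percentiles(self):
        bg = np.arange(1000, dtype=float)
        for score, expected in ((990.0, 5), (950.0, 4), (900.0, 3), (750.0, 2), (100.0, 1)):
            (h,) = grade_hits([_hit(score)], bg)
            pct = np.count_nonzero(bg <= score) / bg.size
            assert h.grade == expected
            assert pct == score_percentile(bg, score)

    def test_empty_background_errors(self):
        with pytest.raises(ValueError, match="empty background"):
            score_percentile(np.array([]), 1.0)


class TestSummaryMatrix:
    def test_indirect_only_cell(self):
        hits = [_hit(150.0, "indirect") for _ in range(4)]
        s = summarize_matrix(hits, ["m"], ["g"])
        assert s.cell_text("m", "g") == "-4"

    def test_mixed_cell(self):
        hits = [_hit(150.0, "indirect") for _ in range(3)] + [_hit(150.0, "direct")]
        s = summarize_matrix(hits, ["m"], ["g"])
        assert s.cell_text("m", "g") == "-3/+1"

    def test_no_hit_cell_and_dense_matrix(self):
        s = summarize_matrix([], ["m1", "m2"], ["g1", "g2"])
        assert s.cell_text("m1", "g2") == "0"
        assert set(s.matrix) == {("m1", "g1"), ("m1", "g2"), ("m2", "g1"), ("m2", "g2")}
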