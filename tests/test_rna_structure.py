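import random
import shutil
import subprocess

import numpy as np
import pytest

from oracles import brute_force_mfe, enumerate_structures, loop_score

from mirfunc.rna_structure import (
    EnergyModel,
    default_energy_window,
    dot_bracket_to_pairs,
    dot_plot,
    fold_mfe,
    fold_suboptimal,
    pairs_to_dot_bracket,
    stability_rank,
    structure_energy,
)
from mirfunc.sequence_io import RnaSequence
from mirfunc.synthetic_data import make_hairpin_rna


def _rna(s: str) -> RnaSequence:
    return RnaSequence(id="x", seq=s)


class TestEnergyModel:
    def test_watson_crick_stacks_are_stabilizing(self, model):
        wc = {"AU", "UA", "GC", "CG"}
        for (outer, inner), e in model.stack.items():
            if outer in wc and inner in wc:
                assert e <= 0

    def test_loop_tables_extrapolate_beyond_range(self, model):
        # log extrapolation keeps penalties finite and increasing
        assert model.hairpin_energy(9) < model.hairpin_energy(30) < 10
        assert model.bulge_energy(6) < model.bulge_energy(25)


class TestFoldMfe:
    def test_no_complementary_bases_stays_open(self, model):
        s = fold_mfe(_rna("AAAAAAAAAA"), model)
        assert s.dot_bracket == ".........."
        assert s.pairs == frozenset()
        assert s.energy == 0.0

    def test_min_loop_blocks_tiny_hairpin(self, model):
        s = fold_mfe(_rna("GC"), model)
        assert s.pairs == frozenset() and s.energy == 0.0

    def test_hairpin_matches_brute_force(self, model):
        seq = "GGGGAAAACCCC"
        s = fold_mfe(_rna(seq), model)
        assert s.energy == pytest.approx(brute_force_mfe(seq), abs=1e-9)
        assert len(s.pairs) >= 3

    def test_random_sequences_match_brute_force(self, model, rng):
        for _ in range(40):
            seq = "".join(rng.choice("ACGU") for _ in range(rng.randint(5, 12)))
            s = fold_mfe(_rna(seq), model)
            assert s.energy == pytest.approx(brute_force_mfe(seq), abs=1e-9), seq

    def test_reported_energy_is_recomputable_from_pairs(self, model, rng):
        for _ in range(20):
            seq = "".join(rng.choice("ACGU") for _ in range(16))
            s = fold_mfe(_rna(seq), model)
            if s.pairs:
                assert s.energy == pytest.approx(
                    structure_energy(seq, s.pairs, model), abs=1e-9
                )

    def test_mfe_never_positive(self, model, rng):
        for _ in range(30):
            seq = "".join(rng.choice("ACGU") for _ in range(22))
            assert fold_mfe(_rna(seq), model).energy <= 0.0


class TestFoldSuboptimal:
    def test_window_zero_returns_co_optimals_only(self, model, rng):
        for _ in range(10):
            seq = "".join(rng.choice("ACGU") for _ in range(18))
            r = fold_suboptimal(_rna(seq), model, energy_window=0.0)
            assert r.structure_count >= 1
            assert all(
                s.energy == pytest.approx(r.mfe, abs=1e-9) for s in r.structures
            )

    def test_full_enumeration_matches_oracle(self, model, rng):
        seq = "GGGAAAACCCAAAGGGAAAACC"  # two competing stems
        window = 4.0
        r = fold_suboptimal(_rna(seq), model, energy_window=window)
        limit = brute_force_mfe(seq) + window
        expected = {
            frozenset(s)
            for s in enumerate_structures(seq)
            if loop_score(seq, s) <= limit + 1e-9
        }
        if 0.0 <= limit + 1e-9:
            expected.add(frozenset())
        assert {s.pairs for s in r.structures} == expected

    def test_count_monotone_in_window(self, model, rng):
        seq = "".join(rng.choice("ACGU") for _ in range(22))
        counts = [
            fold_suboptimal(_rna(seq), model, energy_window=w).structure_count
            for w in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert counts == sorted(counts)

    def test_structures_sorted_and_deduplicated(self, model):
        r = fold_suboptimal(_rna("GGGAAAACCCAAAGGGAAAACC"), model, energy_window=5.0)
        energies = [s.energy for s in r.structures]
        assert energies == sorted(energies)
        assert len({s.pairs for s in r.structures}) == r.structure_count

    def test_default_window_percent_with_floor(self):
        assert default_energy_window(0.0) == 1.0
        assert default_energy_window(-10.0) == 1.0
        assert default_energy_window(-40.0) == pytest.approx(2.0)

    def test_one_of_demo_mirnas_is_single_structure(self, demo_bundle):
        """Qualitative analog of the published folding result: of five 20-22 nt
        microRNAs, one folds to a single structure within the default window
        and the rest have several near-optimal folds."""
        from mirfunc.sequence_io import read_fasta

        mirnas = read_fasta(demo_bundle["mirna_fasta"], "RNA")
        counts = [fold_suboptimal(m).structure_count for m in mirnas]
        assert sorted(counts)[0] >= 1
        assert sum(1 for c in counts if c == 1) == 1
        assert sum(1 for c in counts if c > 1) == len(counts) - 1


class TestDotPlot:
    def test_empty_structure_gives_zero_matrix(self, model):
        r = fold_suboptimal(_rna("AAAAAAAA"), model, energy_window=0.0)
        assert not dot_plot(r).any()

    def test_counts_shared_pairs(self, model):
        r = fold_suboptimal(_rna("GGGGAAAACCCC"), model, energy_window=3.0)
        m = dot_plot(r)
        union = set().union(*(s.pairs for s in r.structures))
        for i, j in union:
            expected = sum(1 for s in r.structures if (i, j) in s.pairs)
            assert m[i, j] == expected == m[j, i]
        assert set(zip(*np.nonzero(np.triu(m)))) == union

    def test_plot_file_written(self, model, tmp_path):
        r = fold_suboptimal(_rna("GGGGAAAACCCC"), model, energy_window=1.0)
        out = tmp_path / "dp.png"
        dot_plot(r, out)
        assert out.stat().st_size > 0


class TestStabilityRank:
    def test_lower_energy_ranks_first(self, model):
        folds = [
            fold_suboptimal(RnaSequence(id=name, seq=seq), model, energy_window=0.0)
            for name, seq in (
                ("a", "GGGGGAAAACCCCC"),
                ("b", "GGGAAAACCC"),
                ("c", "GCAAAAAAGC"),
            )
        ]
        energies = {f.sequence.id: f.mfe for f in folds}
        assert energies["a"] < energies["b"] < energies["c"]
        assert stability_rank(folds) == ["a", "b", "c"]

    def test_single_fold(self, model):
        f = fold_suboptimal(_rna("GGGGAAAACCCC"), model, energy_window=0.0)
        assert stability_rank([f]) == ["x"]

    def test_equal_energies_tie_break_lexicographic(self, model):
        f1 = fold_suboptimal(RnaSequence(id="b", seq="AAAA"), model, 0.0)
        f2 = fold_suboptimal(RnaSequence(id="a", seq="UUUU"), model, 0.0)
        assert stability_rank([f1, f2]) == ["a", "b"]


class TestDotBracket:
    def test_round_trip(self, model, rng):
        for _ in range(20):
            seq = "".join(rng.choice("ACGU") for _ in range(20))
            s = fold_mfe(_rna(seq), model)
            assert dot_bracket_to_pairs(s.dot_bracket) == s.pairs

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            dot_bracket_to_pairs("((.)")


class TestPlantedHairpinRecovery:
    def test_mfe_contains_most_planted_pairs(self, model):
        for seed in range(25):
            rna, truth = make_hairpin_rna(
                stem_len=4, loop_len=4, total_len=12 + (seed % 8), seed=seed
            )
            s = fold_mfe(rna, model)
            planted = {tuple(p) for p in truth["pairs"]}
            assert len(planted & s.pairs) >= len(planted) - 1, rna.seq


@pytest.mark.skipif(shutil.which("RNAfold") is None, reason="ViennaRNA not on PATH")
def test_qualitative_agreement_with_viennarna(model):
    """External cross-check: a strong GC hairpin is folded (negative energy,
    stem paired) by both this package and ViennaRNA; an unstructured homopolymer
    is open in both. Parameter sets differ, so only signs/shape are compared."""
    strong, open_ = "GGGGGGAAAACCCCCC", "AAAAAAAAAAAA"
    out = subprocess.run(
        ["RNAfold", "--noPS"],
        input=f"{strong}\n{open_}\n",
        capture_output=True,
        text=True,
        check=True,
    ).stdout.splitlines()
    strong_db, open_db = out[1].split(" ")[0], out[3].split(" ")[0]
    assert "(" in strong_db and float(out[1].split("(")[-1].rstrip(")")) < 0
    assert "(" not in open_db
    assert fold_mfe(_rna(strong), model).energy < 0
    assert fold_mfe(_rna(open_), model).energy == 0.0
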