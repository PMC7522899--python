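"""Precursor extraction, internal folding, arm/duplex analysis, screening."""

import itertools

import numpy as np
import pytest

from mirdir.formats_io import pair_table
from mirdir.hairpin import (PAIR_ENERGY, PrecursorCandidate, composition_stats,
                            compute_amfe, compute_mfei, duplex_mismatches,
                            evaluate_criteria, extract_precursor, fold_internal,
                            locate_arm, round2)
from mirdir.homology import HomologyHit, reverse_complement
from mirdir.synthetic import gen_hairpin

RNA = "ACGU"


def _hit(gene_id="g", start=0, end=21, strand="+", mirna_id="mir"):
    return HomologyHit(mirna_id=mirna_id, gene_id=gene_id, gene_start=start,
                       gene_end=end, strand=strand, mismatches=0, gaps=0,
                       score=21.0, evalue=1e-9)


class TestExtractPrecursor:
    def test_symmetric_window_arithmetic(self):
        rng = np.random.default_rng(0)
        gene = "".join(rng.choice(list("ACGT"), size=1000))
        hit = _hit(start=490, end=511)
        sym = [c for c in extract_precursor(gene, hit, [60])
               if c.id.endswith("sym")][0]
        assert len(sym.sequence) == 141
        assert (sym.mature_start, sym.mature_end) == (60, 81)
        assert not sym.clipped

    def test_window_clipped_at_gene_start_is_flagged(self):
        gene = "ACGT" * 30
        hit = _hit(start=10, end=31)
        up = [c for c in extract_precursor(gene, hit, [60])
              if c.id.endswith("up")][0]
        assert up.clipped
        assert len(up.sequence) == 31

    def test_minus_strand_mature_is_reverse_complement(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            gene = "".join(rng.choice(list("ACGT"), size=400))
            start = int(rng.integers(100, 250))
            hit = _hit(start=start, end=start + 21, strand="-")
            for cand in extract_precursor(gene, hit, [60]):
                expected = reverse_complement(
                    gene[start : start + 21]).replace("T", "U")
                assert cand.mature_sequence == expected

    def test_all_three_window_modes_per_flank(self):
        gene = "ACGT" * 100
        cands = extract_precursor(gene, _hit(start=150, end=171), [60, 100])
        assert len(cands) == 6

    def test_hit_outside_gene_rejected(self):
        with pytest.raises(ValueError):
            extract_precursor("ACGT", _hit(start=0, end=21), [60])


def enumerate_min_energy(seq, min_loop=3):
    """Exhaustive enumeration over all nested pair sets (tiny n only)."""
    n = len(seq)

    def pairs_energy(i, j):
        return PAIR_ENERGY.get((seq[i], seq[j]))

    def best(i, j):
        if j - i < min_loop + 1:
            return 0.0
        options = [best(i + 1, j)]  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            e = pairs_energy(i, k)
            if e is not None:
                options.append(e + best(i + 1, k - 1) + best(k + 1, j))
        return min(options)

    return best(0, n - 1)


class TestFoldInternal:
    def test_forced_optimum_structure_and_energy(self):
        rec = fold_internal("GGGGAAAACCCC")
        assert rec.structure == "((((....))))"
        assert rec.mfe_kcal_mol == -12.0

    def test_unpairable_sequence_all_dots(self):
        rec = fold_internal("AAAAAAAAAAAA")
        assert rec.structure == "." * 12
        assert rec.mfe_kcal_mol == 0.0

    def test_energy_matches_enumeration_oracle_up_to_length_12(self):
        rng = np.random.default_rng(19)
        for _ in range(40):
            n = int(rng.integers(10, 13))
            seq = "".join(rng.choice(list(RNA), size=n))
            assert fold_internal(seq).mfe_kcal_mol == \
                pytest.approx(enumerate_min_energy(seq))

    def test_structure_energy_consistent_with_pairs(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            seq = "".join(rng.choice(list(RNA), size=60))
            rec = fold_internal(seq)
            partner = pair_table(rec.structure)
            total = sum(PAIR_ENERGY[(seq[i], seq[j])]
                        for i, j in enumerate(partner) if j > i)
            assert rec.mfe_kcal_mol == pytest.approx(total)
            assert rec.mfe_kcal_mol <= 0

    def test_deterministic(self):
        seq = "GCGCAAAUAGCGCUAGCAUCGGCGC"
        assert fold_internal(seq).structure == fold_internal(seq).structure

    def test_min_hairpin_loop_respected(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            seq = "".join(rng.choice(list(RNA), size=30))
            partner = pair_table(fold_internal(seq).structure)
            for i, j in enumerate(partner):
                if j > i:
                    assert j - i > 3

    def test_non_rna_rejected(self):
        with pytest.raises(ValueError):
            fold_internal("ACGTXACGTACG")


class TestArmAndDuplex:
    def test_mature_on_closing_strand_is_3p(self):
        cand, _ = gen_hairpin(lp=80, mature_len=21, arm="3p",
                              duplex_mismatches=0, au_target_pct=50, seed=1)
        assert locate_arm(cand) == "3p"

    def test_mirror_case_is_5p(self):
        cand, _ = gen_hairpin(lp=80, mature_len=21, arm="5p",
                              duplex_mismatches=0, au_target_pct=50, seed=1)
        assert locate_arm(cand) == "5p"

    def test_mature_spanning_the_loop_fails_one_arm(self):
        seq = "GGGGGGGGGG" + "AAAA" + "CCCCCCCCCC"
        structure = "(" * 10 + "." * 4 + ")" * 10
        cand = PrecursorCandidate("x", seq, 5, 19, structure, -30.0)
        assert locate_arm(cand) is None
        ev = evaluate_criteria(cand)
        assert not ev.criteria["mature_in_one_arm"]

    def test_unpaired_structure_has_no_arm(self):
        cand = PrecursorCandidate("x", "A" * 70, 10, 31, "." * 70, 0.0)
        assert locate_arm(cand) is None

    def test_perfect_hairpin_has_zero_duplex_mismatches(self):
        cand, _ = gen_hairpin(lp=80, mature_len=21, arm="3p",
                              duplex_mismatches=0, au_target_pct=50, seed=2)
        assert duplex_mismatches(cand) == 0

    @pytest.mark.parametrize("k", [1, 2, 4, 6])
    def test_planted_unpaired_positions_counted_exactly(self, k):
        for seed in (1, 2, 3):
            cand, _ = gen_hairpin(lp=90, mature_len=21, arm="3p",
                                  duplex_mismatches=k, au_target_pct=50,
                                  seed=seed)
            assert duplex_mismatches(cand) == k

    def test_internal_loop_of_one_counts_once(self):
        # 10-pair stem with the pair at stem position 5 opened on both sides
        seq = "GGGGGGGGGG" + "AAAA" + "CCCCCCCCCC"
        structure = list("(" * 10 + "." * 4 + ")" * 10)
        structure[4] = "."
        structure[19] = "."
        cand = PrecursorCandidate("x", seq, 14, 24, "".join(structure), -27.0)
        assert duplex_mismatches(cand) == 1


class TestCompositionAndIndices:
    def test_uniform_sequence(self):
        stats = composition_stats("AUGC")
        assert (stats["a_pct"], stats["u_pct"], stats["g_pct"], stats["c_pct"]) \
            == (25.0, 25.0, 25.0, 25.0)
        assert stats["au_ratio"] == 1.0 and stats["gc_ratio"] == 1.0
        assert stats["au_content_pct"] == 50.0

    def test_published_mature_sequence_gc_content(self):
        stats = composition_stats("GAGAACGCGUCGUCGACGAGU")
        assert stats["gc_content_pct"] == 61.90

    def test_published_precursor_ratio_arithmetic(self):
        # A 27.21 / U 23.81 -> 1.14 ; A+U = 51.02 under the same rounding
        assert round2(27.21 / 23.81) == 1.14
        assert round2(27.21 + 23.81) == 51.02

    def test_zero_denominator_gives_undefined_ratio(self):
        stats = composition_stats("AAGG")
        assert stats["au_ratio"] is None and stats["gc_ratio"] is None

    def test_percentages_sum_to_100_on_random_sequences(self):
        rng = np.random.default_rng(53)
        for _ in range(1000):
            seq = "".join(rng.choice(list(RNA), size=int(rng.integers(20, 200))))
            s = composition_stats(seq)
            assert s["a_pct"] + s["u_pct"] + s["g_pct"] + s["c_pct"] == \
                pytest.approx(100.0, abs=0.0201)  # four half-up roundings

    @pytest.mark.parametrize("mfe, lp, expected", [
        (39.6, 147, 26.94),
        (56.4, 129, 43.72),
        (187.1, 227, 82.42),
        (0.0, 100, 0.0),
    ])
    def test_amfe(self, mfe, lp, expected):
        assert compute_amfe(mfe, lp) == expected

    @pytest.mark.parametrize("amfe, gc, expected", [
        (26.94, 48.98, 0.55),
        (43.72, 27.91, 1.57),
        (82.42, 75.33, 1.09),
        (50.0, 50.0, 1.0),
    ])
    def test_mfei(self, amfe, gc, expected):
        assert compute_mfei(amfe, gc) == expected

    def test_zero_gc_mfei_undefined(self):
        assert compute_mfei(30.0, 0.0) is None

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            compute_amfe(10.0, 0)


class TestEvaluateCriteria:
    def test_valid_synthetic_hairpin_passes_all(self):
        cand, _ = gen_hairpin(lp=80, mature_len=21, arm="3p",
                              duplex_mismatches=1, au_target_pct=50, seed=4)
        ev = evaluate_criteria(cand)
        assert ev.passes_all
        assert ev.arm == "3p" and ev.lp == 80 and ev.lm == 21

    def test_low_au_content_fails_criterion_six_only(self):
        cand, _ = gen_hairpin(lp=80, mature_len=21, arm="3p",
                              duplex_mismatches=0, au_target_pct=25, seed=4)
        ev = evaluate_criteria(cand)
        assert not ev.criteria["au_content"]
        assert not ev.passes_all
        assert all(ev.criteria[c] for c in
                   ("min_length", "stem_loop", "mature_in_one_arm",
                    "duplex_mismatches", "no_multibranch", "negative_mfe"))

    def test_length_59_fails_minimum_length(self):
        cand, _ = gen_hairpin(lp=59, mature_len=21, arm="3p",
                              duplex_mismatches=0, au_target_pct=50, seed=4,
                              loop_len=5)
        ev = evaluate_criteria(cand)
        assert not ev.criteria["min_length"]
        assert not ev.passes_all

    def test_seven_duplex_mismatches_fail_criterion_four(self):
        cand, _ = gen_hairpin(lp=90, mature_len=21, arm="3p",
                              duplex_mismatches=7, au_target_pct=50, seed=4)
        ev = evaluate_criteria(cand)
        assert not ev.criteria["duplex_mismatches"]

    def test_amfe_mfei_recompute_from_reported_fields(self):
        cand, _ = gen_hairpin(lp=100, mature_len=21, arm="5p",
                              duplex_mismatches=2, au_target_pct=45, seed=6)
        ev = evaluate_criteria(cand)
        assert ev.amfe == compute_amfe(ev.mfe_magnitude, ev.lp)
        assert ev.mfei == compute_mfei(ev.amfe, ev.gc_content_pct)

    def test_mfei_floor_advisory_by_default_but_gates_in_strict_mode(self):
        cand, _ = gen_hairpin(lp=80, mature_len=21, arm="3p",
                              duplex_mismatches=0, au_target_pct=50, seed=7)
        lax = evaluate_criteria(cand, mfei_floor=99.0, enforce_mfei=False)
        strict = evaluate_criteria(cand, mfei_floor=99.0, enforce_mfei=True)
        assert lax.passes_all and not strict.passes_all

    def test_pure_function(self):
        cand, _ = gen_hairpin(lp=80, mature_len=21, arm="3p",
                              duplex_mismatches=1, au_target_pct=50, seed=8)
        assert evaluate_criteria(cand) == evaluate_criteria(cand)

    def test_unfolded_candidate_rejected(self):
        cand = PrecursorCandidate("x", "ACGU" * 20, 0, 21)
        with pytest.raises(ValueError):
            evaluate_criteria(cand)


class TestFoldProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.text(alphabet="ACGU", min_size=10, max_size=35))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_fold_structure_valid_pairs_legal_energy_nonpositive(self, seq):
        from mirdir.formats_io import validate_dot_bracket
        rec = fold_internal(seq)
        validate_dot_bracket(rec.structure)
        partner = pair_table(rec.structure)
        for i, j in enumerate(partner):
            if j > i:
                assert (seq[i], seq[j]) in PAIR_ENERGY
                assert j - i > 3
        assert rec.mfe_kcal_mol <= 0
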