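import numpy as np
import pytest

import oracles
from mirforge.formats_io import revcomp
from mirforge.hairpin import (
    CriteriaConfig,
    HairpinStructure,
    apply_criteria,
    decompose,
    evaluate_window,
    extract_features,
    extract_flank,
    extract_stemloop,
    fold,
)
from mirforge.synthetic_data import baseline_fixture, build_hairpin


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestFold:
    def test_no_complementarity_no_pairs(self):
        s = fold("AAAAAAAAAA")
        assert s.n_pairs == 0
        assert s.free_energy == 0.0
        assert s.dot_bracket == "." * 10

    def test_gc_stem_with_minimal_loop(self):
        s = fold("GGGAAAACCC")
        assert s.dot_bracket == "(((....)))"
        # three G:C pairs at -3.0 each
        assert s.free_energy == -9.0

    def test_rna_alphabet_accepted(self):
        assert fold("GGGAAAACCC").free_energy == fold("GGGAAAACCC".replace("T", "U")).free_energy

    def test_non_acgu_rejected(self):
        with pytest.raises(ValueError, match="non-ACGU"):
            fold("GGGANNNCCC")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            fold("GGGCCC")

    def test_min_loop_of_three_enforced(self):
        # pairing across fewer than 3 intervening bases is disallowed
        s = fold("GGGGGAACCCCC")
        for i, j in s.pairing.items():
            if i < j:
                assert j - i > 3

    def test_deterministic(self):
        seq = "GGCAGCAAUGGGCUACUUAAGCUGCC"
        assert fold(seq).dot_bracket == fold(seq).dot_bracket

    def test_matches_enumeration_on_small_random_sample(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            seq = random_seq(rng, int(rng.integers(10, 26)))
            assert fold(seq).free_energy == pytest.approx(
                oracles.enumerate_min_energy(seq), abs=1e-9
            )


class TestDecompose:
    def test_perfect_stem(self):
        d = decompose(HairpinStructure("G" * 6 + "AAAA" + "C" * 6, "((((((....))))))", -18.0))
        assert d.is_hairpin
        assert len(d.pairs) == 6
        assert d.loop_length == 4
        assert d.bulges == ()

    def test_single_asymmetric_bulge(self):
        db = "(((.(((....))))))"
        seq = "GGGAGGGAAAACCCCCC"
        d = decompose(HairpinStructure(seq, db, -18.0))
        assert d.is_hairpin
        assert len(d.pairs) == 6
        assert d.loop_length == 4
        assert len(d.bulges) == 1
        assert (d.bulges[0].nt5, d.bulges[0].nt3) == (1, 0)

    def test_two_hairpins_rejected(self):
        db = "(((...)))...(((...)))"
        seq = "GGGAAACCCAAAGGGAAACCC"
        d = decompose(HairpinStructure(seq, db, -18.0))
        assert not d.is_hairpin
        assert "terminal loop" in d.reason

    def test_no_pairs_rejected(self):
        d = decompose(HairpinStructure("ACGTACGTAC", ".........." , 0.0))
        assert not d.is_hairpin

    def test_position_conservation_on_random_folds(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(120):
            s = fold(random_seq(rng, int(rng.integers(30, 61))))
            d = decompose(s)
            if not d.is_hairpin:
                continue
            n = len(s.sequence)
            covered = (
                len(d.stem_positions)
                + len(d.loop_positions)
                + sum(len(b.positions) for b in d.bulges)
                + len(d.external_positions)
            )
            assert covered == n
            checked += 1
        assert checked >= 5


class TestFeatures:
    def test_perfect_stem_mature_in_arm(self):
        structure, mature = baseline_fixture()
        f = extract_features(structure, mature)
        assert (
            f.max_stem_bulge_nt, f.stem_base_pairs, f.hairpin_length,
            f.loop_length, f.max_mature_bulge_nt, f.max_mature_bulge_bias,
            f.mature_biased_bulges, f.mature_errors, f.mature_base_pairs,
            f.mature_in_stem_pct,
        ) == (0, 30, 68, 8, 0, 0, 0, 0, 21, 100.0)

    def test_symmetric_internal_loop_in_mature(self):
        s, pos5, _ = build_hairpin(30, 8, bulges=[(14, 5, 5)])
        f = extract_features(s, (pos5[4], pos5[24] + 1))
        assert f.max_mature_bulge_nt == 10
        assert f.max_mature_bulge_bias == 0
        assert f.mature_biased_bulges == 0

    def test_mature_half_in_terminal_loop(self):
        s, pos5, _ = build_hairpin(30, 12)
        mature = (pos5[20], pos5[29] + 1 + 10)  # 10 paired + 10 loop bases
        f = extract_features(s, mature)
        assert f.mature_in_stem_pct == pytest.approx(50.0)

    def test_out_of_bounds_interval(self):
        structure, _ = baseline_fixture()
        with pytest.raises(ValueError, match="out of bounds"):
            extract_features(structure, (0, len(structure.sequence) + 1))


class TestCriteria:
    def boundary_features(self):
        from mirforge.hairpin import StructuralFeatures

        return StructuralFeatures(12, 16, -15.0, 50, 200, 4, 2, 2, 4, 12, 80.0)

    def test_all_boundary_values_pass(self):
        v = apply_criteria(self.boundary_features())
        assert v.passed
        assert all(r.passed for r in v.results)

    def test_fifteen_stem_pairs_fails_only_that_criterion(self):
        import dataclasses

        f = dataclasses.replace(self.boundary_features(), stem_base_pairs=15)
        v = apply_criteria(f)
        assert not v.passed
        assert v.failed_names() == ["stem_base_pairs"]

    def test_weak_energy_fails_only_that_criterion(self):
        import dataclasses

        f = dataclasses.replace(self.boundary_features(), free_energy=-14.9)
        v = apply_criteria(f)
        assert v.failed_names() == ["free_energy"]

    def test_tightening_thresholds_is_monotone(self):
        import dataclasses

        rng = np.random.default_rng(3)
        structures = []
        for _ in range(30):
            s = fold(random_seq(rng, 80))
            d = decompose(s)
            if d.is_hairpin and d.pairs:
                structures.append((s, (5, 26)))
        default = CriteriaConfig()
        tighter_each = [
            dataclasses.replace(default, max_stem_bulge_nt=6),
            dataclasses.replace(default, min_stem_base_pairs=20),
            dataclasses.replace(default, max_free_energy=-30.0),
            dataclasses.replace(default, min_hairpin_length=60),
            dataclasses.replace(default, max_loop_length=10),
            dataclasses.replace(default, min_mature_in_stem_pct=95.0),
        ]
        for s, mature in structures:
            f = extract_features(s, mature)
            base = apply_criteria(f, default).passed
            for cfg in tighter_each:
                if apply_criteria(f, cfg).passed:
                    assert base  # tighter pass implies default pass

    def test_verdict_records_bias_interpretation(self):
        v = apply_criteria(self.boundary_features())
        assert "asymmetry" in v.bias_interpretation
        d = v.to_dict()
        assert len(d["criteria"]) == 11


class TestStemloopExtraction:
    def test_embedded_hairpin_recovered_from_window(self):
        rng = np.random.default_rng(11)
        mature = "GCTAGCTAGGATCGATCGATG"
        core = mature + "A" * 8 + revcomp(mature)
        window = random_seq(rng, 90) + core + random_seq(rng, 90)
        m0 = 90
        m1 = 90 + len(mature)
        v = evaluate_window(fold(window), (m0, m1))
        assert v.passed, v.failed_names() or v.reason

    def test_sub_structure_is_single_hairpin(self):
        rng = np.random.default_rng(13)
        window = random_seq(rng, 150)
        s = fold(window)
        got = extract_stemloop(s, (60, 81))
        if got is not None:
            sub, lo = got
            d = decompose(sub)
            assert d.is_hairpin
            assert lo >= 0


class TestExtractFlank:
    def test_central_hit_window_arithmetic(self):
        rng = np.random.default_rng(5)
        scaffold = random_seq(rng, 1000)
        window, m0, m1 = extract_flank(scaffold, 500, 521)
        assert len(window) == 120 + 21 + 120
        assert (m0, m1) == (120, 141)
        assert window[m0:m1] == scaffold[500:521]

    def test_left_clipping(self):
        rng = np.random.default_rng(5)
        scaffold = random_seq(rng, 1000)
        window, m0, m1 = extract_flank(scaffold, 10, 31)
        assert m0 == 10
        assert len(window) == 10 + 21 + 120

    def test_minus_strand_is_reverse_complement(self):
        rng = np.random.default_rng(5)
        scaffold = random_seq(rng, 500)
        window, m0, m1 = extract_flank(scaffold, 200, 221, strand="-")
        plus_window, p0, p1 = extract_flank(scaffold, 200, 221, strand="+")
        assert window == revcomp(plus_window)
        assert window[m0:m1] == revcomp(scaffold[200:221])
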