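import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirforge.annotate import (
    ANNOTATED_MATURE,
    CANDIDATE_PC,
    ELSEWHERE,
    KNOWN_SPECIES,
    KNOWN_XENO,
    NOVEL_ARM,
    OPPOSITE_ARM,
    UNANNOTATED,
    GenomeIndex,
    align_tag_to_precursor,
    classify_tag,
    classify_tags,
    mature_name_from_precursor,
    name_mirna,
    parse_mirna_name,
)
from mirforge.formats_io import revcomp
from mirforge.preprocess import UniqueTag
from mirforge.synthetic_data import make_precursor


# deliberately non-periodic so the star arm cannot mimic the mature
MATURE = "GGCAGCAATGGGCTACTTACG"
PREC = make_precursor(MATURE, 8, id="zma-MIR395o", species="zma")


def brute_force_alignments(tag, precursor, max_internal_mm=1, mev=3):
    """Oracle: every ungapped placement scored by direct position-wise
    comparison, internal region = positions mev..len-mev."""
    hits = []
    seq = precursor.sequence
    for start in range(len(seq) - len(tag) + 1):
        window = seq[start : start + len(tag)]
        internal = sum(
            1 for k in range(mev, len(tag) - mev) if tag[k] != window[k]
        )
        if internal <= max_internal_mm:
            hits.append((start, internal))
    return hits


class TestAlignment:
    def test_exact_mature_placement(self):
        hits = align_tag_to_precursor(MATURE, PREC)
        exact = [h for h in hits if h.internal_mismatches == 0 and h.arm_hit == ANNOTATED_MATURE]
        assert len(exact) == 1
        aln = exact[0]
        assert (aln.shift5, aln.shift3) == (0, 0)
        assert aln.arm == "5p"

    def test_one_internal_substitution_accepted(self):
        mutated = MATURE[:10] + ("A" if MATURE[10] != "A" else "C") + MATURE[11:]
        hits = align_tag_to_precursor(mutated, PREC)
        best = [h for h in hits if h.arm_hit == ANNOTATED_MATURE]
        assert best and best[0].internal_mismatches == 1

    def test_two_internal_substitutions_rejected(self):
        bad = list(MATURE)
        for p in (8, 12):
            bad[p] = "A" if bad[p] != "A" else "C"
        bad = "".join(bad)
        hits = align_tag_to_precursor(bad, PREC)
        starts = {h.start for h in hits}
        oracle = {s for s, _ in brute_force_alignments(bad, PREC)}
        assert starts == oracle
        # the true placement (the mature offset) must be gone
        mature_start = PREC.mature_arms[0].slice0[0]
        assert mature_start not in starts

    def test_matches_placement_oracle_on_random_tags(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tag = "".join("ACGT"[i] for i in rng.integers(0, 4, size=21))
            got = {(h.start, h.internal_mismatches) for h in align_tag_to_precursor(tag, PREC)}
            assert got == set(brute_force_alignments(tag, PREC))

    def test_end_shift_reported_as_outward_extension(self):
        s0, e0 = PREC.mature_arms[0].slice0
        trimmed = PREC.sequence[s0 + 1 : e0]  # 5' end trimmed by 1
        (aln,) = [
            h for h in align_tag_to_precursor(trimmed, PREC) if h.arm_hit == ANNOTATED_MATURE
        ]
        assert aln.shift5 == -1
        assert aln.shift3 == 0
        extended = PREC.sequence[s0 : e0 + 2]  # 3' end extended by 2
        (aln,) = [
            h for h in align_tag_to_precursor(extended, PREC) if h.arm_hit == ANNOTATED_MATURE
        ]
        assert (aln.shift5, aln.shift3) == (0, 2)


class TestNaming:
    @pytest.mark.parametrize(
        "base,shift5,shift3,expected",
        [
            ("zma-miR395a-3p", -1, 0, "zma-miR395a-3p_L-1"),
            ("zma-miR168b-3p", 0, 1, "zma-miR168b-3p_R+1"),
            ("zma-miR397a-5p", -3, 0, "zma-miR397a-5p_L-3"),
            ("zma-miR167g-3p", 1, 0, "zma-miR167g-3p_L+1"),
            ("zma-miR156d-3p", 0, 0, "zma-miR156d-3p"),
        ],
    )
    def test_shift_suffix_grammar(self, base, shift5, shift3, expected):
        assert name_mirna(base, shift5, shift3) == expected

    def test_parse_known_exemplars(self):
        assert parse_mirna_name("zma-miR167g-3p_L+1") == {
            "kind": "mirna", "base": "zma-miR167g-3p", "left": 1, "right": 0, "variant": 1,
        }
        got = parse_mirna_name("PC-5p-19607_184")
        assert got == {"kind": "pc", "arm": "5p", "serial": 19607, "count": 184, "variant": 1}
        assert parse_mirna_name("zma-MIR395o-p5")["base"] == "zma-MIR395o-p5"

    def test_parse_rejects_malformed_suffix(self):
        with pytest.raises(ValueError):
            parse_mirna_name("zma-miR1-5p_L+0")
        with pytest.raises(ValueError):
            parse_mirna_name("")

    @settings(max_examples=200, deadline=None)
    @given(
        st.text(alphabet="abcdefgh-R135pmiz", min_size=1, max_size=15).filter(
            lambda b: "_" not in b
        ),
        st.integers(-3, 3),
        st.integers(-3, 3),
        st.integers(1, 4),
    )
    def test_format_parse_roundtrip(self, base, left, right, variant):
        name = name_mirna(base, left, right, variant)
        got = parse_mirna_name(name)
        assert got["base"] == base
        assert got["left"] == left
        assert got["right"] == right
        assert got["variant"] == variant

    def test_mature_name_derivation(self):
        assert mature_name_from_precursor("zma-MIR395o", "5p") == "zma-miR395o-5p"
        assert mature_name_from_precursor("novelLocus", "3p") == "novelLocus-3p"


class TestClassification:
    def test_annotated_mature_is_known_species(self):
        ann = classify_tag(MATURE, [PREC])
        assert ann.category == KNOWN_SPECIES
        assert ann.name == "zma-miR395o-5p"

    def test_shifted_tag_gets_suffix(self):
        s0, e0 = PREC.mature_arms[0].slice0
        ann = classify_tag(PREC.sequence[s0 + 1 : e0], [PREC])
        assert ann.category == KNOWN_SPECIES
        assert ann.name == "zma-miR395o-5p_L-1"

    def test_opposite_arm_is_novel(self):
        L = len(PREC.sequence)
        s0, e0 = PREC.mature_arms[0].slice0
        star = PREC.sequence[L - e0 : L - s0]
        ann = classify_tag(star, [PREC])
        assert ann.category == NOVEL_ARM
        assert ann.name == "zma-MIR395o-p3"

    def test_xeno_requires_genome_support(self):
        xeno = make_precursor("TGCATGCATGCATGCATGCAC", 8, id="osa-MIR901", species="osa")
        xmature = xeno.mature_sequence("5p")
        genome_with = {"s1": "ACGT" * 30 + xeno.sequence + "TGCA" * 30}
        ann = classify_tag(xmature, [PREC], [xeno], GenomeIndex(genome_with))
        assert ann.category == KNOWN_XENO
        assert ann.name == "osa-miR901-5p"
        genome_without = {"s1": "ACGT" * 100}
        ann2 = classify_tag(xmature, [PREC], [xeno], GenomeIndex(genome_without))
        assert ann2.category == UNANNOTATED

    def test_genome_candidate_named_pc(self):
        rng = np.random.default_rng(4)
        mature = "GCTAGCTAGGATCGATCGATG"
        ext = "GGATCCAT"
        core = ext + mature + "A" * 8 + revcomp(ext + mature)
        flank1 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
        flank2 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
        genome = {"s1": flank1 + core + flank2}
        tag = UniqueTag(mature, {"lib": 184})
        ann = classify_tag(tag, [PREC], [], GenomeIndex(genome))
        assert ann.category == CANDIDATE_PC
        parsed = parse_mirna_name(ann.name)
        assert parsed["kind"] == "pc"
        assert parsed["arm"] == "5p"
        assert parsed["count"] == 184

    def test_unmatched_tag_unannotated(self):
        ann = classify_tag("TTTTGGGGAAAACCCCTTTTG", [PREC])
        assert ann.category == UNANNOTATED

    def test_precursor_order_does_not_change_annotations(self):
        precs = [
            make_precursor("ACGTACGTACGTACGTACGTG", 8, id=f"zma-MIR{i:03d}", seed=i)
            for i in (1, 2, 3)
        ]
        tags = [UniqueTag(MATURE, {"a": 5})]
        a1 = classify_tags(tags, precs)
        a2 = classify_tags(tags, precs[::-1])
        assert [(x.name, x.category, x.source) for x in a1] == [
            (x.name, x.category, x.source) for x in a2
        ]

    def test_name_collision_resolved_with_variant_suffix(self):
        mutated = MATURE[:10] + ("A" if MATURE[10] != "A" else "C") + MATURE[11:]
        tags = [UniqueTag(MATURE, {"a": 100}), UniqueTag(mutated, {"a": 3})]
        anns = classify_tags(tags, [PREC])
        names = {a.tag_sequence: a.name for a in anns}
        assert names[MATURE] == "zma-miR395o-5p"  # abundant tag claims the bare name
        assert names[mutated] == "zma-miR395o-5p_v2"
        assert parse_mirna_name(names[mutated])["variant"] == 2
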