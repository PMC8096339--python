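"""Rule-based term assignment: chemistry, coding effects, kinds, splice, size."""

import itertools

import pytest

from vario_rna.classifier import (
    MetadataError,
    check_no_contradictions,
    classify_coding_effect,
    classify_full,
    classify_kind_terms,
    classify_ncrna_size,
    classify_splice_variant,
    classify_substitution_chemistry,
)
from vario_rna.examples import annotate_example, load_examples
from vario_rna.hgvs import parse_variant
from vario_rna.synthetic import generate_variants
from vario_rna.transcript import ContextError, TranscriptContext, net_length_change

BTK = TranscriptContext("BTK", cds_start=1, cds_end=1980, rna_class="mRNA")


class TestChemistry:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            ("g", "u", ["RNA substitution", "transversion"]),
            ("g", "a", ["RNA substitution", "transition", "purine transition"]),
            ("c", "u", ["RNA substitution", "transition", "pyrimidine transition"]),
            ("C", "T", ["RNA substitution", "transition", "pyrimidine transition"]),
        ],
    )
    def test_worked_pairs(self, ref, alt, expected):
        assert classify_substitution_chemistry(ref, alt) == expected

    def test_partition_over_all_ordered_pairs(self):
        transitions, transversions = [], []
        purine, pyrimidine = [], []
        for ref, alt in itertools.permutations("acgu", 2):
            names = classify_substitution_chemistry(ref, alt)
            assert names[0] == "RNA substitution"
            if "transition" in names:
                transitions.append((ref, alt))
                if "purine transition" in names:
                    purine.append((ref, alt))
                if "pyrimidine transition" in names:
                    pyrimidine.append((ref, alt))
                assert ("purine transition" in names) != (
                    "pyrimidine transition" in names
                )
            else:
                assert "transversion" in names
                transversions.append((ref, alt))
        assert len(transitions) == 4
        assert len(purine) == len(pyrimidine) == 2
        assert len(transversions) == 8

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution_chemistry("a", "a")


class TestCodingEffect:
    def test_initiation_codon_change(self):
        eff = classify_coding_effect(parse_variant("r.3g>u"), BTK)
        assert eff.effect_label == "initiation_codon_change"
        assert eff.codon_index == 1

    @pytest.mark.parametrize(
        "s, ref_codon, label",
        [
            ("r.1135c>u", "caa", "nonsense"),
            ("r.954u>c", "agu", "silent"),
            ("r.1559g>a", "cga", "missense"),
        ],
    )
    def test_substitution_labels_from_reference_codon(self, s, ref_codon, label):
        eff = classify_coding_effect(parse_variant(s), BTK, ref_codon=ref_codon)
        assert eff.effect_label == label

    def test_termination_codon_change_at_stop(self):
        kiss1r = TranscriptContext("KISS1R", cds_start=1, cds_end=1197)
        eff = classify_coding_effect(
            parse_variant("r.1195u>c"), kiss1r, ref_codon="uga"
        )
        assert eff.effect_label == "termination_codon_change"

    def test_stop_to_stop_exchange_is_silent(self):
        kiss1r = TranscriptContext("KISS1R", cds_start=1, cds_end=1197)
        eff = classify_coding_effect(
            parse_variant("r.1197a>g"), kiss1r, ref_codon="uaa"
        )
        assert eff.effect_label == "silent"

    def test_in_frame_deletion_residue_range(self):
        eff = classify_coding_effect(parse_variant("r.777_839del"), BTK)
        assert eff.frame_status == "in_frame"
        assert eff.protein_del_range == (260, 280)

    def test_frameshift_deletion(self):
        eff = classify_coding_effect(parse_variant("c.1953del"), BTK)
        assert eff.frame_status == "out_of_frame"
        assert eff.effect_label == "frameshift"

    def test_missing_reference_codon_is_insufficient_context(self):
        with pytest.raises(ContextError):
            classify_coding_effect(parse_variant("r.954u>c"), BTK)

    def test_variant_beyond_cds_is_not_applicable(self):
        eff = classify_coding_effect(parse_variant("r.1990a>g"), BTK)
        assert eff.frame_status == "not_applicable"


class TestKindTerms:
    @pytest.mark.parametrize(
        "s, expected",
        [
            ("r.777_839del", ["RNA deletion", "in-frame deletion"]),
            ("c.1953del", ["RNA deletion", "out-of-frame deletion"]),
            ("r.1812_1813insgacagu", ["RNA insertion", "in-frame insertion"]),
            ("r.1682_1683delinsa", ["RNA indel", "out-of-frame indel"]),
            ("r.1401_1402delinsuu", ["RNA indel", "in-frame indel"]),
            ("r.100_120inv", ["RNA inversion"]),
        ],
    )
    def test_coding_context(self, s, expected):
        assert classify_kind_terms(parse_variant(s), BTK) == expected

    def test_noncoding_molecule_gets_no_frame_subterm(self):
        mir = TranscriptContext("MIR140", rna_class="microRNA")
        assert classify_kind_terms(parse_variant("r.5_7del"), mir) == ["RNA deletion"]

    def test_no_context_gets_no_frame_subterm(self):
        assert classify_kind_terms(parse_variant("r.5_7del"), None) == ["RNA deletion"]


class TestSpliceTerms:
    def test_non_canonical_donor(self):
        names = classify_splice_variant(parse_variant("c.839+5G>A"))
        assert names == [
            "variation at five prime splice site",
            "variation at non canonical five prime splice site",
        ]

    def test_canonical_acceptor(self):
        names = classify_splice_variant(parse_variant("c.392-2A>C"))
        assert names == [
            "variation at three prime splice site",
            "variation at canonical three prime splice site",
        ]

    def test_recursive_site_flag_appends_term(self):
        names = classify_splice_variant(
            parse_variant("c.100+1g>a"), recursive_site=True
        )
        assert "variation at recursive splice site" in names

    def test_exonic_variant_rejected(self):
        with pytest.raises(ValueError):
            classify_splice_variant(parse_variant("r.954u>c"))


class TestSizeClasses:
    @pytest.mark.parametrize(
        "length, expected",
        [
            (22, "short non-coding RNA"),
            (199, "short non-coding RNA"),
            (200, "long non-coding RNA"),
            (10_000, "long non-coding RNA"),
            (10_001, "very long non-coding RNA"),
            (1_000_000, "very long non-coding RNA"),
        ],
    )
    def test_boundaries(self, length, expected):
        assert classify_ncrna_size(length) == expected

    def test_every_length_maps_to_exactly_one_class(self):
        probe = list(range(1, 300)) + [9_999, 10_000, 10_001, 50_000]
        classes = {
            "short non-coding RNA",
            "long non-coding RNA",
            "very long non-coding RNA",
        }
        for n in probe:
            assert classify_ncrna_size(n) in classes

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            classify_ncrna_size(0)


class TestClassifyFull:
    def test_initiation_example_terms(self, hierarchy):
        ann = classify_full(parse_variant("r.3g>u"), BTK, hierarchy=hierarchy)
        assert set(ann.names()) == {
            "initiation codon change",
            "RNA substitution",
            "transversion",
        }

    def test_metadata_terms_validated_never_inferred(self, hierarchy):
        v = parse_variant("c.1442G>C")
        ann = classify_full(
            v, BTK, meta=["VariO:0247"], hierarchy=hierarchy, ref_codon="ugu"
        )
        basis = {t.name: t.basis for t in ann.terms}
        assert basis["artificial RNA variation"] == "metadata"
        with pytest.raises(MetadataError):
            classify_full(v, BTK, meta=["VariO:8888"], hierarchy=hierarchy,
                          ref_codon="ugu")

    def test_worked_examples_concordance(self, hierarchy):
        for ex in load_examples():
            ann = annotate_example(ex, hierarchy)
            got = set(ann.accessions())
            assert set(ex.expected) <= got, (ex.variant, set(ex.expected) - got)
            assert check_no_contradictions(ann) == [], ex.variant
            assert len(ann.accessions()) == len(set(ann.accessions()))

    def test_frame_partition_on_seeded_variants(self, transcript, hierarchy):
        cases = generate_variants(
            transcript, 12, 1000, kinds=["deletion", "insertion", "delins"]
        )
        for c in cases:
            ann = classify_full(c.variant, transcript, hierarchy=hierarchy)
            names = set(ann.names())
            in_frame = net_length_change(c.variant) % 3 == 0
            frame_terms = {n for n in names if "frame" in n}
            assert len(frame_terms) == 1
            assert ("out-of-frame" not in frame_terms.pop()) == in_frame

    def test_oracle_equivalence_on_seeded_substitutions(self, transcript, hierarchy):
        cases = generate_variants(transcript, 11, 1000, kinds=["substitution"])
        for c in cases:
            eff = classify_coding_effect(c.variant, transcript)
            assert eff.effect_label == c.oracle_label, c.variant.raw
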