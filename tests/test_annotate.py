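"""Coding effects, CpG status, trinucleotide contexts, and spectra."""

import pytest

from earlygc.annotate import (
    AnnotationError,
    GeneIndex,
    ReferenceGenome,
    annotate_cohort,
    annotate_variant,
    classify_coding_effect,
    export_4col,
    spectrum_summary,
    trinucleotide_context,
)
from earlygc.io import read_4col

from conftest import FORWARD_SEQ, make_call


def snv(chrom, pos0, ref_base, alt_base):
    return make_call(chrom=chrom, pos=pos0 + 1, ref=ref_base, alt=alt_base)


class TestCodingEffect:
    def test_synonymous_at_fourfold_site(self, toy_pair):
        ref, fwd, _ = toy_pair
        index = GeneIndex([fwd], ref)
        # GGG -> GGA, third codon position (Gly four-fold site)
        effect, genes = classify_coding_effect(snv("chrF", 10, "G", "A"), index)
        assert effect == "synonymous" and genes == ("FWD",)

    def test_nonsynonymous_start_codon(self, toy_pair):
        ref, fwd, _ = toy_pair
        index = GeneIndex([fwd], ref)
        effect, _ = classify_coding_effect(snv("chrF", 5, "A", "G"), index)
        assert effect == "nonsynonymous"  # ATG -> GTG, Met -> Val

    def test_stop_loss_is_nonsynonymous(self, toy_pair):
        ref, fwd, _ = toy_pair
        index = GeneIndex([fwd], ref)
        # TAA -> CAA (stop -> Gln)
        effect, _ = classify_coding_effect(snv("chrF", 14, "T", "C"), index)
        assert effect == "nonsynonymous"

    def test_outside_cds_is_noncoding(self, toy_pair):
        ref, fwd, _ = toy_pair
        index = GeneIndex([fwd], ref)
        effect, genes = classify_coding_effect(snv("chrF", 2, "T", "A"), index)
        assert effect == "noncoding" and genes == ()

    def test_indel_overlapping_cds(self, toy_pair):
        ref, fwd, _ = toy_pair
        index = GeneIndex([fwd], ref)
        call = make_call(chrom="chrF", pos=9, ref=FORWARD_SEQ[8:11],
                         alt=FORWARD_SEQ[8], var_class="deletion")
        effect, genes = classify_coding_effect(call, index)
        assert effect == "coding_indel" and genes == ("FWD",)

    def test_reference_mismatch_names_position(self, toy_pair):
        ref, fwd, _ = toy_pair
        index = GeneIndex([fwd], ref)
        with pytest.raises(AnnotationError, match="chrF:11"):
            classify_coding_effect(snv("chrF", 10, "C", "A"), index)

    def test_strand_consistency(self, toy_pair):
        """Mirrored genes on reverse-complement chromosomes agree on every
        coding position's effect."""
        ref, fwd, rev = toy_pair
        index = GeneIndex([fwd, rev], ref)
        length = len(FORWARD_SEQ)
        complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for pos0 in range(5, 17):
            base = FORWARD_SEQ[pos0]
            for alt in "ACGT":
                if alt == base:
                    continue
                eff_f, _ = classify_coding_effect(snv("chrF", pos0, base, alt), index)
                mirror = length - 1 - pos0
                eff_r, _ = classify_coding_effect(
                    snv("chrR", mirror, complement[base], complement[alt]), index
                )
                assert eff_f == eff_r


class TestCpG:
    @pytest.mark.parametrize(
        "seq, pos0, expected",
        [
            ("ACGT", 1, True),   # the C of CpG
            ("ACGT", 2, True),   # the G of CpG
            ("ACAT", 1, False),
            ("ACGT", 0, False),  # A site: False by definition
            ("CGNN", 0, True),
            ("ANGT", 2, False),  # N context never forms a CpG
        ],
    )
    def test_definitional(self, seq, pos0, expected):
        ref = ReferenceGenome({"c": seq})
        assert ref.is_cpg("c", pos0) is expected


class TestContext96:
    @pytest.mark.parametrize(
        "seq, pos0, ref_base, alt_base, expected",
        [
            ("ATCGA", 2, "C", "T", "T[C>T]G"),
            ("ACGAT", 2, "G", "A", "T[C>T]G"),  # purine centre reverse-complemented
            ("AACAG", 2, "C", "G", "A[C>G]A"),
        ],
    )
    def test_labels(self, seq, pos0, ref_base, alt_base, expected):
        ref = ReferenceGenome({"c": seq})
        assert trinucleotide_context(ref, snv("c", pos0, ref_base, alt_base)) == expected

    def test_edge_position_has_no_context(self):
        ref = ReferenceGenome({"c": "CGT"})
        assert trinucleotide_context(ref, snv("c", 0, "C", "T")) is None


class TestSpectrum:
    def test_counts_and_modal(self, toy_pair):
        ref, fwd, _ = toy_pair
        index = GeneIndex([fwd], ref)
        calls = [snv("chrF", 1, "T", "C")] * 1  # T>C == A>G class
        variants = [annotate_variant(c, index) for c in calls]
        variants += [
            annotate_variant(snv("chrF", 11, "C", "T"), index) for _ in range(3)
        ]
        summary = spectrum_summary(variants)
        assert summary.modal_class == "C>T" and summary.modal_count == 3
        assert summary.counts6["T>C"] == 1
        assert summary.n_snvs == 4

    def test_empty_input(self):
        summary = spectrum_summary([])
        assert summary.modal_class is None
        assert all(v == 0 for v in summary.counts6.values())

    def test_96_collapses_to_6(self, small_reference, small_cohort):
        ref, genes = small_reference
        variants = annotate_cohort(small_cohort.all_calls(), genes, ref)
        summary = spectrum_summary(variants)
        collapsed = {}
        for context, count in summary.counts96.items():
            sub = context[2:5]  # 'X[R>A]Y' -> 'R>A'
            collapsed[sub] = collapsed.get(sub, 0) + count
        expected = {}
        n_with_context = 0
        for v in variants:
            if v.call.var_class == "SNV" and v.context96 is not None:
                expected[v.subclass6] = expected.get(v.subclass6, 0) + 1
                n_with_context += 1
        assert collapsed == expected
        assert sum(summary.counts96.values()) == n_with_context
        assert n_with_context > 0


class TestExport:
    def test_round_trip(self, toy_pair, tmp_path):
        ref, fwd, _ = toy_pair
        index = GeneIndex([fwd], ref)
        variants = [annotate_variant(snv("chrF", 10, "G", "A"), index),
                    annotate_variant(snv("chrF", 2, "T", "A"), index)]
        path = tmp_path / "out.tsv"
        export_4col(variants, path)
        df = read_4col(path)
        assert [tuple(r) for r in df.itertuples(index=False)] == [
            ("chrF", 11, "G", "A"), ("chrF", 3, "T", "A"),
        ]

    def test_empty_is_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        export_4col([], path)
        assert path.read_text() == "CHROM\tPOS\tREF\tALT\n"


def test_annotation_is_pure(small_reference, small_cohort):
    ref, genes = small_reference
    calls = small_cohort.all_calls()
    first = annotate_cohort(calls, genes, ref)
    second = annotate_cohort(calls[::-1], genes, ref)
    assert sorted(first, key=lambda v: (v.call.sample_id, v.call.chrom, v.call.pos)) == \
        sorted(second, key=lambda v: (v.call.sample_id, v.call.chrom, v.call.pos))
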