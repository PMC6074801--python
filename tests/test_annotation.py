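"""Region assignment, strand-aware coding effects and database
membership on toy transcript models."""

from __future__ import annotations

import pytest

from somaticbench.annotate import (
    TranscriptIndex,
    TranscriptModel,
    annotate_coding_effect,
    annotate_membership,
    annotate_region,
    read_transcript_models,
    write_gff3,
)
from somaticbench.model import Effect, Membership, Region, VariantKey

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@pytest.fixture()
def two_gene_locus():
    """Two plus-strand genes on chr5 with introns, UTRs and a gap."""
    seq = list("A" * 500)
    seq[149:152] = "ATG"  # GENEA start codon at 150
    seq[450:453] = "ATG"  # GENEB start codon at 451
    sequence = "".join(seq)
    gene_a = TranscriptModel(
        gene="GENEA", contig="chr5", strand="+",
        exons=[(100, 200), (300, 400)],
        cds=[(150, 200), (300, 350)],
        sequence=sequence,
    )
    gene_b = TranscriptModel(
        gene="GENEB", contig="chr5", strand="+",
        exons=[(450, 480)], cds=[(451, 477)],
        sequence=sequence,
    )
    return [gene_a, gene_b]


class TestRegionAssignment:
    @pytest.mark.parametrize(
        "position, expected_region, expected_gene",
        [
            (160, Region.EXONIC, "GENEA"),      # inside CDS
            (120, Region.UTR, "GENEA"),         # exon outside CDS
            (202, Region.SPLICING, "GENEA"),    # 2 bases into the intron
            (250, Region.INTRONIC, "GENEA"),    # deep intron
        ],
    )
    def test_precedence_within_gene(self, two_gene_locus, position, expected_region,
                                    expected_gene):
        key = VariantKey.make("chr5", position, "A", "G")
        assignment = annotate_region(key, two_gene_locus)
        assert assignment.region is expected_region
        assert assignment.gene == expected_gene

    def test_intergenic_reports_both_flanking_genes(self, two_gene_locus):
        key = VariantKey.make("chr5", 430, "A", "G")
        assignment = annotate_region(key, two_gene_locus)
        assert assignment.region is Region.INTERGENIC
        assert assignment.flanking_genes == ("GENEA", "GENEB")

    def test_upstream_intergenic_has_one_flank(self, two_gene_locus):
        assignment = annotate_region(VariantKey.make("chr5", 50, "A", "G"), two_gene_locus)
        assert assignment.region is Region.INTERGENIC
        assert assignment.flanking_genes == (None, "GENEA")

    def test_contig_without_models_is_intergenic_empty_flanks(self, two_gene_locus):
        assignment = annotate_region(VariantKey.make("chr9", 50, "A", "G"), two_gene_locus)
        assert assignment.region is Region.INTERGENIC
        assert assignment.flanking_genes == (None, None)

    def test_splice_window_is_configurable(self, two_gene_locus):
        key = VariantKey.make("chr5", 204, "A", "G")  # 4 bases into the intron
        assert annotate_region(key, two_gene_locus, splice_window=2).region is Region.INTRONIC
        assert annotate_region(key, two_gene_locus, splice_window=5).region is Region.SPLICING

    def test_every_position_gets_a_label(self, two_gene_locus):
        index = TranscriptIndex(two_gene_locus)
        for position in range(1, 500, 7):
            assignment = index.region_of(VariantKey.make("chr5", position, "A", "C"))
            assert assignment.region in Region


class TestCodingEffect:
    """Manual codon-translation oracle on the M-A-K-stop micro gene."""

    def test_nonsynonymous_snv(self, toy_gene):
        annotation = annotate_coding_effect(VariantKey.make("chr1", 8, "G", "T"), toy_gene)
        assert annotation.effect is Effect.NONSYNONYMOUS_SNV
        assert annotation.aa_change == "A2S"  # GCA -> TCA

    def test_synonymous_snv(self, toy_gene):
        annotation = annotate_coding_effect(VariantKey.make("chr1", 10, "A", "G"), toy_gene)
        assert annotation.effect is Effect.SYNONYMOUS_SNV
        assert annotation.aa_change == "A2A"  # GCA -> GCG

    def test_stopgain_written_as_x(self, toy_gene):
        annotation = annotate_coding_effect(VariantKey.make("chr1", 11, "A", "T"), toy_gene)
        assert annotation.effect is Effect.STOPGAIN
        assert annotation.aa_change == "K3X"  # AAA -> TAA

    def test_stoploss(self, toy_gene):
        annotation = annotate_coding_effect(VariantKey.make("chr1", 14, "T", "C"), toy_gene)
        assert annotation.effect is Effect.STOPLOSS
        assert annotation.aa_change == "X4Q"  # TAA -> CAA

    def test_one_base_insertion_is_frameshift(self, toy_gene):
        annotation = annotate_coding_effect(VariantKey.make("chr1", 8, "G", "GT"), toy_gene)
        assert annotation.effect is Effect.FRAMESHIFT_INDEL
        assert annotation.aa_change == "A2fs"

    def test_three_base_deletion_is_in_frame(self, toy_gene):
        annotation = annotate_coding_effect(
            VariantKey.make("chr1", 10, "AAAA", "A"), toy_gene
        )
        assert annotation.effect is Effect.NONFRAMESHIFT_INDEL
        assert annotation.aa_change == "K3del"

    def test_key_outside_cds_rejected(self, toy_gene):
        with pytest.raises(ValueError):
            annotate_coding_effect(VariantKey.make("chr1", 2, "T", "A"), toy_gene)

    def test_reference_mismatch_detected(self, toy_gene):
        with pytest.raises(ValueError, match="mismatch"):
            annotate_coding_effect(VariantKey.make("chr1", 8, "C", "T"), toy_gene)

    @pytest.mark.parametrize(
        "position, ref, alt",
        [(8, "G", "T"), (10, "A", "G"), (11, "A", "T"), (14, "T", "C")],
    )
    def test_strand_consistency(self, toy_gene, position, ref, alt):
        """A minus-strand model of the reverse-complemented locus yields
        identical effects for the mirrored, complemented variant."""
        length = len(toy_gene.sequence)
        minus = TranscriptModel(
            gene=toy_gene.gene, contig="chr2", strand="-",
            exons=[(length - e + 1, length - s + 1) for s, e in toy_gene.exons],
            cds=[(length - e + 1, length - s + 1) for s, e in toy_gene.cds],
            sequence=revcomp(toy_gene.sequence),
        )
        plus_annotation = annotate_coding_effect(
            VariantKey.make("chr1", position, ref, alt), toy_gene
        )
        minus_annotation = annotate_coding_effect(
            VariantKey.make("chr2", length - position + 1,
                            ref.translate(_COMP), alt.translate(_COMP)),
            minus,
        )
        assert minus_annotation.effect is plus_annotation.effect
        assert minus_annotation.aa_change == plus_annotation.aa_change

    def test_effect_partition_is_exclusive(self, toy_gene):
        """Every CDS-overlapping variant gets exactly one effect label."""
        for position in range(5, 17):
            ref = toy_gene.sequence[position - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                annotation = annotate_coding_effect(
                    VariantKey.make("chr1", position, ref, alt), toy_gene
                )
                assert annotation.effect in Effect


class TestModelValidation:
    def test_cds_must_start_with_start_codon(self):
        with pytest.raises(ValueError, match="start codon"):
            TranscriptModel(gene="BAD", contig="chr1", strand="+",
                            exons=[(1, 12)], cds=[(1, 12)],
                            sequence="CCCGCAAAATAA")

    def test_cds_length_multiple_of_three(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            TranscriptModel(gene="BAD", contig="chr1", strand="+",
                            exons=[(1, 11)], cds=[(1, 11)],
                            sequence="ATGGCAAAATA")

    def test_cds_outside_exons_rejected(self):
        with pytest.raises(ValueError, match="not inside an exon"):
            TranscriptModel(gene="BAD", contig="chr1", strand="+",
                            exons=[(1, 10)], cds=[(5, 16)],
                            sequence="ATGGCAAAATAATTTT")


class TestMembership:
    def test_four_way(self):
        key = VariantKey.make("chr1", 10, "A", "G")
        other = VariantKey.make("chr1", 20, "A", "G")
        assert annotate_membership(key, {key}, set()) is Membership.COSMIC_ONLY
        assert annotate_membership(key, set(), {key}) is Membership.DBSNP_ONLY
        assert annotate_membership(key, {key}, {key}) is Membership.BOTH
        assert annotate_membership(key, {other}, {other}) is Membership.NEITHER


class TestGff3RoundTrip:
    def test_models_survive_gff3_fasta_round_trip(self, tmp_path, two_gene_locus):
        gff3 = tmp_path / "models.gff3"
        fasta = tmp_path / "genome.fa"
        write_gff3(two_gene_locus, gff3)
        fasta.write_text(">chr5\n" + two_gene_locus[0].sequence + "\n")
        restored = read_transcript_models(gff3, fasta)
        assert sorted(m.gene for m in restored) == ["GENEA", "GENEB"]
        by_gene = {m.gene: m for m in restored}
        for original in two_gene_locus:
            model = by_gene[original.gene]
            assert model.exons == original.exons
            assert model.cds == original.cds
            assert model.strand == original.strand
        key = VariantKey.make("chr5", 151, "T", "A")
        with pytest.raises(ValueError, match="mismatch"):
            # base at 151 is the T of ATG; a wrong ref must still be caught
            annotate_coding_effect(VariantKey.make("chr5", 151, "A", "C"), by_gene["GENEA"])
        annotation = annotate_coding_effect(key, by_gene["GENEA"])
        assert annotation.gene == "GENEA"
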