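"""Domain types and VCF/TSV I/O: key normalization, record splitting,
allele-fraction recomputation and round-trip stability."""

from __future__ import annotations

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somaticbench.datasets import gbm_driver_candidates
from somaticbench.model import (
    Platform,
    Thresholds,
    VariantCall,
    VariantKey,
    VcfParseError,
    read_annotated_tsv,
    read_calls,
    write_calls,
    write_vcf,
)

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1>
##contig=<ID=chr7>
##INFO=<ID=TLOD,Number=A,Type=Float,Description="Tumor LOD">
##INFO=<ID=NLOD,Number=A,Type=Float,Description="Normal LOD">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele fraction">
##FILTER=<ID=t_lod_fstar,Description="low TLOD">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def _write_vcf(tmp_path, body: str, name: str = "toy.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


class TestVariantKey:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            (("chr1", 100, "AT", "AC"), ("chr1", 101, "T", "C")),
            (("7", 100, "G", "T"), ("chr7", 100, "G", "T")),
            (("chr2", 50, "GCC", "GC"), ("chr2", 51, "CC", "C")),
            (("chr2", 51, "CC", "C"), ("chr2", 51, "CC", "C")),
            (("chr3", 10, "G", "GA"), ("chr3", 10, "G", "GA")),
        ],
    )
    def test_normalization(self, raw, expected):
        key = VariantKey.make(*raw)
        assert (key.contig, key.position, key.ref_allele, key.alt_allele) == expected

    def test_alternative_indel_spellings_unify(self):
        # every left-shifted spelling of deleting one C from the GCC run
        assert VariantKey.make("chr2", 50, "GCC", "GC") == VariantKey.make(
            "chr2", 51, "CC", "C"
        )

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            VariantKey.make("chr1", 5, "A", "A")

    @given(
        contig=st.sampled_from(["chr1", "1", "chrX"]),
        position=st.integers(min_value=10, max_value=10_000),
        ref=st.text(alphabet="ACGT", min_size=1, max_size=6),
        alt=st.text(alphabet="ACGT", min_size=1, max_size=6),
    )
    @settings(max_examples=200, deadline=None)
    def test_normalization_is_idempotent(self, contig, position, ref, alt):
        if ref == alt:
            return
        key = VariantKey.make(contig, position, ref, alt)
        again = VariantKey.make(key.contig, key.position, key.ref_allele, key.alt_allele)
        assert again == key

    def test_total_order(self):
        keys = [
            VariantKey.make("chr2", 5, "A", "T"),
            VariantKey.make("chr1", 9, "A", "T"),
            VariantKey.make("chr1", 5, "A", "T"),
        ]
        assert sorted(keys)[0].contig == "chr1"
        assert sorted(keys)[0].position == 5


class TestVariantCall:
    def test_af_recomputed_from_read_counts(self):
        call = VariantCall(
            sample_id="S", platform=Platform.RNA, contig="chr7", position=100,
            ref_allele="T", alt_allele="G", alt_reads=22, depth=4792,
        )
        assert call.allele_fraction == pytest.approx(22 / 4792)
        assert call.allele_fraction == pytest.approx(0.00459, abs=1e-5)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            VariantCall("S", Platform.RNA, "chr1", 10, "A", "G", alt_reads=5, depth=3)
        with pytest.raises(ValueError):
            VariantCall("S", Platform.RNA, "chr1", 0, "A", "G", alt_reads=1, depth=3)
        with pytest.raises(ValueError):
            VariantCall("S", Platform.RNA, "chr1", 10, "A", "G",
                        alt_reads=1, depth=4, allele_fraction=0.9)


class TestReadCalls:
    def test_biallelic_records_one_call_each(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tG\t.\tPASS\tTLOD=10;NLOD=5\tGT:AD:DP\t0/1:10,5:15\n"
            "chr1\t200\t.\tC\tT\t.\tPASS\tTLOD=8\tGT:AD:DP\t0/1:8,2:10\n"
            "chr7\t300\t.\tG\tGA\t.\tt_lod_fstar\tTLOD=3\tGT:AD:DP\t0/1:9,1:10\n"
        )
        result = read_calls(_write_vcf(tmp_path, body), "S1", Platform.RNA)
        assert len(result) == 3
        assert result[0].tlod == pytest.approx(10.0)
        assert result[0].nlod == pytest.approx(5.0)
        assert result[1].nlod is None
        assert result[2].filter_labels == {"t_lod_fstar"}
        assert result[0].allele_fraction == pytest.approx(5 / 15)

    def test_multiallelic_split_shares_position(self, tmp_path):
        body = "chr1\t100\t.\tG\tA,T\t.\tPASS\tTLOD=9,4\tGT:AD:DP\t0/1:10,6,4:20\n"
        result = read_calls(_write_vcf(tmp_path, body), "S1", Platform.WES)
        assert len(result) == 2
        assert {c.alt_allele for c in result} == {"A", "T"}
        assert all(c.position == 100 for c in result)
        assert {c.alt_reads for c in result} == {6, 4}
        assert sorted(c.tlod for c in result) == pytest.approx([4.0, 9.0])

    def test_symbolic_alleles_skipped_and_counted(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\t<DEL>\t.\tPASS\tTLOD=9\tGT:AD:DP\t0/1:5,5:10\n"
            "chr1\t200\t.\tC\tT\t.\tPASS\tTLOD=9\tGT:AD:DP\t0/1:5,5:10\n"
        )
        result = read_calls(_write_vcf(tmp_path, body), "S1", Platform.RNA)
        assert len(result) == 1
        assert result.n_symbolic_skipped == 1

    def test_malformed_record_names_position(self, tmp_path):
        body = "chr1\tnot_a_position\t.\tA\tG\t.\tPASS\tTLOD=9\tGT:AD:DP\t0/1:5,5:10\n"
        with pytest.raises(VcfParseError, match="record"):
            list(read_calls(_write_vcf(tmp_path, body), "S1", Platform.RNA))

    def test_vcf_round_trip(self, tmp_path):
        calls = [
            VariantCall("S1", Platform.RNA, "chr1", 100, "A", "G",
                        alt_reads=5, depth=50, tlod=12.5, nlod=7.25,
                        filter_labels={"PASS"}),
            VariantCall("S1", Platform.RNA, "chr1", 200, "CT", "C",
                        alt_reads=3, depth=30, tlod=8.0, nlod=None,
                        filter_labels={"germline_risk", "alt_allele_in_normal"}),
        ]
        path = tmp_path / "out.vcf"
        write_vcf(calls, path, sample_id="S1")
        back = read_calls(path, "S1", Platform.RNA)
        assert len(back) == 2
        assert [c.key for c in back] == [c.key for c in calls]
        assert back[0].tlod == pytest.approx(12.5, abs=1e-3)
        assert back[1].nlod is None
        assert back[1].filter_labels == {"germline_risk", "alt_allele_in_normal"}
        assert back[0].alt_reads == 5 and back[0].depth == 50


class TestAnnotatedTsvRoundTrip:
    def test_empty_sequence_gives_header_only_file(self):
        sink = io.StringIO()
        write_calls([], sink)
        text = sink.getvalue()
        assert text.count("\n") == 1
        assert "sample_id" in text

    def test_candidate_records_round_trip(self, tmp_path):
        records = gbm_driver_candidates()
        path = tmp_path / "records.tsv"
        write_calls(records, path)
        back = read_annotated_tsv(path)
        assert len(back) == len(records)
        for original, restored in zip(records, back):
            assert restored.key == original.key
            assert restored.gene == original.gene
            assert restored.effect == original.effect
            assert restored.aa_change == original.aa_change
            assert restored.in_cosmic == original.in_cosmic
            assert restored.in_dbsnp == original.in_dbsnp
            assert restored.comparison_class == original.comparison_class
            assert restored.scores.is_indel == original.scores.is_indel
            assert restored.scores.sift_pred == original.scores.sift_pred

    def test_absent_nlod_round_trips_as_none(self, tmp_path):
        call = VariantCall("S", Platform.WES, "chr1", 10, "A", "G",
                           alt_reads=4, depth=10, tlod=9.0, nlod=None)
        path = tmp_path / "one.tsv"
        write_calls([call], path)
        assert read_annotated_tsv(path)[0].call.nlod is None


def test_thresholds_defaults_and_validation():
    t = Thresholds()
    assert (t.tlod_pass, t.nlod_somatic, t.nlod_dbsnp) == (6.3, 2.2, 5.5)
    assert (t.sift_cutoff, t.fathmm_cutoff) == (0.05, -0.75)
    with pytest.raises(ValueError):
        Thresholds(pon_min_samples=0)
    with pytest.raises(ValueError):
        Thresholds(tlod_pass=float("nan"))
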