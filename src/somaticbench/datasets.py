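"""Bundled reference data: the curated GBM gene set and two small
benchmark tables of published glioblastoma mutation records.

The 29-gene set collects the genes most frequently mutated in GBM
pathways (RTK/RAS/PI3K, p53 and RB signalling).  Note that ``ARF`` and
``P16`` are kept verbatim as curated even though both are aliases of
CDKN2A gene products (p14ARF / p16INK4a); user-supplied gene symbols must
match these spellings to hit the set.

The two record tables reconstruct published candidate lists from their
printed columns (sample, comparison class, amino-acid change, SIFT and
cancer-weighted FATHMM scores, allele fraction and coverage, with the
database membership stated for each table).  Genomic coordinates and
alleles are placeholders — every selection criterion downstream operates
on gene, effect, membership, scores and read counts, none of which depend
on the placeholder coordinates.  One gene symbol is printed truncated as
"PIK3C2" in the source table; it is recorded here as PIK3C2B so the row
carries a symbol from the gene set.

``*_decoys`` builders produce records that each violate exactly one
criterion of the corresponding filter, for specificity testing.
"""

from __future__ import annotations

from typing import List

from .model import (
    AnnotatedVariant,
    ComparisonClass,
    Effect,
    Platform,
    Region,
    ScorePair,
    VariantCall,
)
from .scores import GeneSet

__all__ = [
    "GBM_GENE_SYMBOLS",
    "gbm_gene_set",
    "gbm_driver_candidates",
    "gbm_novel_candidates",
    "driver_decoys",
    "novel_decoys",
]

GBM_GENE_SYMBOLS = (
    "ARF", "BRCA2", "CBL", "CDK4", "CDKN2B", "CDKN2C", "EGFR", "EP300",
    "ERBB2", "ERBB3", "FGFR2", "IRS1", "MDM2", "MDM4", "MET", "MSH6",
    "NF1", "P16", "PDGFRB", "PIK3C2B", "PIK3C2G", "PIK3CA", "PIK3R1",
    "PRKCZ", "PTEN", "RB1", "SPRY2", "TP53", "TSC2",
)


def gbm_gene_set() -> GeneSet:
    """The packaged 29-gene GBM pathway set."""
    return GeneSet(name="gbm-29", genes=frozenset(GBM_GENE_SYMBOLS))


_CLASS_PLATFORM = {
    ComparisonClass.RNA_ONLY: Platform.RNA,
    ComparisonClass.INTERSECTION: Platform.RNA,
    ComparisonClass.WES_ONLY: Platform.WES,
}


def _record(
    index: int,
    gene: str,
    sample: str,
    cls: ComparisonClass,
    aa_change: str,
    af: float,
    coverage: int,
    scores: ScorePair,
    in_cosmic: bool,
    in_dbsnp: bool,
    alt_reads: int | None = None,
) -> AnnotatedVariant:
    is_indel = scores.is_indel
    if alt_reads is None:
        alt_reads = max(1, round(af * coverage))
    call = VariantCall(
        sample_id=sample,
        platform=_CLASS_PLATFORM[cls],
        contig="chr1",
        position=10_000 + 100 * index,
        ref_allele="A" if not is_indel else "A",
        alt_allele="G" if not is_indel else "AG",
        alt_reads=alt_reads,
        depth=coverage,
        tlod=20.0,
        nlod=8.0,
        filter_labels={"PASS"},
    )
    effect = Effect.FRAMESHIFT_INDEL if aa_change.endswith("fs") else Effect.NONSYNONYMOUS_SNV
    return AnnotatedVariant(
        call=call,
        gene=gene,
        region=Region.EXONIC,
        effect=effect,
        aa_change=aa_change,
        in_cosmic=in_cosmic,
        in_dbsnp=in_dbsnp,
        scores=scores,
        comparison_class=cls,
    )


def _snv_scores(fathmm: float, sift: float) -> ScorePair:
    return ScorePair(
        is_indel=False,
        sift_score=sift,
        sift_pred="Deleterious" if sift < 0.05 else "Tolerated",
        fathmm_score=fathmm,
        fathmm_pred="CANCER" if fathmm < -0.75 else "PASSENGER",
    )


def _indel_scores(fathmm_conf: float, fathmm_pred: str, sift_conf: float, sift_pred: str) -> ScorePair:
    return ScorePair(
        is_indel=True,
        sift_score=sift_conf,
        sift_pred=sift_pred,
        fathmm_pred=fathmm_pred,
        fathmm_confidence=fathmm_conf,
    )


_R = ComparisonClass.RNA_ONLY
_I = ComparisonClass.INTERSECTION
_W = ComparisonClass.WES_ONLY


def gbm_driver_candidates() -> List[AnnotatedVariant]:
    """Eleven published best-GBM-related mutations (COSMIC-only records).

    Three were found by RNA-seq only, six by both platforms and two by
    WES only.  All satisfy the conjunctive driver criterion.
    """
    rows = [
        ("EGFR", "SD01", _R, "A702S", -0.97, 0.01, 0.015, 852),
        ("EGFR", "SD01", _I, "A289V", -1.04, 0.002, 0.072, 125),
        ("EGFR", "GBM01", _I, "G63R", -1.93, 0.0, 0.175, 296),
        ("TP53", "GBM01", _I, "G105R", -10.02, 0.0, 0.44, 50),
        ("TP53", "GBM02", _R, "I254S", -9.48, 0.0, 0.949, 390),
        ("PTEN", "GBM02", _I, "D107Y", -3.06, 0.0, 0.69, 92),
        ("PTEN", "GBM03", _I, "R173H", -6.42, 0.0, 0.331, 173),
        ("PTEN", "GBM07", _W, "R130Q", -5.84, 0.0, 0.713, 190),
        ("NF1", "GBM10", _W, "C622F", -0.83, 0.01, 0.403, 389),
    ]
    records = [
        _record(i, gene, sample, cls, aa, af, cov, _snv_scores(fathmm, sift), True, False)
        for i, (gene, sample, cls, aa, fathmm, sift, af, cov) in enumerate(rows)
    ]
    records.append(
        _record(
            9, "TSC2", "GBM02", _R, "V296fs", 0.137, 55,
            _indel_scores(71.0, "pathogenic", 85.8, "Damaging"), True, False,
        )
    )
    records.append(
        _record(
            10, "PTEN", "GBM04", _I, "D326fs", 0.393, 146,
            _indel_scores(88.0, "pathogenic", 85.8, "Damaging"), True, False,
        )
    )
    return records


def gbm_novel_candidates() -> List[AnnotatedVariant]:
    """Nine published candidate novel mutations (unknown to COSMIC and
    dbSNP).  Eight were found by RNA-seq only and one by WES only; several
    are retained by only one of the two scores (the filter is
    disjunctive)."""
    records = [
        _record(20, "EGFR", "SD01", _R, "S229fs", 0.045, 169,
                _indel_scores(93.0, "pathogenic", 85.8, "Damaging"), False, False),
        _record(21, "EGFR", "SD01", _R, "W477fs", 0.046, 447,
                _indel_scores(51.0, "neutral", 85.8, "Damaging"), False, False),
        _record(22, "PIK3C2B", "SD01", _W, "I255N", 0.433, 64,
                _snv_scores(-3.49, 0.0), False, False),
        _record(23, "CDKN2C", "GBM02", _R, "V130A", 0.027, 470,
                _snv_scores(-0.21, 0.03), False, False),
        _record(24, "PDGFRB", "GBM02", _R, "V840A", 0.021, 262,
                _snv_scores(-2.34, 0.23), False, False),
        _record(25, "RB1", "GBM03", _R, "L872fs", 0.035, 355,
                _indel_scores(77.0, "pathogenic", 85.8, "Damaging"), False, False),
        _record(26, "EGFR", "GBM05", _R, "M600T", 8.1e-3, 6240,
                _snv_scores(-1.69, 0.38), False, False),
        _record(27, "EGFR", "GBM05", _R, "L718R", 4.5e-3, 4792,
                _snv_scores(-2.85, 0.0), False, False, alt_reads=22),
        _record(28, "PDGFRB", "GBM06", _R, "Q1075R", 0.058, 90,
                _snv_scores(-1.25, 0.52), False, False),
    ]
    return records


def driver_decoys() -> List[AnnotatedVariant]:
    """Decoys for the driver criterion, each violating exactly one of its
    clauses (gene set, COSMIC-only membership, protein-altering effect,
    SIFT retention, FATHMM retention)."""
    decoys = []
    d = _record(41, "GAPDH", "DECOY", _I, "A100V", 0.2, 200, _snv_scores(-2.0, 0.01), True, False)
    decoys.append(d)  # gene outside the set
    d = _record(42, "EGFR", "DECOY", _I, "A100V", 0.2, 200, _snv_scores(-2.0, 0.01), True, True)
    decoys.append(d)  # also in dbSNP -> membership both
    d = _record(43, "EGFR", "DECOY", _I, "A100V", 0.2, 200, _snv_scores(-2.0, 0.01), False, False)
    decoys.append(d)  # absent from COSMIC -> membership neither
    d = _record(44, "EGFR", "DECOY", _I, "A100A", 0.2, 200, _snv_scores(-2.0, 0.01), True, False)
    d.effect = Effect.SYNONYMOUS_SNV
    decoys.append(d)  # synonymous -> not protein-altering
    d = _record(45, "EGFR", "DECOY", _I, "A100V", 0.2, 200, _snv_scores(-2.0, 0.23), True, False)
    decoys.append(d)  # SIFT tolerated
    d = _record(46, "EGFR", "DECOY", _I, "A100V", 0.2, 200, _snv_scores(-0.21, 0.01), True, False)
    decoys.append(d)  # FATHMM passenger
    return decoys


def novel_decoys() -> List[AnnotatedVariant]:
    """Decoys for the novel-candidate criterion, each violating exactly
    one clause (gene set, unknown-to-databases, effect, score
    disjunction, minimum altered reads)."""
    decoys = []
    d = _record(60, "GAPDH", "DECOY", _R, "A100V", 0.2, 200, _snv_scores(-2.0, 0.01), False, False)
    decoys.append(d)  # gene outside the set
    d = _record(61, "EGFR", "DECOY", _R, "A100V", 0.2, 200, _snv_scores(-2.0, 0.01), True, False)
    decoys.append(d)  # known to COSMIC (belongs to the driver criterion)
    d = _record(62, "EGFR", "DECOY", _R, "A100A", 0.2, 200, _snv_scores(-2.0, 0.01), False, False)
    d.effect = Effect.SYNONYMOUS_SNV
    decoys.append(d)  # synonymous
    d = _record(63, "EGFR", "DECOY", _R, "A100V", 0.2, 200, _snv_scores(-0.21, 0.4), False, False)
    decoys.append(d)  # neither score retains
    d = _record(64, "EGFR", "DECOY", _R, "A100V", 0.005, 200, _snv_scores(-2.0, 0.01), False, False)
    d.call.alt_reads = 1
    d.call.allele_fraction = 1 / 200
    decoys.append(d)  # single supporting read
    return decoys
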