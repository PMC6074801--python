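"""Variant annotation against toy transcript models.

Provides the annotation layer a RefSeq-style annotator would supply on
real data: genomic region (exonic / splicing / UTR / intronic /
intergenic, with the two flanking genes for intergenic variants), coding
effect with amino-acid change notation (``A702S``, ``V296fs``), and
COSMIC/dbSNP membership classification.

A :class:`TranscriptModel` is a minimal gene model — exon and CDS
intervals plus the genomic sequence of its locus — sufficient for
strand-aware codon translation on synthetic genes.  Coordinates are
1-based and intervals closed, matching VCF convention.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .model import Effect, Membership, Region, VariantKey, membership_class

__all__ = [
    "TranscriptModel",
    "EffectAnnotation",
    "RegionAssignment",
    "TranscriptIndex",
    "annotate_region",
    "annotate_coding_effect",
    "annotate_membership",
    "write_gff3",
    "read_transcript_models",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """Exon/CDS structure and sequence of one toy transcript.

    ``sequence`` holds the genomic bases of the locus starting at
    1-based coordinate ``offset`` (typically the whole toy contig with
    ``offset=1``).  Intervals are 1-based closed, sorted, non-overlapping;
    CDS intervals lie within exons, their concatenated length is a
    multiple of 3 and translation starts with a start codon on the coding
    strand.
    """

    gene: str
    contig: str
    strand: str
    exons: List[Tuple[int, int]]
    cds: List[Tuple[int, int]]
    sequence: str
    offset: int = 1
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        if self.transcript_id is None:
            self.transcript_id = f"{self.gene}.t1"
        self.validate()

    def validate(self) -> None:
        for intervals, name in ((self.exons, "exons"), (self.cds, "cds")):
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                if s2 <= e1:
                    raise ValueError(f"{name} of {self.gene} overlap or are unsorted")
            for s, e in intervals:
                if s > e:
                    raise ValueError(f"{name} interval ({s}, {e}) of {self.gene} is empty")
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ValueError(f"CDS ({cs}, {ce}) of {self.gene} not inside an exon")
        if self.cds_length % 3 != 0:
            raise ValueError(f"CDS length of {self.gene} not a multiple of 3")
        if self.cds and not self.cds_sequence().upper().startswith("ATG"):
            raise ValueError(f"CDS of {self.gene} does not begin with a start codon")

    # -- coordinates -----------------------------------------------------

    @property
    def span(self) -> Tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def base_at(self, position: int) -> str:
        idx = position - self.offset
        if not 0 <= idx < len(self.sequence):
            raise ValueError(f"position {position} outside the sequence of {self.gene}")
        return self.sequence[idx].upper()

    def slice(self, start: int, end: int) -> str:
        return self.sequence[start - self.offset : end - self.offset + 1].upper()

    def cds_sequence(self) -> str:
        cached = getattr(self, "_cds_seq", None)
        if cached is None:
            seq = "".join(self.slice(s, e) for s, e in self.cds)
            cached = _revcomp(seq) if self.strand == "-" else seq
            self._cds_seq = cached
        return cached

    def protein(self) -> str:
        """Cached translation of the CDS (stop codons written ``X``)."""
        cached = getattr(self, "_protein", None)
        if cached is None:
            cached = _translate(self.cds_sequence())
            self._protein = cached
        return cached

    def genomic_to_cds(self, position: int) -> Optional[int]:
        """0-based coding-strand CDS coordinate of a genomic position, or
        None when the position is outside every CDS interval."""
        running = 0
        plus_index = None
        for s, e in self.cds:
            if s <= position <= e:
                plus_index = running + (position - s)
                break
            running += e - s + 1
        if plus_index is None:
            return None
        if self.strand == "-":
            return self.cds_length - 1 - plus_index
        return plus_index

    def overlaps_cds(self, key: VariantKey) -> bool:
        start = key.position
        end = key.position + max(len(key.ref_allele) - 1, 0)
        return any(s <= end and start <= e for s, e in self.cds)


@dataclass
class EffectAnnotation:
    """Coding-effect call for one variant on one transcript."""

    region: Region
    effect: Optional[Effect] = None
    aa_change: Optional[str] = None
    gene: Optional[str] = None
    transcript_id: Optional[str] = None


@dataclass
class RegionAssignment:
    """Region label with its supporting gene, or flanking genes for
    intergenic positions."""

    region: Region
    gene: Optional[str] = None
    transcript_id: Optional[str] = None
    flanking_genes: Tuple[Optional[str], Optional[str]] = (None, None)


_REGION_PRECEDENCE = {
    Region.EXONIC: 0,
    Region.SPLICING: 1,
    Region.UTR: 2,
    Region.INTRONIC: 3,
    Region.INTERGENIC: 4,
}


class TranscriptIndex:
    """Contig-indexed lookup over a set of transcript models.

    Region precedence across overlapping transcripts is
    exonic > splicing > UTR > intronic > intergenic; the reported gene is
    the transcript supporting the winning label.
    """

    def __init__(self, models: Iterable[TranscriptModel], splice_window: int = 2):
        self.splice_window = splice_window
        self._by_contig: Dict[str, List[TranscriptModel]] = {}
        for model in models:
            contig = _harmonize(model.contig)
            self._by_contig.setdefault(contig, []).append(model)
        self._starts: Dict[str, List[int]] = {}
        for contig, contig_models in self._by_contig.items():
            contig_models.sort(key=lambda m: m.span)
            self._starts[contig] = [m.span[0] for m in contig_models]

    def models_on(self, contig: str) -> List[TranscriptModel]:
        return self._by_contig.get(_harmonize(contig), [])

    # -- region ----------------------------------------------------------

    def _model_region(self, model: TranscriptModel, key: VariantKey) -> Optional[Region]:
        start = key.position
        end = key.position + max(len(key.ref_allele) - 1, 0)
        span_s, span_e = model.span
        if end < span_s or start > span_e:
            return None
        if model.overlaps_cds(key):
            return Region.EXONIC
        if any(s <= end and start <= e for s, e in model.exons):
            return Region.UTR
        # intronic: within the splice window of an exon boundary -> splicing
        w = self.splice_window
        for s, e in model.exons:
            if (s - w <= end < s) or (e < start <= e + w):
                return Region.SPLICING
        return Region.INTRONIC

    def region_of(self, key: VariantKey) -> RegionAssignment:
        best: Optional[Tuple[int, Region, TranscriptModel]] = None
        for model in self.models_on(key.contig):
            region = self._model_region(model, key)
            if region is None:
                continue
            rank = _REGION_PRECEDENCE[region]
            if best is None or rank < best[0]:
                best = (rank, region, model)
        if best is not None:
            _, region, model = best
            return RegionAssignment(
                region=region, gene=model.gene, transcript_id=model.transcript_id
            )
        return RegionAssignment(
            region=Region.INTERGENIC, flanking_genes=self._flanks(key)
        )

    def _flanks(self, key: VariantKey) -> Tuple[Optional[str], Optional[str]]:
        contig = _harmonize(key.contig)
        models = self._by_contig.get(contig, [])
        if not models:
            return (None, None)
        left = None
        right = None
        idx = bisect.bisect_right(self._starts[contig], key.position)
        for model in reversed(models[:idx]):
            if model.span[1] < key.position:
                left = model.gene
                break
        for model in models[idx:] if idx < len(models) else []:
            if model.span[0] > key.position:
                right = model.gene
                break
        return (left, right)

    # -- coding ----------------------------------------------------------

    def coding_model(self, key: VariantKey) -> Optional[TranscriptModel]:
        for model in self.models_on(key.contig):
            if model.overlaps_cds(key):
                return model
        return None


def _harmonize(contig: str) -> str:
    name = contig[3:] if contig.lower().startswith("chr") else contig
    return f"chr{name}"


def annotate_region(
    key: VariantKey,
    models: Union[TranscriptIndex, Iterable[TranscriptModel]],
    splice_window: int = 2,
) -> RegionAssignment:
    """Region label for a variant key against a set of transcript models.

    Accepts a prebuilt :class:`TranscriptIndex` (preferred for cohort
    work) or any iterable of models.  Variants on contigs without models
    are intergenic with empty flanks.
    """
    index = models if isinstance(models, TranscriptIndex) else TranscriptIndex(models, splice_window)
    return index.region_of(key)


def _translate(seq: str) -> str:
    protein = str(Seq(seq).translate())
    return protein.replace("*", "X")  # stop codon written as X in AA changes


def annotate_coding_effect(key: VariantKey, model: TranscriptModel) -> EffectAnnotation:
    """Coding effect and AA change of a CDS-overlapping variant.

    SNVs are mapped to their CDS coordinate (strand-aware), the codon
    mutated and translated, and the change classified as
    synonymous/nonsynonymous/stopgain/stoploss with notation
    ``<refAA><aaPos><altAA>`` (stop written ``X``).  Indels are
    frameshift when the length difference is not a multiple of 3, with
    notation ``<refAA><aaPos>fs`` (``del``/``ins`` for in-frame indels).
    AA position 1 is the initiator methionine.

    Raises ``ValueError`` for keys outside the model CDS; route those
    through :func:`annotate_region` instead.
    """
    if not model.overlaps_cds(key):
        raise ValueError(f"{key} does not overlap the CDS of {model.gene}")
    minus = model.strand == "-"
    cds_seq = model.cds_sequence()
    protein = model.protein()
    ref, alt = key.ref_allele, key.alt_allele

    if len(ref) == 1 and len(alt) == 1:
        # fast path: a single substituted codon
        idx = model.genomic_to_cds(key.position)
        if idx is None:  # pragma: no cover - guarded by overlaps_cds
            raise ValueError(f"{key} maps to no CDS base of {model.gene}")
        expected = model.base_at(key.position)
        if expected != ref.upper():
            raise ValueError(
                f"reference mismatch at {key.contig}:{key.position}: "
                f"model has {expected}, key has {ref}"
            )
        codon_start = idx - idx % 3
        codon = list(cds_seq[codon_start : codon_start + 3])
        codon[idx % 3] = _revcomp(alt.upper()) if minus else alt.upper()
        ref_aa = protein[codon_start // 3]
        alt_aa = _translate("".join(codon))
        aa_pos = codon_start // 3 + 1
        if ref_aa == alt_aa:
            effect = Effect.SYNONYMOUS_SNV
        elif alt_aa == "X" and ref_aa != "X":
            effect = Effect.STOPGAIN
        elif ref_aa == "X":
            effect = Effect.STOPLOSS
        else:
            effect = Effect.NONSYNONYMOUS_SNV
        return EffectAnnotation(
            region=Region.EXONIC,
            effect=effect,
            aa_change=f"{ref_aa}{aa_pos}{alt_aa}",
            gene=model.gene,
            transcript_id=model.transcript_id,
        )

    if len(ref) == len(alt):
        # (M)NV: substitute each mapped base on the coding strand.
        mutated = list(cds_seq)
        first_idx = None
        for offset, (rb, ab) in enumerate(zip(ref, alt)):
            idx = model.genomic_to_cds(key.position + offset)
            if idx is None:
                continue
            expected = model.base_at(key.position + offset)
            if expected != rb.upper():
                raise ValueError(
                    f"reference mismatch at {key.contig}:{key.position + offset}: "
                    f"model has {expected}, key has {rb}"
                )
            mutated[idx] = _revcomp(ab)[0].upper() if minus else ab.upper()
            if first_idx is None or idx < first_idx:
                first_idx = idx
        if first_idx is None:  # pragma: no cover - guarded by overlaps_cds
            raise ValueError(f"{key} maps to no CDS base of {model.gene}")
        alt_protein = _translate("".join(mutated))
        for aa_index, (r_aa, a_aa) in enumerate(zip(protein, alt_protein)):
            if r_aa != a_aa:
                if a_aa == "X" and r_aa != "X":
                    effect = Effect.STOPGAIN
                elif r_aa == "X" and a_aa != "X":
                    effect = Effect.STOPLOSS
                else:
                    effect = Effect.NONSYNONYMOUS_SNV
                return EffectAnnotation(
                    region=Region.EXONIC,
                    effect=effect,
                    aa_change=f"{r_aa}{aa_index + 1}{a_aa}",
                    gene=model.gene,
                    transcript_id=model.transcript_id,
                )
        aa_index = first_idx // 3
        return EffectAnnotation(
            region=Region.EXONIC,
            effect=Effect.SYNONYMOUS_SNV,
            aa_change=f"{protein[aa_index]}{aa_index + 1}{protein[aa_index]}",
            gene=model.gene,
            transcript_id=model.transcript_id,
        )

    # Indel: locate the first changed base (after the shared anchor).
    shared = 0
    for rb, ab in zip(ref, alt):
        if rb.upper() != ab.upper():
            break
        shared += 1
    first_changed = key.position + shared
    idx = model.genomic_to_cds(first_changed)
    if idx is None:
        idx = model.genomic_to_cds(key.position)
    if idx is None:
        # Deletion starting upstream of the CDS; use the first CDS base hit.
        for pos in range(key.position, key.position + len(ref)):
            idx = model.genomic_to_cds(pos)
            if idx is not None:
                break
    if idx is None:  # pragma: no cover - guarded by overlaps_cds
        raise ValueError(f"{key} maps to no CDS base of {model.gene}")
    aa_pos = idx // 3 + 1
    ref_aa = protein[aa_pos - 1] if aa_pos - 1 < len(protein) else "X"
    frameshift = key.indel_length % 3 != 0
    if frameshift:
        suffix, effect = "fs", Effect.FRAMESHIFT_INDEL
    else:
        suffix = "del" if len(ref) > len(alt) else "ins"
        effect = Effect.NONFRAMESHIFT_INDEL
    return EffectAnnotation(
        region=Region.EXONIC,
        effect=effect,
        aa_change=f"{ref_aa}{aa_pos}{suffix}",
        gene=model.gene,
        transcript_id=model.transcript_id,
    )


def annotate_membership(key: VariantKey, cosmic_keys: set, dbsnp_keys: set) -> Membership:
    """COSMIC/dbSNP membership class of a normalized key."""
    return membership_class(key in cosmic_keys, key in dbsnp_keys)


# ---------------------------------------------------------------------------
# GFF3 + FASTA I/O
# ---------------------------------------------------------------------------


def write_gff3(models: Sequence[TranscriptModel], sink: Union[str, Path]) -> None:
    """Write transcript models as GFF3 (gene/mRNA/exon/CDS features)."""
    lines = ["##gff-version 3"]
    for model in models:
        s, e = model.span
        gene_id = model.gene
        tx_id = model.transcript_id
        lines.append(
            f"{model.contig}\tsomaticbench\tgene\t{s}\t{e}\t.\t{model.strand}\t.\t"
            f"ID={gene_id};Name={gene_id}"
        )
        lines.append(
            f"{model.contig}\tsomaticbench\tmRNA\t{s}\t{e}\t.\t{model.strand}\t.\t"
            f"ID={tx_id};Parent={gene_id}"
        )
        for i, (es, ee) in enumerate(model.exons, 1):
            lines.append(
                f"{model.contig}\tsomaticbench\texon\t{es}\t{ee}\t.\t{model.strand}\t.\t"
                f"ID={tx_id}.exon{i};Parent={tx_id}"
            )
        for i, (cs, ce) in enumerate(model.cds, 1):
            lines.append(
                f"{model.contig}\tsomaticbench\tCDS\t{cs}\t{ce}\t.\t{model.strand}\t0\t"
                f"ID={tx_id}.cds{i};Parent={tx_id}"
            )
    Path(sink).write_text("\n".join(lines) + "\n")


def read_transcript_models(
    gff3: Union[str, Path], fasta: Union[str, Path]
) -> List[TranscriptModel]:
    """Read toy transcript models from a GFF3 file plus genome FASTA."""
    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    db = gffutils.create_db(
        str(gff3),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: List[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA"):
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        gene = list(db.parents(mrna, featuretype="gene"))
        gene_name = gene[0].id if gene else mrna.id
        if mrna.seqid not in sequences:
            raise ValueError(f"contig {mrna.seqid} of {mrna.id} missing from FASTA")
        models.append(
            TranscriptModel(
                gene=gene_name,
                contig=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
                sequence=sequences[mrna.seqid],
                offset=1,
                transcript_id=mrna.id,
            )
        )
    return models
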