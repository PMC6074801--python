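"""Core domain types and I/O for paired tumor variant call sets.

The central objects are :class:`VariantCall` (one called variant in one
sample on one platform, carrying the MuTect2-style confidence scores) and
:class:`VariantKey` (a normalized ``(contig, position, ref, alt)`` identity
used for all set algebra between RNA-seq and WES call sets).

Two log-odds scores drive the caller emulation downstream:

* ``TLOD`` — confidence that the variant is present in the tumor sample;
* ``NLOD`` — confidence that it is absent from the matched normal.

Allele fraction (AF) is defined throughout as altered reads divided by
total reads at the variant position; when both read counts are available
the recorded AF annotation is ignored and AF is recomputed.

Readers and writers go through :mod:`pysam` for VCF and :mod:`pandas` for
the TSV sidecars; nothing here re-implements a format parser.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

import pandas as pd
import pysam

__all__ = [
    "Platform",
    "ComparisonClass",
    "Region",
    "Effect",
    "AA_CHANGING_EFFECTS",
    "Membership",
    "membership_class",
    "VariantKey",
    "VariantCall",
    "make_key",
    "Thresholds",
    "ScorePair",
    "AnnotatedVariant",
    "VcfParseError",
    "VcfReadResult",
    "read_calls",
    "write_vcf",
    "write_sites_vcf",
    "read_key_set",
    "write_calls",
    "read_annotated_tsv",
    "write_score_sidecar",
    "read_score_sidecar",
]


class Platform(str, enum.Enum):
    """Sequencing platform a call set came from."""

    RNA = "RNA"
    WES = "WES"


class ComparisonClass(str, enum.Enum):
    """Three-way class of a variant in a paired RNA-seq/WES comparison."""

    RNA_ONLY = "RNA_ONLY"
    INTERSECTION = "INTERSECTION"
    WES_ONLY = "WES_ONLY"


class Region(str, enum.Enum):
    """Genomic location category relative to the transcript models."""

    EXONIC = "exonic"
    SPLICING = "splicing"
    UTR = "UTR"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"


class Effect(str, enum.Enum):
    """Coding-effect category for variants overlapping a CDS."""

    SYNONYMOUS_SNV = "synonymous_SNV"
    NONSYNONYMOUS_SNV = "nonsynonymous_SNV"
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    FRAMESHIFT_INDEL = "frameshift_indel"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    NONCODING = "noncoding"


#: Effects that alter the protein sequence (the "Del" class of coding
#: variants: non-synonymous SNVs, stop gain/loss and frameshift indels).
AA_CHANGING_EFFECTS = frozenset(
    {
        Effect.NONSYNONYMOUS_SNV,
        Effect.STOPGAIN,
        Effect.STOPLOSS,
        Effect.FRAMESHIFT_INDEL,
    }
)


class Membership(str, enum.Enum):
    """Joint COSMIC/dbSNP database membership of a variant key.

    COSMIC-only membership is the strongest database evidence of somatic
    origin; dbSNP-only suggests a germline variant.
    """

    COSMIC_ONLY = "COSMIC_only"
    DBSNP_ONLY = "dbSNP_only"
    BOTH = "both"
    NEITHER = "neither"


def membership_class(in_cosmic: bool, in_dbsnp: bool) -> Membership:
    """Four-way membership class from the two database flags."""
    if in_cosmic and in_dbsnp:
        return Membership.BOTH
    if in_cosmic:
        return Membership.COSMIC_ONLY
    if in_dbsnp:
        return Membership.DBSNP_ONLY
    return Membership.NEITHER


def _harmonize_contig(contig: str) -> str:
    """Canonical contig spelling: always ``chr``-prefixed for comparison."""
    name = contig[3:] if contig.lower().startswith("chr") else contig
    return f"chr{name}"


def _normalize_alleles(position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared bases between ref and alt, re-anchoring indels.

    Shared suffix bases are trimmed first, then shared prefix bases (the
    position advancing with each prefix base).  If trimming empties one
    allele (an indel) a single anchor base is restored: the last trimmed
    suffix base when one exists, else the last trimmed prefix base.  The
    result is a canonical form under which alternative spellings of the
    same indel (e.g. ``GCC>GC`` at 50 and ``CC>C`` at 51) compare equal.
    """
    if not ref or not alt:
        raise ValueError("empty allele before normalization")
    if ref == alt:
        raise ValueError("ref and alt alleles are identical")
    r, a = ref, alt
    last_suffix: Optional[str] = None
    while r and a and r[-1] == a[-1]:
        last_suffix = r[-1]
        r, a = r[:-1], a[:-1]
    last_prefix: Optional[str] = None
    while r and a and r[0] == a[0]:
        last_prefix = r[0]
        r, a = r[1:], a[1:]
        position += 1
    if not r or not a:
        if last_suffix is not None:
            r, a = r + last_suffix, a + last_suffix
        elif last_prefix is not None:
            r, a = last_prefix + r, last_prefix + a
            position -= 1
        else:  # pragma: no cover - unreachable for valid ref != alt
            raise ValueError(
                f"allele pair {ref!r}>{alt!r} empties without an anchor base"
            )
    return position, r, a


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized variant identity: ``(contig, position, ref, alt)``.

    Keys are hashable, totally ordered, and canonical: shared leading and
    trailing bases are trimmed (a single anchor base is retained for
    indels) and contig naming is harmonized (``7`` and ``chr7`` compare
    equal).  All cross-platform set algebra operates on keys.
    """

    contig: str
    position: int
    ref_allele: str
    alt_allele: str

    @classmethod
    def make(cls, contig: str, position: int, ref: str, alt: str) -> "VariantKey":
        position, ref, alt = _normalize_alleles(position, ref.upper(), alt.upper())
        return cls(_harmonize_contig(contig), position, ref, alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    def __str__(self) -> str:
        return f"{self.contig}:{self.position}:{self.ref_allele}>{self.alt_allele}"


@dataclass
class VariantCall:
    """One called variant in one sample on one platform.

    ``allele_fraction`` is always consistent with ``alt_reads / depth``
    when ``depth > 0``; passing ``allele_fraction=None`` computes it.
    ``filter_labels`` holds the caller's FILTER column verbatim (``PASS``
    or named filters); the harness in :mod:`somaticbench.filters` replaces
    the threshold-expressible labels with emulated decisions.
    """

    sample_id: str
    platform: Platform
    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    alt_reads: int
    depth: int
    tlod: Optional[float] = None
    nlod: Optional[float] = None
    allele_fraction: Optional[float] = None
    filter_labels: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")
        if self.alt_reads < 0 or self.depth < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth})"
            )
        if self.depth > 0:
            af = self.alt_reads / self.depth
            if self.allele_fraction is not None and abs(self.allele_fraction - af) > 1e-9:
                raise ValueError(
                    f"allele_fraction {self.allele_fraction} inconsistent with "
                    f"{self.alt_reads}/{self.depth}"
                )
            self.allele_fraction = af
        elif self.allele_fraction is None:
            self.allele_fraction = 0.0
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError(f"allele_fraction {self.allele_fraction} outside [0, 1]")
        self.filter_labels = set(self.filter_labels)

    @property
    def key(self) -> VariantKey:
        return VariantKey.make(
            self.contig, self.position, self.ref_allele, self.alt_allele
        )

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def is_pass(self) -> bool:
        return self.filter_labels == {"PASS"}


def make_key(call: VariantCall) -> VariantKey:
    """Normalized :class:`VariantKey` for a call (see :class:`VariantKey`)."""
    return call.key


@dataclass(frozen=True)
class Thresholds:
    """Every threshold used by the analysis, with the published defaults.

    * ``tlod_pass`` — a variant passes only with TLOD strictly above 6.3.
    * ``nlod_somatic`` — NLOD must exceed 2.2 to be accepted as somatic.
    * ``nlod_dbsnp`` — for dbSNP variants the NLOD requirement is raised
      to 5.5 unless the variant is also in COSMIC.
    * ``nlod_alt_in_normal`` — the evidence-in-normal filter fires below
      NLOD 2.0.
    * ``pon_min_samples`` — a panel-of-normals site must be called in at
      least this many normal samples (2).
    * ``sift_cutoff`` — SIFT calls Deleterious strictly below 0.05.
    * ``fathmm_cutoff`` — cancer-weighted FATHMM calls CANCER strictly
      below -0.75.
    * ``fathmm_indel_max_len`` — FATHMM scores indels shorter than 20 bp.
    * ``recurrence_min_samples`` — recurrent genes must be altered in at
      least 5 tumors.

    All comparisons downstream are strict, exactly as printed.
    """

    tlod_pass: float = 6.3
    nlod_somatic: float = 2.2
    nlod_dbsnp: float = 5.5
    nlod_alt_in_normal: float = 2.0
    pon_min_samples: int = 2
    sift_cutoff: float = 0.05
    fathmm_cutoff: float = -0.75
    fathmm_indel_max_len: int = 20
    recurrence_min_samples: int = 5

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not math.isfinite(value):
                raise ValueError(f"threshold {f.name} must be finite")
        if self.pon_min_samples < 1:
            raise ValueError("pon_min_samples must be >= 1")


@dataclass
class ScorePair:
    """SIFT and cancer-weighted FATHMM information for one variant.

    SNVs carry numeric scores (``sift_score`` in [0, 1], ``fathmm_score``
    unbounded, more negative = more driver-like).  Indels carry categorical
    predictions with confidence percentages instead of numeric scores:
    ``sift_score`` then holds the SIFT-indel confidence (%) and
    ``fathmm_confidence`` the FATHMM-indel confidence (%).
    """

    is_indel: bool = False
    sift_score: Optional[float] = None
    sift_pred: Optional[str] = None
    fathmm_score: Optional[float] = None
    fathmm_pred: Optional[str] = None
    fathmm_confidence: Optional[float] = None


@dataclass
class AnnotatedVariant:
    """A :class:`VariantCall` plus everything downstream filters consume:
    gene, genomic region, coding effect, amino-acid change, database
    membership, functional scores and the three-way comparison class."""

    call: VariantCall
    gene: Optional[str] = None
    flanking_genes: Optional[tuple] = None
    region: Optional[Region] = None
    effect: Optional[Effect] = None
    aa_change: Optional[str] = None
    in_cosmic: Optional[bool] = None
    in_dbsnp: Optional[bool] = None
    scores: Optional[ScorePair] = None
    comparison_class: Optional[ComparisonClass] = None
    flags: set = field(default_factory=set)

    @property
    def key(self) -> VariantKey:
        return self.call.key

    @property
    def membership(self) -> Membership:
        if self.in_cosmic is None or self.in_dbsnp is None:
            raise ValueError("database membership flags are unset")
        return membership_class(self.in_cosmic, self.in_dbsnp)


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------


class VcfParseError(ValueError):
    """Raised when a VCF stream cannot be parsed into calls."""


class VcfReadResult(Sequence):
    """Sequence of :class:`VariantCall` plus parsing bookkeeping.

    Behaves like a list of calls; ``n_symbolic_skipped`` counts records
    whose ALT allele was symbolic (``<DEL>``, ``*`` ...) and was skipped.
    """

    def __init__(self, calls: list, n_symbolic_skipped: int = 0):
        self.calls = calls
        self.n_symbolic_skipped = n_symbolic_skipped

    def __len__(self) -> int:
        return len(self.calls)

    def __getitem__(self, item):
        return self.calls[item]

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls)


def _info_float(record, key: str, alt_index: int) -> Optional[float]:
    """A per-alt or scalar float INFO value, None when absent."""
    value = record.info.get(key)
    if value is None:
        return None
    if isinstance(value, tuple):
        if not value:
            return None
        value = value[alt_index] if alt_index < len(value) else value[0]
    return None if value is None else float(value)


_SYMBOLIC = ("<", ">", "*", "[", "]", ".")


def read_calls(
    source: Union[str, Path],
    sample_id: str,
    platform: Platform,
) -> VcfReadResult:
    """Read a VCF into :class:`VariantCall` objects, one per (record, alt).

    Multi-allelic records are split per alternate allele.  AF is
    recomputed from ``AD``/``DP`` whenever read counts are present and
    only taken from the ``AF`` annotation otherwise.  Records with
    symbolic alternate alleles are skipped and counted on the result.

    Raises :class:`VcfParseError` naming the failing record for malformed
    input; a VCF without a FILTER column is rejected by the header parser.
    """
    platform = Platform(platform)
    calls: list[VariantCall] = []
    n_symbolic = 0
    try:
        vcf = pysam.VariantFile(str(source))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF header of {source}: {exc}") from exc
    with vcf:
        record_no = 0
        iterator = iter(vcf)
        while True:
            record_no += 1
            try:
                try:
                    record = next(iterator)
                except StopIteration:
                    break
            except Exception as exc:
                raise VcfParseError(
                    f"malformed VCF record #{record_no} in {source}: {exc}"
                ) from exc
            alts = record.alts or ()
            filters = set(record.filter.keys())
            sample = record.samples[0] if record.samples else None
            for alt_index, alt in enumerate(alts):
                if alt is None or any(c in alt for c in _SYMBOLIC):
                    n_symbolic += 1
                    continue
                alt_reads, depth = _read_counts(record, sample, alt_index)
                af = None
                if depth == 0:
                    af = _info_float(record, "AF", alt_index)
                    if af is None and sample is not None and "AF" in sample:
                        value = sample["AF"]
                        af = float(value[alt_index] if isinstance(value, tuple) else value)
                try:
                    calls.append(
                        VariantCall(
                            sample_id=sample_id,
                            platform=platform,
                            contig=record.contig,
                            position=record.pos,
                            ref_allele=record.ref,
                            alt_allele=alt,
                            alt_reads=alt_reads,
                            depth=depth,
                            tlod=_info_float(record, "TLOD", alt_index),
                            nlod=_info_float(record, "NLOD", alt_index),
                            allele_fraction=af,
                            filter_labels=set(filters),
                        )
                    )
                except ValueError as exc:
                    raise VcfParseError(
                        f"invalid record #{record_no} in {source}: {exc}"
                    ) from exc
    return VcfReadResult(calls, n_symbolic)


def _read_counts(record, sample, alt_index: int) -> tuple[int, int]:
    """(alt_reads, depth) from FORMAT AD/DP, falling back to INFO."""
    alt_reads = 0
    depth = 0
    ad = None
    if sample is not None and "AD" in sample and sample["AD"] is not None:
        ad = sample["AD"]
    elif "AD" in record.info:
        ad = record.info["AD"]
    if ad is not None and not isinstance(ad, tuple):
        ad = (ad,)
    if ad is not None and len(ad) > alt_index + 1 and ad[alt_index + 1] is not None:
        alt_reads = int(ad[alt_index + 1])
    if sample is not None and "DP" in sample and sample["DP"] is not None:
        depth = int(sample["DP"])
    elif "DP" in record.info:
        depth = int(record.info["DP"])
    elif ad is not None:
        depth = int(sum(x for x in ad if x is not None))
    # Guard against inconsistent inputs rather than fail the whole file.
    if ad is not None and depth < alt_reads:
        depth = int(sum(x for x in ad if x is not None))
    return alt_reads, depth


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------

_FILTER_DESCRIPTIONS = {
    "t_lod_fstar": "Insufficient evidence of presence in the tumor (TLOD below threshold)",
    "alt_allele_in_normal": "Evidence of the alternate allele in the matched normal",
    "germline_risk": "Evidence of germline origin from dbSNP/COSMIC and NLOD",
    "panel_of_normals": "Present in at least two samples of the panel of normals",
    "homologous_mapping_event": "Homologous mapping event (passed through)",
    "clustered_events": "Clustered artifacts (passed through)",
    "str_contraction": "Short tandem repeat contraction (passed through)",
    "multi_event_alt_allele_in_normal": "Multiple events in normal (passed through)",
}


def _vcf_header(
    contigs: Iterable[str],
    sample_ids: Sequence[str],
    extra_filters: Iterable[str] = (),
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    header.info.add("TLOD", "A", "Float", "Tumor LOD score")
    header.info.add("NLOD", "A", "Float", "Normal LOD score")
    header.info.add("AF", "A", "Float", "Allele fraction")
    header.info.add("DP", "1", "Integer", "Total depth")
    names = set(_FILTER_DESCRIPTIONS) | {str(f) for f in extra_filters}
    for name in sorted(names - {"PASS"}):
        header.filters.add(name, None, None, _FILTER_DESCRIPTIONS.get(name, "Filtered"))
    header.formats.add("GT", "1", "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", "1", "Integer", "Total depth")
    header.formats.add("AF", "A", "Float", "Allele fraction")
    for sample_id in sample_ids:
        header.add_sample(sample_id)
    return header


def write_vcf(
    calls: Sequence[VariantCall],
    sink: Union[str, Path],
    sample_id: Optional[str] = None,
    contigs: Optional[Sequence[str]] = None,
) -> None:
    """Write calls as a single-sample uncompressed VCF.

    TLOD/NLOD go to INFO, read counts to the sample column
    (``GT:AD:DP:AF``), and ``filter_labels`` verbatim to FILTER.  Records
    are emitted sorted by (contig, position, ref, alt).
    """
    calls = sorted(calls, key=lambda c: (c.contig, c.position, c.ref_allele, c.alt_allele))
    if sample_id is None:
        sample_id = calls[0].sample_id if calls else "SAMPLE"
    if contigs is None:
        contigs = sorted({c.contig for c in calls})
    labels = set().union(*(c.filter_labels for c in calls)) if calls else set()
    header = _vcf_header(contigs, [sample_id], labels)
    with pysam.VariantFile(str(sink), "w", header=header) as out:
        for call in calls:
            rec = out.new_record(
                contig=call.contig,
                start=call.position - 1,
                alleles=(call.ref_allele, call.alt_allele),
            )
            if call.tlod is not None:
                rec.info["TLOD"] = (round(call.tlod, 4),)
            if call.nlod is not None:
                rec.info["NLOD"] = (round(call.nlod, 4),)
            for label in sorted(call.filter_labels):
                rec.filter.add(label)
            sample = rec.samples[sample_id]
            sample["GT"] = (0, 1)
            sample["AD"] = (call.depth - call.alt_reads, call.alt_reads)
            sample["DP"] = call.depth
            sample["AF"] = (round(call.allele_fraction, 6),)
            out.write(rec)


def write_sites_vcf(keys: Iterable[VariantKey], sink: Union[str, Path]) -> None:
    """Write a sites-only VCF (no samples) from a key set, sorted."""
    keys = sorted(set(keys))
    header = pysam.VariantHeader()
    for contig in sorted({k.contig for k in keys}):
        header.contigs.add(contig)
    with pysam.VariantFile(str(sink), "w", header=header) as out:
        for key in keys:
            rec = out.new_record(
                contig=key.contig,
                start=key.position - 1,
                alleles=(key.ref_allele, key.alt_allele),
            )
            out.write(rec)


def read_key_set(source: Union[str, Path]) -> set:
    """Normalized :class:`VariantKey` set from a (sites-only) VCF."""
    keys: set = set()
    with pysam.VariantFile(str(source)) as vcf:
        for record in vcf:
            for alt in record.alts or ():
                if alt is None or any(c in alt for c in _SYMBOLIC):
                    continue
                keys.add(VariantKey.make(record.contig, record.pos, record.ref, alt))
    return keys


# ---------------------------------------------------------------------------
# Annotated TSV round trip
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "sample_id", "platform", "contig", "position", "ref_allele", "alt_allele",
    "tlod", "nlod", "alt_reads", "depth", "allele_fraction", "filter_labels",
    "gene", "flanking_genes", "region", "effect", "aa_change",
    "in_cosmic", "in_dbsnp", "comparison_class",
    "is_indel", "sift_score", "sift_pred", "fathmm_score", "fathmm_pred",
    "fathmm_confidence", "flags",
]


def _annotated_row(v: AnnotatedVariant) -> dict:
    c = v.call
    s = v.scores or ScorePair()
    return {
        "sample_id": c.sample_id,
        "platform": c.platform.value,
        "contig": c.contig,
        "position": c.position,
        "ref_allele": c.ref_allele,
        "alt_allele": c.alt_allele,
        "tlod": c.tlod,
        "nlod": c.nlod,
        "alt_reads": c.alt_reads,
        "depth": c.depth,
        "allele_fraction": c.allele_fraction,
        "filter_labels": ";".join(sorted(c.filter_labels)),
        "gene": v.gene,
        "flanking_genes": ";".join(v.flanking_genes) if v.flanking_genes else None,
        "region": v.region.value if v.region else None,
        "effect": v.effect.value if v.effect else None,
        "aa_change": v.aa_change,
        "in_cosmic": v.in_cosmic,
        "in_dbsnp": v.in_dbsnp,
        "comparison_class": v.comparison_class.value if v.comparison_class else None,
        "is_indel": s.is_indel,
        "sift_score": s.sift_score,
        "sift_pred": s.sift_pred,
        "fathmm_score": s.fathmm_score,
        "fathmm_pred": s.fathmm_pred,
        "fathmm_confidence": s.fathmm_confidence,
        "flags": ";".join(sorted(v.flags)) if v.flags else None,
    }


def write_calls(
    calls: Sequence[Union[AnnotatedVariant, VariantCall]],
    sink: Union[str, Path, IO[str]],
) -> None:
    """Write (annotated) calls as a TSV; round-trip stable via
    :func:`read_annotated_tsv`.  Plain :class:`VariantCall` inputs are
    wrapped with empty annotations.  An empty input yields a header-only
    file.  Absent scores (e.g. NLOD in tumor-only mode) serialize as empty
    cells and read back as ``None``."""
    records = [
        v if isinstance(v, AnnotatedVariant) else AnnotatedVariant(call=v)
        for v in calls
    ]
    frame = pd.DataFrame([_annotated_row(v) for v in records], columns=_TSV_COLUMNS)
    frame.to_csv(sink, sep="\t", index=False)


def _opt(value, cast=float):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return cast(value)


def read_annotated_tsv(source: Union[str, Path, IO[str]]) -> list:
    """Read a TSV written by :func:`write_calls` back into
    :class:`AnnotatedVariant` objects."""
    frame = pd.read_csv(source, sep="\t", dtype={"contig": str})
    out: list[AnnotatedVariant] = []
    for row in frame.to_dict("records"):
        call = VariantCall(
            sample_id=row["sample_id"],
            platform=Platform(row["platform"]),
            contig=row["contig"],
            position=int(row["position"]),
            ref_allele=row["ref_allele"],
            alt_allele=row["alt_allele"],
            alt_reads=int(row["alt_reads"]),
            depth=int(row["depth"]),
            tlod=_opt(row["tlod"]),
            nlod=_opt(row["nlod"]),
            filter_labels=set(str(row["filter_labels"]).split(";"))
            if _opt(row["filter_labels"], str)
            else set(),
        )
        scores = ScorePair(
            is_indel=bool(row["is_indel"]),
            sift_score=_opt(row["sift_score"]),
            sift_pred=_opt(row["sift_pred"], str),
            fathmm_score=_opt(row["fathmm_score"]),
            fathmm_pred=_opt(row["fathmm_pred"], str),
            fathmm_confidence=_opt(row["fathmm_confidence"]),
        )
        if all(
            getattr(scores, f) in (None, False)
            for f in ("sift_score", "sift_pred", "fathmm_score", "fathmm_pred",
                      "fathmm_confidence")
        ):
            scores = None
        flanks = _opt(row["flanking_genes"], str)
        out.append(
            AnnotatedVariant(
                call=call,
                gene=_opt(row["gene"], str),
                flanking_genes=tuple(flanks.split(";")) if flanks else None,
                region=Region(row["region"]) if _opt(row["region"], str) else None,
                effect=Effect(row["effect"]) if _opt(row["effect"], str) else None,
                aa_change=_opt(row["aa_change"], str),
                in_cosmic=_opt(row["in_cosmic"], bool),
                in_dbsnp=_opt(row["in_dbsnp"], bool),
                scores=scores,
                comparison_class=ComparisonClass(row["comparison_class"])
                if _opt(row["comparison_class"], str)
                else None,
                flags=set(str(row["flags"]).split(";"))
                if _opt(row["flags"], str)
                else set(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Score sidecar
# ---------------------------------------------------------------------------

_SIDECAR_COLUMNS = [
    "contig", "position", "ref", "alt", "gene", "aa_change",
    "sift_score", "sift_pred", "fathmm_score", "fathmm_pred", "score_confidence",
]


def write_score_sidecar(rows: pd.DataFrame, sink: Union[str, Path]) -> None:
    """Write a functional-score sidecar TSV.

    Expected columns: contig, position, ref, alt, gene, aa_change,
    sift_score, sift_pred, fathmm_score, fathmm_pred, score_confidence.
    For indels ``sift_score`` holds the SIFT-indel confidence (%) and
    ``score_confidence`` the FATHMM-indel confidence (%).
    """
    rows.loc[:, _SIDECAR_COLUMNS].to_csv(sink, sep="\t", index=False)


def read_score_sidecar(source: Union[str, Path]) -> dict:
    """Sidecar TSV as a mapping ``VariantKey -> ScorePair`` (plus gene and
    aa_change kept on the returned pairs via attributes ``gene`` /
    ``aa_change`` in the companion mapping)."""
    frame = pd.read_csv(source, sep="\t", dtype={"contig": str})
    scores: dict = {}
    for row in frame.to_dict("records"):
        key = VariantKey.make(row["contig"], int(row["position"]), row["ref"], row["alt"])
        is_indel = key.is_indel
        scores[key] = ScorePair(
            is_indel=is_indel,
            sift_score=_opt(row["sift_score"]),
            sift_pred=_opt(row["sift_pred"], str),
            fathmm_score=_opt(row["fathmm_score"]),
            fathmm_pred=_opt(row["fathmm_pred"], str),
            fathmm_confidence=_opt(row["score_confidence"]),
        )
    return scores
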