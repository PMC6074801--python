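"""SIFT/FATHMM threshold calls and the two headline candidate filters.

Two selection criteria operate on fully annotated variants:

* the *best GBM-related mutation* criterion — variant in the curated
  29-gene GBM pathway set, COSMIC-only (in COSMIC, not in dbSNP),
  protein-altering, and retained by **both** SIFT and cancer-weighted
  FATHMM;
* the *candidate novel mutation* criterion — variant in the gene set,
  unknown to both databases, protein-altering, retained by **either**
  score, and supported by at least ``min_alt_reads`` altered reads (a
  plausibility guard against artifacts).

Threshold semantics are strict as printed: SIFT Deleterious below 0.05,
FATHMM CANCER below -0.75; boundary values are not retained.  Indels are
scored categorically (SIFT-indel Damaging; FATHMM-indel pathogenic, only
for indels shorter than 20 bp — longer indels are unscorable and counted,
never silently dropped).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set

from .model import (
    AA_CHANGING_EFFECTS,
    AnnotatedVariant,
    ComparisonClass,
    Membership,
    ScorePair,
    Thresholds,
)

__all__ = [
    "GeneSet",
    "sift_call",
    "fathmm_call",
    "fathmm_scorable",
    "FilterReport",
    "best_gbm_filter",
    "novel_candidate_filter",
    "flag_suspect_recurrent_indels",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols used to restrict candidate searches."""

    name: str
    genes: FrozenSet[str]

    def __contains__(self, gene: Optional[str]) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


def sift_call(pair: ScorePair, thresholds: Thresholds = Thresholds()) -> bool:
    """True when SIFT retains the variant as deleterious.

    SNVs: numeric score strictly below ``sift_cutoff`` (0.05).
    Indels: SIFT-indel prediction ``Damaging``.
    """
    if pair.is_indel:
        if pair.sift_pred is None:
            raise ValueError("indel without a SIFT-indel prediction")
        return pair.sift_pred == "Damaging"
    if pair.sift_score is None:
        if pair.sift_pred is None:
            raise ValueError("SNV without SIFT score or prediction")
        return pair.sift_pred == "Deleterious"
    return pair.sift_score < thresholds.sift_cutoff


def fathmm_scorable(pair: ScorePair, indel_length: int, thresholds: Thresholds = Thresholds()) -> bool:
    """FATHMM-indel only scores indels shorter than ``fathmm_indel_max_len``."""
    return not pair.is_indel or indel_length < thresholds.fathmm_indel_max_len


def fathmm_call(
    pair: ScorePair,
    thresholds: Thresholds = Thresholds(),
    indel_length: int = 1,
) -> bool:
    """True when cancer-weighted FATHMM retains the variant.

    SNVs: numeric score strictly below ``fathmm_cutoff`` (-0.75, the
    CANCER call).  Indels: FATHMM-indel prediction ``pathogenic``; indels
    of ``fathmm_indel_max_len`` (20 bp) or longer are unscorable and
    treated as not retained (count them via :func:`fathmm_scorable`).
    """
    if pair.is_indel:
        if not fathmm_scorable(pair, indel_length, thresholds):
            return False
        if pair.fathmm_pred is None:
            raise ValueError("indel without a FATHMM-indel prediction")
        return pair.fathmm_pred == "pathogenic"
    if pair.fathmm_score is None:
        if pair.fathmm_pred is None:
            raise ValueError("SNV without FATHMM score or prediction")
        return pair.fathmm_pred == "CANCER"
    return pair.fathmm_score < thresholds.fathmm_cutoff


@dataclass
class FilterReport(Sequence):
    """Retained variants plus rejection bookkeeping.

    Iterates over the retained subset; ``rejected`` counts rejections by
    first failing criterion and ``n_fathmm_unscorable`` counts indels too
    long for FATHMM-indel.
    """

    retained: List[AnnotatedVariant] = field(default_factory=list)
    rejected: Dict[str, int] = field(default_factory=dict)
    n_fathmm_unscorable: int = 0

    def __len__(self) -> int:
        return len(self.retained)

    def __getitem__(self, item):
        return self.retained[item]

    def __iter__(self):
        return iter(self.retained)


def _require_annotations(variant: AnnotatedVariant, need_scores: bool = True) -> None:
    missing = []
    if variant.gene is None:
        missing.append("gene")
    if variant.effect is None:
        missing.append("effect")
    if variant.in_cosmic is None or variant.in_dbsnp is None:
        missing.append("database membership")
    if need_scores and variant.scores is None:
        missing.append("SIFT/FATHMM scores")
    if missing:
        raise ValueError(f"variant {variant.key} lacks annotations: {', '.join(missing)}")


def best_gbm_filter(
    variants: Sequence[AnnotatedVariant],
    gene_set: GeneSet,
    thresholds: Thresholds = Thresholds(),
) -> FilterReport:
    """Select the best GBM-related mutations.

    Retained iff gene in ``gene_set`` AND membership is COSMIC-only AND
    the effect is protein-altering AND SIFT retains AND FATHMM retains
    (conjunction).  Raises for variants missing any required annotation.
    """
    report = FilterReport(rejected=Counter())
    for variant in variants:
        _require_annotations(variant)
        indel_len = variant.key.indel_length
        if variant.scores.is_indel and not fathmm_scorable(
            variant.scores, indel_len, thresholds
        ):
            report.n_fathmm_unscorable += 1
        if variant.gene not in gene_set:
            report.rejected["gene_not_in_set"] += 1
        elif variant.membership is not Membership.COSMIC_ONLY:
            report.rejected["not_cosmic_only"] += 1
        elif variant.effect not in AA_CHANGING_EFFECTS:
            report.rejected["not_aa_changing"] += 1
        elif not sift_call(variant.scores, thresholds):
            report.rejected["sift_not_retained"] += 1
        elif not fathmm_call(variant.scores, thresholds, indel_len):
            report.rejected["fathmm_not_retained"] += 1
        else:
            report.retained.append(variant)
    report.rejected = dict(report.rejected)
    return report


def novel_candidate_filter(
    variants: Sequence[AnnotatedVariant],
    gene_set: GeneSet,
    thresholds: Thresholds = Thresholds(),
    min_alt_reads: int = 2,
) -> FilterReport:
    """Select candidate novel mutations.

    Retained iff gene in ``gene_set`` AND membership is neither (unknown
    to COSMIC and dbSNP) AND protein-altering AND retained by SIFT **or**
    FATHMM AND supported by at least ``min_alt_reads`` altered reads.
    """
    report = FilterReport(rejected=Counter())
    for variant in variants:
        _require_annotations(variant)
        indel_len = variant.key.indel_length
        if variant.scores.is_indel and not fathmm_scorable(
            variant.scores, indel_len, thresholds
        ):
            report.n_fathmm_unscorable += 1
        if variant.gene not in gene_set:
            report.rejected["gene_not_in_set"] += 1
        elif variant.membership is not Membership.NEITHER:
            report.rejected["known_to_database"] += 1
        elif variant.effect not in AA_CHANGING_EFFECTS:
            report.rejected["not_aa_changing"] += 1
        elif not (
            sift_call(variant.scores, thresholds)
            or fathmm_call(variant.scores, thresholds, indel_len)
        ):
            report.rejected["no_score_retains"] += 1
        elif variant.call.alt_reads < min_alt_reads:
            report.rejected["too_few_alt_reads"] += 1
        else:
            report.retained.append(variant)
    report.rejected = dict(report.rejected)
    return report


def flag_suspect_recurrent_indels(
    variants: Iterable[AnnotatedVariant],
    min_samples: int = 9,
) -> Set:
    """Flag indels recurring at the identical key in many tumors yet never
    seen by WES.

    An indel called RNA-only at exactly the same position in
    ``min_samples`` or more tumors, with no WES support anywhere, is
    suspicious of a systematic artifact.  Matching variants get the flag
    ``suspect_recurrent_indel`` added to ``flags`` (they are never
    dropped); the set of flagged keys is returned.
    """
    by_key: Dict = defaultdict(list)
    for variant in variants:
        if variant.call.is_indel:
            by_key[variant.key].append(variant)
    flagged = set()
    for key, group in by_key.items():
        samples = {v.call.sample_id for v in group}
        all_rna_only = all(
            v.comparison_class is ComparisonClass.RNA_ONLY for v in group
        )
        if len(samples) >= min_samples and all_rna_only:
            for v in group:
                v.flags.add("suspect_recurrent_indel")
            flagged.add(key)
    return flagged
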