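"""Threshold-level emulation of the MuTect2 acceptance logic.

Only the filters that are pure functions of the caller's published scores
are recomputed here: ``t_lod_fstar`` (TLOD), ``germline_risk`` and
``alt_allele_in_normal`` (NLOD and database membership) and
``panel_of_normals`` (site recurrence in normal samples).  Filters that
depend on read alignments (``homologous_mapping_event``,
``clustered_events``, ``str_contraction``,
``multi_event_alt_allele_in_normal``) are never recomputed — they are
passed through verbatim from the input FILTER column.

Acceptance rule emulated: a variant is PASS when TLOD > 6.3 and, in
tumor-normal mode, NLOD > 2.2; for dbSNP variants the NLOD requirement is
raised to 5.5, except when the variant is also present in COSMIC.  All
comparisons are strict.  In tumor-only mode only the TLOD rule applies.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

from .model import Thresholds, VariantCall, VariantKey

__all__ = [
    "CallingMode",
    "PanelOfNormals",
    "FilterDecision",
    "EMULATED_LABELS",
    "build_pon",
    "decide_filters",
    "apply_filter_harness",
    "filter_stats",
]


class CallingMode(str, enum.Enum):
    TUMOR_NORMAL = "TUMOR_NORMAL"
    TUMOR_ONLY = "TUMOR_ONLY"


#: Labels this harness computes itself; anything else on an input call is
#: treated as a pass-through (alignment-dependent) label.
EMULATED_LABELS = frozenset(
    {"PASS", "t_lod_fstar", "alt_allele_in_normal", "germline_risk", "panel_of_normals"}
)


@dataclass
class PanelOfNormals:
    """Sites recurrently called across normal samples.

    ``keys`` holds every variant key seen in at least ``min_samples``
    distinct normal call sets out of ``n_normals`` contributed.
    """

    keys: set
    n_normals: int
    min_samples: int

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)


def build_pon(
    normal_call_sets: Sequence[Iterable[VariantCall]],
    min_samples: int = 2,
) -> PanelOfNormals:
    """Compile a panel of normals from per-normal call sets.

    A key enters the panel when it is called in at least ``min_samples``
    distinct normal samples; duplicate calls of a key within one normal
    count once.  Membership is independent of the order of the samples.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if len(normal_call_sets) == 0:
        raise ValueError("at least one normal call set is required")
    counts: Counter = Counter()
    for call_set in normal_call_sets:
        for key in {call.key for call in call_set}:
            counts[key] += 1
    keys = {key for key, n in counts.items() if n >= min_samples}
    return PanelOfNormals(keys=keys, n_normals=len(normal_call_sets), min_samples=min_samples)


@dataclass
class FilterDecision:
    """Outcome of the emulated acceptance logic for one call.

    ``labels`` contains ``PASS`` exactly when no emulated or pass-through
    filter fired; otherwise it contains every label that fired.
    """

    labels: set = field(default_factory=set)
    mode: CallingMode = CallingMode.TUMOR_NORMAL

    @property
    def is_pass(self) -> bool:
        return self.labels == {"PASS"}


def decide_filters(
    call: VariantCall,
    in_dbsnp: bool,
    in_cosmic: bool,
    pon: Optional[PanelOfNormals],
    thresholds: Thresholds = Thresholds(),
    mode: CallingMode = CallingMode.TUMOR_NORMAL,
    apply_pon: bool = True,
) -> FilterDecision:
    """Emulated filter decision for one call.

    * ``t_lod_fstar`` fires when TLOD <= ``tlod_pass`` (the strict
      TLOD > 6.3 pass rule, negated).
    * ``germline_risk`` fires (tumor-normal mode) when NLOD fails the
      effective requirement: ``nlod_somatic`` normally, raised to
      ``nlod_dbsnp`` for dbSNP variants not present in COSMIC.
    * ``alt_allele_in_normal`` fires when NLOD < ``nlod_alt_in_normal``,
      i.e. low confidence that the allele is absent from the normal.  At
      default thresholds it is subsumed by ``germline_risk`` but both are
      reported independently.
    * ``panel_of_normals`` fires when the key is in the panel.
    * Pass-through labels on the input call are retained verbatim.

    TLOD is required; NLOD is required in tumor-normal mode only.
    """
    mode = CallingMode(mode)
    if call.tlod is None:
        raise ValueError(f"call {call.key} has no TLOD score")
    if mode is CallingMode.TUMOR_NORMAL and call.nlod is None:
        raise ValueError(f"call {call.key} has no NLOD score (tumor-normal mode)")
    labels: set = set()
    if call.tlod <= thresholds.tlod_pass:
        labels.add("t_lod_fstar")
    if mode is CallingMode.TUMOR_NORMAL:
        nlod_required = thresholds.nlod_somatic
        if in_dbsnp and not in_cosmic:
            nlod_required = thresholds.nlod_dbsnp
        if call.nlod <= nlod_required:
            labels.add("germline_risk")
        if call.nlod < thresholds.nlod_alt_in_normal:
            labels.add("alt_allele_in_normal")
    if apply_pon and pon is not None and call.key in pon:
        labels.add("panel_of_normals")
    labels |= set(call.filter_labels) - EMULATED_LABELS
    if not labels:
        labels = {"PASS"}
    return FilterDecision(labels=labels, mode=mode)


def apply_filter_harness(
    calls: Iterable[VariantCall],
    dbsnp_keys: set,
    cosmic_keys: set,
    pon: Optional[PanelOfNormals],
    thresholds: Thresholds = Thresholds(),
    mode: CallingMode = CallingMode.TUMOR_NORMAL,
    apply_pon: bool = True,
) -> list:
    """Run :func:`decide_filters` over a call set, rewriting each call's
    ``filter_labels`` with the emulated decision.  Returns the calls."""
    out = []
    for call in calls:
        key = call.key
        decision = decide_filters(
            call,
            in_dbsnp=key in dbsnp_keys,
            in_cosmic=key in cosmic_keys,
            pon=pon,
            thresholds=thresholds,
            mode=mode,
            apply_pon=apply_pon,
        )
        call.filter_labels = decision.labels
        out.append(call)
    return out


def filter_stats(calls: Sequence[VariantCall]) -> Dict[str, float]:
    """Proportion of calls failing each filter, plus the PASS proportion.

    Every call must carry a decision in ``filter_labels``.  A call bearing
    k filter labels contributes to each of the k labels; the ``PASS``
    entry is the fraction of calls whose label set is exactly ``{PASS}``.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("filter_stats requires at least one decided call")
    n = len(calls)
    tally: Counter = Counter()
    n_pass = 0
    for call in calls:
        if not call.filter_labels:
            raise ValueError(f"call {call.key} carries no filter decision")
        if call.is_pass:
            n_pass += 1
        for label in call.filter_labels - {"PASS"}:
            tally[label] += 1
    stats = {label: count / n for label, count in sorted(tally.items())}
    stats["PASS"] = n_pass / n
    return stats
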