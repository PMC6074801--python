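"""Three-way comparison of paired RNA-seq and WES call sets.

Every variant of a tumor is classified by which platform(s) called it:
``RNA_ONLY``, ``INTERSECTION`` or ``WES_ONLY``.  By default the
comparison is restricted to PASS calls (the accepted-as-somatic sets);
``pass_only=False`` compares everything (the "ALL" view).
"""

from __future__ import annotations

from collections import Counter
from typing import Callable, Dict, Iterable, Mapping, Optional, Sequence

from .model import ComparisonClass, VariantCall, VariantKey

__all__ = [
    "classify_three_way",
    "class_counts",
    "overlap_fraction",
    "cohort_average",
]


def _check_same_sample(rna_calls: Sequence[VariantCall], wes_calls: Sequence[VariantCall]) -> None:
    samples = {c.sample_id for c in rna_calls} | {c.sample_id for c in wes_calls}
    if len(samples) > 1:
        raise ValueError(f"call sets mix samples: {sorted(samples)}")


def classify_three_way(
    rna_calls: Sequence[VariantCall],
    wes_calls: Sequence[VariantCall],
    pass_only: bool = True,
) -> Dict[VariantKey, ComparisonClass]:
    """Classify every variant key of one tumor by platform support.

    Keys present in both call sets are ``INTERSECTION``; keys in a single
    set are ``RNA_ONLY`` / ``WES_ONLY``.  With ``pass_only`` (the
    default) both inputs are first restricted to calls whose decision is
    exactly ``{PASS}``.  Both call sets must come from the same tumor.
    """
    _check_same_sample(rna_calls, wes_calls)
    if pass_only:
        rna_calls = [c for c in rna_calls if c.is_pass]
        wes_calls = [c for c in wes_calls if c.is_pass]
    rna_keys = {c.key for c in rna_calls}
    wes_keys = {c.key for c in wes_calls}
    classes: Dict[VariantKey, ComparisonClass] = {}
    for key in rna_keys | wes_keys:
        if key in rna_keys and key in wes_keys:
            classes[key] = ComparisonClass.INTERSECTION
        elif key in rna_keys:
            classes[key] = ComparisonClass.RNA_ONLY
        else:
            classes[key] = ComparisonClass.WES_ONLY
    return classes


def class_counts(classes: Mapping[VariantKey, ComparisonClass]) -> Dict[ComparisonClass, int]:
    """Counts per comparison class (zero-filled for absent classes)."""
    counts = Counter(classes.values())
    return {cls: counts.get(cls, 0) for cls in ComparisonClass}


def overlap_fraction(
    reference_calls: Sequence[VariantCall],
    query_calls: Sequence[VariantCall],
    subset_predicate: Optional[Callable[[VariantCall], bool]] = None,
) -> Optional[float]:
    """Fraction of (predicate-selected) reference variants also present in
    the query call set.

    Computed on normalized keys:
    ``|{k in ref ∩ query : pred}| / |{k in ref : pred}|``.  Returns
    ``None`` (undefined, not 0) when the predicate selects no reference
    variant.  The predicate is evaluated on reference calls.
    """
    if subset_predicate is None:
        subset_predicate = lambda call: True  # noqa: E731
    reference_keys = {c.key for c in reference_calls if subset_predicate(c)}
    if not reference_keys:
        return None
    query_keys = {c.key for c in query_calls}
    return len(reference_keys & query_keys) / len(reference_keys)


def cohort_average(per_sample_values: Iterable[Optional[float]]) -> Optional[float]:
    """Unweighted mean over samples, ignoring undefined (None) entries.

    Cohort-level proportions are reported as the average of per-sample
    proportions (not pooled counts), matching how the reference cohort
    statistics are averaged over nine tumors.
    """
    values = [v for v in per_sample_values if v is not None]
    if not values:
        return None
    return sum(values) / len(values)
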