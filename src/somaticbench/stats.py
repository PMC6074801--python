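"""Cohort-level statistics on call sets.

Substitution spectrum (the 12 ordered ref>alt SNV types, kept
strand-specific because RNA editing shows up asymmetrically as A>G/T>C),
allele-fraction/coverage stratification, per-chromosome distribution, and
the closed-form binomial detectability of a variant given its allele
fraction and the other platform's coverage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import Region, VariantCall

__all__ = [
    "SUBSTITUTION_TYPES",
    "SpectrumProfile",
    "mutation_spectrum",
    "AFStrata",
    "af_coverage_strata",
    "detection_probability",
    "chromosome_distribution",
]

#: The 12 base substitutions in fixed display order.
SUBSTITUTION_TYPES = (
    "A>C", "A>G", "A>T", "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T", "T>A", "T>C", "T>G",
)


@dataclass
class SpectrumProfile:
    """Proportions of the 12 substitution types over the SNVs of a call
    set.  Indels are excluded; proportions sum to 1."""

    proportions: Dict[str, float]
    n_snvs: int = 0

    def __getitem__(self, substitution: str) -> float:
        return self.proportions[substitution]

    def transition_mass(self, types: Sequence[str] = ("A>G", "T>C")) -> float:
        return sum(self.proportions[t] for t in types)

    def to_series(self) -> pd.Series:
        return pd.Series(self.proportions, name="proportion")


def mutation_spectrum(
    calls: Sequence[VariantCall],
    pass_only: bool = True,
) -> SpectrumProfile:
    """Normalized multinomial over ref>alt substitution types.

    Computed on SNVs as recorded — no strand collapsing, so A>G and T>C
    are distinct classes (RNA editing enriches both in RNA-seq call
    sets).  By default restricted to PASS calls; raises when no SNV is
    available.
    """
    counts: Counter = Counter()
    for call in calls:
        if pass_only and not call.is_pass:
            continue
        if call.is_indel or len(call.ref_allele) != 1:
            continue
        subst = f"{call.ref_allele}>{call.alt_allele}"
        if subst in _VALID:
            counts[subst] += 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError("mutation_spectrum requires at least one SNV")
    return SpectrumProfile(
        proportions={t: counts.get(t, 0) / n for t in SUBSTITUTION_TYPES},
        n_snvs=n,
    )


_VALID = frozenset(SUBSTITUTION_TYPES)


@dataclass
class AFStrata:
    """Allele-fraction stratification of a class of variants.

    ``fractions`` gives the mass below/above the outer AF bounds plus the
    middle stratum (bounds are strict: a value exactly at a bound falls
    into the middle stratum) and, separately, the fraction above the
    median bound.  ``high_cov_low_af`` reports the joint
    (AF < low bound, coverage > high coverage bound) cell — the
    high-coverage/low-AF region most likely to hide somatic mutations
    that the other platform misses.  ``joint`` is a tidy count table over
    (AF stratum x coverage stratum x region) when regions are supplied.
    """

    bounds: Tuple[float, float, float]
    cov_bounds: Tuple[int, ...]
    n: int
    fractions: Dict[str, float]
    high_cov_low_af: Dict[str, float]
    joint: Optional[pd.DataFrame] = None


def af_coverage_strata(
    calls: Sequence[VariantCall],
    af_bounds: Tuple[float, float, float] = (0.05, 0.50, 0.95),
    cov_bounds: Tuple[int, ...] = (100, 500),
    regions: Optional[Sequence[Region]] = None,
) -> AFStrata:
    """Stratify calls by allele fraction and coverage.

    ``af_bounds`` are the (low, median, high) cut points; all
    comparisons are strict, so the reported strata are AF < low,
    AF > high, the inclusive middle band, and AF > median as a separate
    overlapping fraction.  When ``regions`` is given (aligned with
    ``calls``) a joint (AF stratum x coverage stratum x region) count
    table is included.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("af_coverage_strata requires at least one call")
    low, mid, high = af_bounds
    af = np.array([c.allele_fraction for c in calls], dtype=float)
    depth = np.array([c.depth for c in calls], dtype=float)
    n = len(calls)
    below = af < low
    above = af > high
    middle = ~below & ~above
    fractions = {
        f"af_lt_{low}": below.mean(),
        f"af_mid": middle.mean(),
        f"af_gt_{high}": above.mean(),
        f"af_gt_{mid}": (af > mid).mean(),
    }
    high_cov = depth > cov_bounds[-1]
    joint_mask = below & high_cov
    fractions = {k: float(v) for k, v in fractions.items()}
    high_cov_low_af = {
        "count": int(joint_mask.sum()),
        "fraction_of_all": float(joint_mask.mean()),
        "fraction_of_low_af": float(joint_mask.sum() / below.sum())
        if below.any()
        else float("nan"),
    }
    joint = None
    if regions is not None:
        if len(regions) != n:
            raise ValueError("regions must align with calls")
        af_stratum = np.where(below, f"af_lt_{low}", np.where(above, f"af_gt_{high}", "af_mid"))
        edges = [-np.inf, *cov_bounds, np.inf]
        labels = [f"cov_le_{cov_bounds[0]}"] + [
            f"cov_{cov_bounds[i]}_to_{cov_bounds[i+1]}" for i in range(len(cov_bounds) - 1)
        ] + [f"cov_gt_{cov_bounds[-1]}"]
        cov_stratum = pd.cut(depth, bins=edges, labels=labels)
        joint = (
            pd.DataFrame(
                {
                    "af_stratum": af_stratum,
                    "cov_stratum": cov_stratum,
                    "region": [r.value for r in regions],
                }
            )
            .value_counts()
            .rename("count")
            .reset_index()
        )
    return AFStrata(
        bounds=af_bounds,
        cov_bounds=tuple(cov_bounds),
        n=n,
        fractions=fractions,
        high_cov_low_af=high_cov_low_af,
        joint=joint,
    )


def detection_probability(af: float, coverage: int) -> float:
    """Probability of seeing at least one variant read.

    For a variant at allele fraction ``af`` sampled by ``coverage``
    independent reads, the number of variant reads is
    Binomial(coverage, af), so
    ``P(>=1 read) = 1 - (1 - af)^coverage``.  Nondecreasing in both
    arguments.
    """
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele fraction {af} outside [0, 1]")
    if coverage < 0:
        raise ValueError("coverage must be non-negative")
    return 1.0 - (1.0 - af) ** coverage


def chromosome_distribution(calls: Sequence[VariantCall]) -> Dict[str, float]:
    """Proportion of calls per contig (sums to 1 over observed contigs)."""
    calls = list(calls)
    if not calls:
        raise ValueError("chromosome_distribution requires at least one call")
    counts = Counter(call.key.contig for call in calls)
    n = len(calls)
    return {contig: count / n for contig, count in sorted(counts.items())}
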