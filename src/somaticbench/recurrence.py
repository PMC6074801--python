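"""Gene x sample recurrence of coding variants.

Builds the mutation-count matrix behind recurrence heatmaps (rows =
genes, columns = tumors), selects genes altered in a minimum number of
tumors, and produces a deterministic agglomerative clustering order for
reporting.  Rendering is out of scope: the outputs are a count matrix and
two label permutations.

Clustering convention: average-linkage agglomeration on Euclidean
distances between count vectors, with all ties broken lexicographically
by cluster label so that a given matrix always yields the same order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import AnnotatedVariant, ComparisonClass, Region

__all__ = [
    "RecurrenceMatrix",
    "build_matrix",
    "recurrent_genes",
    "cluster_order",
    "average_linkage_order",
]


@dataclass
class RecurrenceMatrix:
    """Integer matrix of variant counts per gene (rows) and sample
    (columns)."""

    genes: List[str]
    samples: List[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match gene/sample labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)


def build_matrix(
    variants: Iterable[AnnotatedVariant],
    class_filter: Optional[ComparisonClass] = ComparisonClass.RNA_ONLY,
    region_filter: Optional[frozenset] = frozenset({Region.EXONIC}),
) -> RecurrenceMatrix:
    """Count retained variants per gene per sample.

    Defaults count RNA-only variants in coding regions, the selection
    behind "genes mutated in RNA-seq only" recurrence analysis.  Pass
    ``None`` for either filter to disable it.  Variants without a gene
    assignment are skipped.  An empty selection yields a 0x0 matrix.
    """
    tally: Dict[Tuple[str, str], int] = {}
    for variant in variants:
        if class_filter is not None and variant.comparison_class is not class_filter:
            continue
        if region_filter is not None and variant.region not in region_filter:
            continue
        if variant.gene is None:
            continue
        key = (variant.gene, variant.call.sample_id)
        tally[key] = tally.get(key, 0) + 1
    if not tally:
        return RecurrenceMatrix(genes=[], samples=[], counts=np.zeros((0, 0), dtype=int))
    genes = sorted({g for g, _ in tally})
    samples = sorted({s for _, s in tally})
    counts = np.zeros((len(genes), len(samples)), dtype=int)
    gene_idx = {g: i for i, g in enumerate(genes)}
    sample_idx = {s: j for j, s in enumerate(samples)}
    for (gene, sample), count in tally.items():
        counts[gene_idx[gene], sample_idx[sample]] = count
    return RecurrenceMatrix(genes=genes, samples=samples, counts=counts)


def recurrent_genes(matrix: RecurrenceMatrix, min_samples: int = 5) -> List[str]:
    """Genes with variants in at least ``min_samples`` distinct samples.

    Sorted by (number of mutated samples desc, total count desc, name
    asc).  Monotone: raising ``min_samples`` never adds genes.
    """
    if min_samples > len(matrix.samples):
        return []
    mutated = (matrix.counts > 0).sum(axis=1)
    totals = matrix.counts.sum(axis=1)
    selected = [
        (int(-mutated[i]), int(-totals[i]), gene)
        for i, gene in enumerate(matrix.genes)
        if mutated[i] >= min_samples
    ]
    return [gene for _, _, gene in sorted(selected)]


def average_linkage_order(vectors: np.ndarray, labels: Sequence[str]) -> List[str]:
    """Deterministic average-linkage leaf order over row vectors.

    Naive O(n^3) agglomeration on Euclidean distances.  At each step the
    pair of clusters with the smallest average pairwise distance merges;
    distance ties break on the lexicographically smallest (label of
    first member) pair, and within a merge the cluster whose first label
    is smaller keeps the left position.  Returns labels in leaf order.
    """
    n = len(labels)
    if n == 0:
        return []
    if n == 1:
        return [labels[0]]
    vectors = np.asarray(vectors, dtype=float)
    # pairwise distances between original elements
    diff = vectors[:, None, :] - vectors[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    clusters: List[List[int]] = [[i] for i in range(n)]

    def cluster_label(cluster: List[int]) -> str:
        return min(labels[i] for i in cluster)

    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            avg = dist[np.ix_(clusters[a], clusters[b])].mean()
            tie = tuple(sorted((cluster_label(clusters[a]), cluster_label(clusters[b]))))
            candidate = (avg, tie, a, b)
            if best is None or candidate[:2] < best[:2]:
                best = candidate
        _, _, a, b = best
        left, right = clusters[a], clusters[b]
        if cluster_label(right) < cluster_label(left):
            left, right = right, left
        merged = left + right
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return [labels[i] for i in clusters[0]]


def cluster_order(matrix: RecurrenceMatrix) -> Tuple[List[str], List[str]]:
    """Deterministic (row order, column order) for heatmap reporting.

    Rows (genes) are clustered on their count vectors across samples,
    columns (samples) on their vectors across genes, both by
    :func:`average_linkage_order`.  Output is a permutation of the input
    labels; a single row or column yields the identity order.
    """
    if not matrix.genes or not matrix.samples:
        return (list(matrix.genes), list(matrix.samples))
    row_order = average_linkage_order(matrix.counts, matrix.genes)
    col_order = average_linkage_order(matrix.counts.T, matrix.samples)
    return (row_order, col_order)
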