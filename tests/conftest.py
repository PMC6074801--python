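"""Shared fixtures: small synthetic cohorts and a toy gene model.

Everything is generated programmatically — no stored fixture files.
"""

from __future__ import annotations

import pytest

from somaticbench.annotate import TranscriptModel
from somaticbench.simulate import GeneratorConfig, preset, simulate_cohort


def small_config(seed: int = 3) -> GeneratorConfig:
    """A scaled-down default cohort for fast structural tests."""
    config = preset("tcga-gbm-default", seed=seed)
    config.n_samples = 2
    config.class_counts = {"RNA_ONLY": 150, "INTERSECTION": 30, "WES_ONLY": 90}
    config.filler_counts = {"tlod_fail_rna": 30, "tlod_fail_wes": 15,
                            "germline": 20, "pon_rna": 8, "pon_wes": 8}
    config.pon_n_sites = 60
    config.normal_private_calls = 20
    config.n_normals = 6
    config.dbsnp_background = 300
    config.cosmic_background = 120
    config.genome.n_contigs = 4
    config.genome.contig_length = 120_000
    return config


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture()
def toy_gene() -> TranscriptModel:
    """Single-exon plus-strand micro gene: CDS codes M-A-K-stop.

    Sequence layout (1-based): 1-4 upstream UTR bases, 5-16 CDS
    (ATG GCA AAA TAA), 17-20 downstream UTR bases.
    """
    return TranscriptModel(
        gene="TOY1",
        contig="chr1",
        strand="+",
        exons=[(1, 20)],
        cds=[(5, 16)],
        sequence="TTTTATGGCAAAATAATTTT",
    )
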