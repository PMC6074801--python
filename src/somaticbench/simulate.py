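"""Synthetic paired RNA-seq/WES tumor cohorts with ground truth.

The generator emulates the *statistical structure* of a paired
tumor-cohort comparison without any read-level simulation: per tumor it
emits an RNA-seq call set and a WES call set over a toy genome with toy
transcript models, plus normal-sample call sets for panel-of-normals
construction, COSMIC-like and dbSNP-like key sets, a functional-score
sidecar and a complete truth table.

Structure emulated by the default cohort preset:

* a bimodal RNA-only allele-fraction distribution (a large AF > 0.95
  spike of low-coverage intronic/intergenic calls and a large AF < 0.05
  spike of high-coverage coding calls), against a unimodal WES-only AF
  distribution;
* platform overlap that grows with variant significance (all PASS <
  coding < protein-altering);
* class-dependent database membership (intersection coding variants
  overwhelmingly COSMIC-only);
* an RNA-editing-skewed substitution spectrum (A>G/T>C boosted in
  RNA-only calls);
* non-PASS "filler" calls that exercise each emulated caller filter.

Cohort-level masses (class sizes, AF strata, region mix, membership) are
realized by stratified largest-remainder allocation within each sample,
with randomness only in the within-stratum values, positions and
spectra: the generator's job is to realize its configured fractions at
finite n, so allocation noise is deliberately excluded.  Read counts are
drawn inside the intended AF stratum's integer range (depth clamped to
at least 21 so every stratum is realizable), which keeps the recomputed
AF = alt/depth inside the intended stratum.

A single seeded pseudo-random stream drives everything; the same
configuration and seed reproduce the cohort byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .annotate import TranscriptIndex, TranscriptModel, annotate_coding_effect, write_gff3
from .filters import CallingMode, PanelOfNormals, build_pon
from .model import (
    Platform,
    Region,
    ScorePair,
    VariantCall,
    VariantKey,
    write_score_sidecar,
    write_sites_vcf,
    write_vcf,
)
from .stats import SUBSTITUTION_TYPES

__all__ = [
    "GenomeConfig",
    "GeneratorConfig",
    "preset",
    "PRESET_NAMES",
    "SyntheticCohort",
    "simulate_cohort",
]

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = {"TAA", "TAG", "TGA"}

_REGION_CODES = {
    Region.INTERGENIC.value: 0,
    Region.INTRONIC.value: 1,
    Region.SPLICING.value: 2,
    Region.UTR.value: 3,
    Region.EXONIC.value: 4,
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class GenomeConfig:
    """Toy genome layout: identical tiled genes on a few small contigs."""

    n_contigs: int = 10
    contig_length: int = 200_000
    genes_per_contig: int = 8
    exons_per_gene: int = 6
    exon_length: int = 300
    intron_length: int = 900
    utr_length: int = 150
    first_gene_start: int = 5_000
    gene_spacing: int = 10_000


def _default_class_counts() -> Dict[str, int]:
    return {"RNA_ONLY": 3200, "INTERSECTION": 141, "WES_ONLY": 1995}


def _default_af_weights() -> Dict[str, Tuple[float, float, float]]:
    # (low, mid, high) stratum weights: AF < 0.05 / middle / AF > 0.95
    return {
        "RNA_ONLY": (0.363, 0.255, 0.382),
        "WES_ONLY": (0.228, 0.767, 0.005),
        "INTERSECTION:RNA": (0.08, 0.87, 0.05),
        "INTERSECTION:WES": (0.05, 0.93, 0.02),
        "GERMLINE": (0.0, 0.70, 0.30),
        "ARTIFACT": (0.10, 0.85, 0.05),
    }


def _default_af_shapes() -> Dict[str, Tuple[float, float]]:
    return {"low": (1.2, 40.0), "mid": (2.0, 3.0), "high": (40.0, 1.0)}


def _default_region_mix() -> Dict[str, Dict[str, float]]:
    return {
        "RNA_ONLY:low": {
            "exonic": 0.811, "UTR": 0.05, "splicing": 0.009,
            "intronic": 0.08, "intergenic": 0.05,
        },
        "RNA_ONLY:mid": {
            "exonic": 0.35, "UTR": 0.08, "splicing": 0.02,
            "intronic": 0.35, "intergenic": 0.20,
        },
        "RNA_ONLY:high": {
            "exonic": 0.10, "UTR": 0.03, "splicing": 0.014,
            "intronic": 0.476, "intergenic": 0.38,
        },
        "INTERSECTION": {
            "exonic": 0.897, "UTR": 0.03, "splicing": 0.01,
            "intronic": 0.04, "intergenic": 0.023,
        },
        "WES_ONLY": {
            "exonic": 0.50, "UTR": 0.04, "splicing": 0.01,
            "intronic": 0.30, "intergenic": 0.15,
        },
        "GERMLINE": {
            "exonic": 0.55, "UTR": 0.05, "splicing": 0.01,
            "intronic": 0.24, "intergenic": 0.15,
        },
        "ARTIFACT:RNA": {
            "exonic": 0.30, "UTR": 0.06, "splicing": 0.02,
            "intronic": 0.37, "intergenic": 0.25,
        },
        "ARTIFACT:WES": {
            "exonic": 0.45, "UTR": 0.05, "splicing": 0.01,
            "intronic": 0.29, "intergenic": 0.20,
        },
    }


def _default_membership() -> Dict[str, Tuple[float, float, float, float]]:
    # (COSMIC_only, dbSNP_only, both, neither)
    return {
        "INTERSECTION:coding": (0.877, 0.043, 0.02, 0.06),
        "RNA_ONLY:coding": (0.030, 0.004, 0.002, 0.964),
        "WES_ONLY:coding": (0.395, 0.18, 0.025, 0.40),
        "INTERSECTION:noncoding": (0.05, 0.12, 0.005, 0.825),
        "RNA_ONLY:noncoding": (0.005, 0.06, 0.001, 0.934),
        "WES_ONLY:noncoding": (0.02, 0.15, 0.004, 0.826),
    }


def _default_coverage() -> Dict[str, Tuple[float, float]]:
    # (mean, dispersion r) of a negative binomial, clamped at min_depth
    return {
        "wes": (150.0, 8.0),
        "rna_coding": (300.0, 1.5),
        "rna_coding_lowaf": (1000.0, 1.2),  # ~half the low-AF spike above 500x
        "rna_noncoding": (40.0, 3.0),
        "normal": (60.0, 5.0),
    }


def _default_spectrum() -> Dict[str, Dict[str, float]]:
    wes = {
        "A>C": 0.05, "A>G": 0.06, "A>T": 0.05, "C>A": 0.08, "C>G": 0.05,
        "C>T": 0.21, "G>A": 0.21, "G>C": 0.05, "G>T": 0.08, "T>A": 0.05,
        "T>C": 0.06, "T>G": 0.05,
    }
    rna = {
        "A>C": 0.04, "A>G": 0.21, "A>T": 0.04, "C>A": 0.04, "C>G": 0.04,
        "C>T": 0.13, "G>A": 0.13, "G>C": 0.04, "G>T": 0.04, "T>A": 0.04,
        "T>C": 0.21, "T>G": 0.04,
    }
    return {"RNA": rna, "WES": wes}


def _default_indel_fraction() -> Dict[str, float]:
    return {"RNA_ONLY": 0.06, "INTERSECTION": 0.04, "WES_ONLY": 0.05,
            "GERMLINE": 0.03, "ARTIFACT": 0.08}


def _default_filler_counts() -> Dict[str, int]:
    return {"tlod_fail_rna": 600, "tlod_fail_wes": 300,
            "germline": 200, "pon_rna": 80, "pon_wes": 80}


@dataclass
class GeneratorConfig:
    """Full parameterization of a synthetic paired cohort.

    ``class_counts`` are the intended per-sample numbers of PASS variants
    by comparison class; ``filler_counts`` add non-PASS calls that
    exercise each emulated caller filter.  ``af_weights`` give the
    (AF < 0.05, middle, AF > 0.95) stratum masses per class (per platform
    side for intersection variants); ``af_shapes`` the Beta shapes used
    within each stratum.  ``region_mix`` distributes variants over
    genomic regions (conditioned on the AF stratum for RNA-only calls,
    which couples the AF > 0.95 spike to intronic/intergenic positions
    and the AF < 0.05 spike to coding ones).  ``membership`` gives the
    four-way COSMIC/dbSNP class per (comparison class, coding) group.
    The seed fully determines the output.
    """

    name: str = "custom"
    seed: int = 0
    n_samples: int = 9
    mode: str = "TUMOR_NORMAL"
    n_normals: int = 12
    class_counts: Dict[str, int] = field(default_factory=_default_class_counts)
    filler_counts: Dict[str, int] = field(default_factory=_default_filler_counts)
    af_weights: Dict[str, Tuple[float, float, float]] = field(default_factory=_default_af_weights)
    af_shapes: Dict[str, Tuple[float, float]] = field(default_factory=_default_af_shapes)
    region_mix: Dict[str, Dict[str, float]] = field(default_factory=_default_region_mix)
    membership: Dict[str, Tuple[float, float, float, float]] = field(default_factory=_default_membership)
    coverage: Dict[str, Tuple[float, float]] = field(default_factory=_default_coverage)
    min_depth: int = 21
    spectrum: Dict[str, Dict[str, float]] = field(default_factory=_default_spectrum)
    indel_fraction: Dict[str, float] = field(default_factory=_default_indel_fraction)
    indel_lengths: Tuple[int, ...] = (1, 1, 1, 2, 3, 21)
    indel_length_weights: Tuple[float, ...] = (0.45, 0.2, 0.15, 0.1, 0.08, 0.02)
    tlod_slope: float = 0.4
    tlod_noise: float = 2.0
    nlod_pass_floor: float = 5.51
    nlod_pass_scale: float = 3.0
    germline_dbsnp_prob: float = 0.85
    passthrough_label_prob: float = 0.10
    pon_n_sites: int = 300
    normal_private_calls: int = 150
    dbsnp_background: int = 4000
    cosmic_background: int = 1500
    cosmic_dbsnp_overlap: float = 0.0015
    contig_weights: Optional[List[float]] = None
    genome: GenomeConfig = field(default_factory=GenomeConfig)

    def __post_init__(self) -> None:
        if isinstance(self.genome, dict):
            self.genome = GenomeConfig(**self.genome)
        for key, weights in self.af_weights.items():
            if not np.isclose(sum(weights), 1.0):
                raise ValueError(f"af_weights[{key}] do not sum to 1")
        for key, mix in self.region_mix.items():
            if not np.isclose(sum(mix.values()), 1.0):
                raise ValueError(f"region_mix[{key}] does not sum to 1")
        for key, probs in self.membership.items():
            if not np.isclose(sum(probs), 1.0):
                raise ValueError(f"membership[{key}] does not sum to 1")
        for platform, spec in self.spectrum.items():
            if set(spec) != set(SUBSTITUTION_TYPES):
                raise ValueError(f"spectrum[{platform}] must cover the 12 types")
            if not np.isclose(sum(spec.values()), 1.0):
                raise ValueError(f"spectrum[{platform}] does not sum to 1")
        if any(n < 0 for n in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")
        if any(n < 0 for n in self.filler_counts.values()):
            raise ValueError("filler counts must be non-negative")
        if self.mode not in {m.value for m in CallingMode}:
            raise ValueError(f"unknown calling mode {self.mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        return cls(**data)


PRESET_NAMES = ("tcga-gbm-default", "uniform-null", "sd01-like")


def preset(name: str, seed: int = 0) -> GeneratorConfig:
    """A named generator configuration.

    * ``tcga-gbm-default`` — nine tumor-normal pairs with the full
      reported class structure: RNA-only AF spikes (38.2% above 0.95,
      36.3% below 0.05 versus 0.50%/22.8% for WES-only), 87.7%
      COSMIC-only among intersection coding variants, and a 6.60%
      WES-PASS-in-RNA overlap rising with variant significance.
    * ``uniform-null`` — no class structure at all: equal class sizes,
      one flat AF/region/membership configuration for every class and a
      uniform substitution spectrum; for false-positive checks of the
      downstream statistics.
    * ``sd01-like`` — a single tumor-only pair (no NLOD): elevated
      germline content passing the caller, chromosome-7 excess and a
      transition-heavy spectrum.
    """
    if name == "tcga-gbm-default":
        return GeneratorConfig(name=name, seed=seed)
    if name == "uniform-null":
        uniform_spec = {t: 1.0 / 12.0 for t in SUBSTITUTION_TYPES}
        flat_region = {
            "exonic": 0.2, "UTR": 0.2, "splicing": 0.2,
            "intronic": 0.2, "intergenic": 0.2,
        }
        flat_af = (0.05, 0.90, 0.05)
        flat_membership = (0.05, 0.15, 0.01, 0.79)
        return GeneratorConfig(
            name=name,
            seed=seed,
            n_samples=6,
            class_counts={"RNA_ONLY": 400, "INTERSECTION": 400, "WES_ONLY": 400},
            filler_counts={"tlod_fail_rna": 50, "tlod_fail_wes": 50,
                           "germline": 50, "pon_rna": 20, "pon_wes": 20},
            af_weights={
                "RNA_ONLY": flat_af, "WES_ONLY": flat_af,
                "INTERSECTION:RNA": flat_af, "INTERSECTION:WES": flat_af,
                "GERMLINE": flat_af, "ARTIFACT": flat_af,
            },
            af_shapes={"low": (1.0, 1.0), "mid": (1.0, 1.0), "high": (1.0, 1.0)},
            region_mix={
                "RNA_ONLY:low": flat_region, "RNA_ONLY:mid": flat_region,
                "RNA_ONLY:high": flat_region, "INTERSECTION": flat_region,
                "WES_ONLY": flat_region, "GERMLINE": flat_region,
                "ARTIFACT:RNA": flat_region, "ARTIFACT:WES": flat_region,
            },
            membership={k: flat_membership for k in _default_membership()},
            spectrum={"RNA": uniform_spec, "WES": dict(uniform_spec)},
        )
    if name == "sd01-like":
        spec = {
            "A>C": 0.04, "A>G": 0.17, "A>T": 0.04, "C>A": 0.04, "C>G": 0.04,
            "C>T": 0.17, "G>A": 0.17, "G>C": 0.04, "G>T": 0.04, "T>A": 0.04,
            "T>C": 0.17, "T>G": 0.04,
        }
        # shift mass toward dbSNP membership (germline-rich tumor-only calls)
        membership = {
            key: (0.6 * c, d + 0.3 * n, b, 0.4 * c + 0.7 * n)
            for key, (c, d, b, n) in _default_membership().items()
        }
        weights = [1.0] * 10
        weights[6] = 4.0  # chromosome 7 excess
        return GeneratorConfig(
            name=name,
            seed=seed,
            n_samples=1,
            mode="TUMOR_ONLY",
            class_counts={"RNA_ONLY": 4000, "INTERSECTION": 400, "WES_ONLY": 3000},
            filler_counts={"tlod_fail_rna": 800, "tlod_fail_wes": 400,
                           "germline": 1200, "pon_rna": 100, "pon_wes": 100},
            germline_dbsnp_prob=0.9,
            spectrum={"RNA": spec, "WES": dict(spec)},
            membership=membership,
            contig_weights=weights,
        )
    raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")


# ---------------------------------------------------------------------------
# Genome and position pools
# ---------------------------------------------------------------------------


def _build_genome(
    config: GenomeConfig, rng: np.random.Generator
) -> Tuple[Dict[str, str], List[TranscriptModel]]:
    """Random toy genome plus tiled transcript models.

    Start codons are stamped onto the CDS 5' ends, a stop codon onto the
    3' ends, and internal in-frame stops scrubbed, so every model
    validates and translates cleanly.  Strands alternate.
    """
    contigs = [f"chr{i + 1}" for i in range(config.n_contigs)]
    genome: Dict[str, List[str]] = {}
    gene_specs: List[tuple] = []
    gene_counter = 0
    for contig in contigs:
        seq = rng.choice(list(_BASES), size=config.contig_length).tolist()
        genome[contig] = seq
        gene_span = (
            config.exons_per_gene * config.exon_length
            + (config.exons_per_gene - 1) * config.intron_length
        )
        for g in range(config.genes_per_contig):
            start = config.first_gene_start + g * (gene_span + config.gene_spacing)
            if start + gene_span > config.contig_length:
                break
            gene_counter += 1
            strand = "+" if gene_counter % 2 else "-"
            exons = []
            for e in range(config.exons_per_gene):
                es = start + e * (config.exon_length + config.intron_length)
                exons.append((es, es + config.exon_length - 1))
            cds = [list(iv) for iv in exons]
            cds[0][0] += config.utr_length
            cds[-1][1] -= config.utr_length
            cds = [tuple(iv) for iv in cds]
            _stamp_cds(seq, cds, strand)
            gene_specs.append((f"GENE{gene_counter:03d}", contig, strand, exons, cds))
    genome_str = {contig: "".join(seq) for contig, seq in genome.items()}
    models = [
        TranscriptModel(
            gene=gene, contig=contig, strand=strand, exons=exons, cds=cds,
            sequence=genome_str[contig],
        )
        for gene, contig, strand, exons, cds in gene_specs
    ]
    return genome_str, models


def _stamp_cds(seq: List[str], cds: Sequence[Tuple[int, int]], strand: str) -> None:
    positions: List[int] = []
    for s, e in cds:
        positions.extend(range(s, e + 1))  # 1-based genomic order
    if strand == "-":
        positions = positions[::-1]

    def write(cds_index: int, base: str) -> None:
        pos = positions[cds_index]
        seq[pos - 1] = base if strand == "+" else _COMPLEMENT[base]

    def read(cds_index: int) -> str:
        pos = positions[cds_index]
        base = seq[pos - 1]
        return base if strand == "+" else _COMPLEMENT[base]

    for i, base in enumerate("ATG"):
        write(i, base)
    n = len(positions)
    for i, base in enumerate("TAA"):
        write(n - 3 + i, base)
    # scrub internal in-frame stop codons
    for codon_start in range(3, n - 3, 3):
        codon = read(codon_start) + read(codon_start + 1) + read(codon_start + 2)
        if codon in _STOPS:
            write(codon_start + 2, "C")


class _PositionPools:
    """Per-(contig, region, base) arrays of candidate positions."""

    def __init__(self, genome: Dict[str, str], models: Sequence[TranscriptModel],
                 splice_window: int = 2):
        self.contigs = list(genome)
        self.pools: Dict[Tuple[str, int, str], np.ndarray] = {}
        for contig, seq in genome.items():
            codes = np.zeros(len(seq), dtype=np.int8)
            for model in models:
                if model.contig != contig:
                    continue
                span_s, span_e = model.span
                codes[span_s - 1 : span_e] = np.maximum(
                    codes[span_s - 1 : span_e], _REGION_CODES["intronic"]
                )
                w = splice_window
                for s, e in model.exons:
                    codes[max(s - 1 - w, 0) : s - 1] = np.maximum(
                        codes[max(s - 1 - w, 0) : s - 1], _REGION_CODES["splicing"]
                    )
                    codes[e : e + w] = np.maximum(codes[e : e + w], _REGION_CODES["splicing"])
                for s, e in model.exons:
                    codes[s - 1 : e] = np.maximum(codes[s - 1 : e], _REGION_CODES["UTR"])
                for s, e in model.cds:
                    codes[s - 1 : e] = np.maximum(codes[s - 1 : e], _REGION_CODES["exonic"])
            bases = np.frombuffer(seq.encode(), dtype="S1")
            for region_name, code in _REGION_CODES.items():
                mask = codes == code
                positions = np.flatnonzero(mask) + 1  # back to 1-based
                self.pools[(contig, code, "*")] = positions
                for base in _BASES:
                    base_mask = mask & (bases == base.encode())
                    self.pools[(contig, code, base)] = np.flatnonzero(base_mask) + 1

    def draw(
        self,
        contig: str,
        region: str,
        base: str,
        rng: np.random.Generator,
        excluded,
        max_tries: int = 200,
    ) -> int:
        pool = self.pools[(contig, _REGION_CODES[region], base)]
        if len(pool) == 0:
            raise ValueError(f"empty position pool for {contig}/{region}/{base}")
        for _ in range(max_tries):
            pos = int(pool[rng.integers(len(pool))])
            if (contig, pos) not in excluded:
                return pos
        # dense pools: fall back to an exact scan of unused positions
        available = [int(p) for p in pool if (contig, int(p)) not in excluded]
        if not available:
            raise ValueError(f"position pool exhausted for {contig}/{region}/{base}")
        return available[rng.integers(len(available))]


# ---------------------------------------------------------------------------
# Allocation helpers
# ---------------------------------------------------------------------------


def _allocate(n: int, weights: Sequence[float]) -> np.ndarray:
    """Largest-remainder integer allocation of n among weights."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * n
    counts = np.floor(raw).astype(int)
    shortfall = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:shortfall]] += 1
    return counts


def _spread(labels: Sequence[str], counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.repeat(np.asarray(labels, dtype=object), counts)
    rng.shuffle(out)
    return out


def _stratum_alt_range(stratum: str, depth: int) -> Tuple[int, int]:
    if stratum == "low":
        return 1, max(1, int(np.ceil(0.05 * depth)) - 1)
    if stratum == "high":
        return int(np.floor(0.95 * depth)) + 1, depth
    lo = max(1, int(np.ceil(0.05 * depth)))
    hi = max(lo, int(np.floor(0.95 * depth)))
    return lo, hi


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """Everything a benchmarking run needs, generated in memory.

    ``truth`` has one row per distinct variant event per sample (an
    intersection variant is one event emitted to both platforms).
    """

    config: GeneratorConfig
    samples: List[str]
    genome: Dict[str, str]
    models: List[TranscriptModel]
    rna_calls: Dict[str, List[VariantCall]]
    wes_calls: Dict[str, List[VariantCall]]
    normals: Dict[str, List[VariantCall]]
    cosmic_keys: set
    dbsnp_keys: set
    pon_sites: set
    scores: Dict[VariantKey, ScorePair]
    scores_frame: pd.DataFrame
    truth: pd.DataFrame

    def build_pon(self, min_samples: Optional[int] = None) -> PanelOfNormals:
        """Panel of normals compiled from the generated normal call sets."""
        if min_samples is None:
            min_samples = 2
        return build_pon(list(self.normals.values()), min_samples=min_samples)

    def write(self, out_dir: Union[str, Path]) -> dict:
        """Write the cohort as plain files; returns the manifest.

        Layout: per-sample VCFs under ``samples/``, normals under
        ``normals/``, sites-only database VCFs under ``databases/``,
        genome FASTA, transcript GFF3, score sidecar and truth TSVs, the
        serialized configuration and a ``manifest.json`` listing it all.
        """
        out = Path(out_dir)
        (out / "samples").mkdir(parents=True, exist_ok=True)
        (out / "normals").mkdir(exist_ok=True)
        (out / "databases").mkdir(exist_ok=True)
        contigs = sorted(self.genome, key=lambda c: int(c[3:]))
        manifest: dict = {
            "config": "config.json",
            "genome": "genome.fa",
            "transcripts": "transcripts.gff3",
            "scores": "scores.tsv",
            "truth": "truth.tsv",
            "mode": self.config.mode,
            "samples": {},
            "normals": {},
            "databases": {
                "cosmic": "databases/cosmic.vcf",
                "dbsnp": "databases/dbsnp.vcf",
            },
        }
        for sample in self.samples:
            rna = f"samples/{sample}.rna.vcf"
            wes = f"samples/{sample}.wes.vcf"
            write_vcf(self.rna_calls[sample], out / rna, sample_id=sample, contigs=contigs)
            write_vcf(self.wes_calls[sample], out / wes, sample_id=sample, contigs=contigs)
            manifest["samples"][sample] = {"rna": rna, "wes": wes}
        for normal_id, calls in self.normals.items():
            path = f"normals/{normal_id}.vcf"
            write_vcf(calls, out / path, sample_id=normal_id, contigs=contigs)
            manifest["normals"][normal_id] = path
        write_sites_vcf(self.cosmic_keys, out / "databases/cosmic.vcf")
        write_sites_vcf(self.dbsnp_keys, out / "databases/dbsnp.vcf")
        with open(out / "genome.fa", "w") as handle:
            for contig in contigs:
                handle.write(f">{contig}\n")
                seq = self.genome[contig]
                for i in range(0, len(seq), 80):
                    handle.write(seq[i : i + 80] + "\n")
        write_gff3(self.models, out / "transcripts.gff3")
        write_score_sidecar(self.scores_frame, out / "scores.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        (out / "config.json").write_text(json.dumps(self.config.to_dict(), indent=2))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


_CLASS_PLATFORMS = {
    "RNA_ONLY": ("RNA",),
    "INTERSECTION": ("RNA", "WES"),
    "WES_ONLY": ("WES",),
}
_MEMBERSHIP_LEVELS = ("COSMIC_only", "dbSNP_only", "both", "neither")


def simulate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full paired cohort from a configuration.

    Deterministic given ``config`` (including its seed): the same
    configuration produces byte-identical files through
    :meth:`SyntheticCohort.write`.
    """
    rng = np.random.default_rng(config.seed)
    genome, models = _build_genome(config.genome, rng)
    pools = _PositionPools(genome, models)
    index = TranscriptIndex(models)
    contigs = list(genome)
    contig_weights = np.asarray(
        config.contig_weights or [1.0] * len(contigs), dtype=float
    )
    contig_weights = contig_weights / contig_weights.sum()
    tumor_only = config.mode == CallingMode.TUMOR_ONLY.value

    # --- normals and panel-of-normals sites ------------------------------
    reserved: set = set()
    normals: Dict[str, List[VariantCall]] = {
        f"N{i + 1:02d}": [] for i in range(config.n_normals)
    }
    pon_site_list: List[Tuple[str, int, str, str]] = []
    normal_ids = list(normals)
    for _ in range(config.pon_n_sites):
        contig = contigs[rng.choice(len(contigs), p=contig_weights)]
        region = "intronic" if rng.random() < 0.5 else "intergenic"
        pos = pools.draw(contig, region, "*", rng, reserved)
        reserved.add((contig, pos))
        ref = genome[contig][pos - 1]
        alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
        pon_site_list.append((contig, pos, ref, alt))
        k = int(rng.choice([2, 3, 4], p=[0.6, 0.3, 0.1]))
        chosen = rng.choice(len(normal_ids), size=min(k, len(normal_ids)), replace=False)
        for idx in sorted(chosen):
            normals[normal_ids[idx]].append(
                _normal_call(normal_ids[idx], contig, pos, ref, alt, config, rng)
            )
    for normal_id in normal_ids:
        for _ in range(config.normal_private_calls):
            contig = contigs[rng.choice(len(contigs), p=contig_weights)]
            region = "intronic" if rng.random() < 0.5 else "intergenic"
            pos = pools.draw(contig, region, "*", rng, reserved)
            reserved.add((contig, pos))
            ref = genome[contig][pos - 1]
            alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
            normals[normal_id].append(
                _normal_call(normal_id, contig, pos, ref, alt, config, rng)
            )
    pon_sites = {
        VariantKey.make(contig, pos, ref, alt) for contig, pos, ref, alt in pon_site_list
    }

    # --- tumor samples ----------------------------------------------------
    samples = [f"T{i + 1:02d}" for i in range(config.n_samples)]
    rna_calls: Dict[str, List[VariantCall]] = {s: [] for s in samples}
    wes_calls: Dict[str, List[VariantCall]] = {s: [] for s in samples}
    truth_rows: List[dict] = []
    key_membership: Dict[VariantKey, Tuple[bool, bool]] = {}
    cohort_positions: set = set(reserved)
    score_events: List[dict] = []

    for sample in samples:
        events = _sample_events(config, sample, rng)
        # positions, alleles, calls; tumor event positions are unique
        # cohort-wide so database membership stays exact per event
        for event in events:
            if event["source"] == "pon":
                site = pon_site_list[event["pon_site"]]
                contig, pos, ref, alt = site
            else:
                contig = contigs[rng.choice(len(contigs), p=contig_weights)]
                if event["is_indel"]:
                    pos = pools.draw(contig, event["region"], "*", rng,
                                     cohort_positions)
                    ref, alt = _indel_alleles(genome[contig], pos, config, rng)
                else:
                    subst = event["subst"]
                    ref, alt = subst.split(">")
                    pos = pools.draw(contig, event["region"], ref, rng,
                                     cohort_positions)
                cohort_positions.add((contig, pos))
            event["contig"], event["position"] = contig, pos
            event["ref"], event["alt"] = ref, alt
            event["key"] = VariantKey.make(contig, pos, ref, alt)
            for platform in event["platforms"]:
                call = _tumor_call(event, platform, sample, config, rng, tumor_only)
                (rna_calls if platform == "RNA" else wes_calls)[sample].append(call)

        _assign_membership(events, config, rng, key_membership)

        for event in events:
            in_cosmic, in_dbsnp = key_membership.get(event["key"], (False, False))
            truth_rows.append(
                {
                    "sample_id": sample,
                    "contig": event["contig"],
                    "position": event["position"],
                    "ref": event["ref"],
                    "alt": event["alt"],
                    "comparison_class": event["class"],
                    "truth_class": event["truth"],
                    "region": event["region"],
                    "af_stratum": event["strata"].get("RNA")
                    or event["strata"].get("WES"),
                    "in_cosmic": in_cosmic,
                    "in_dbsnp": in_dbsnp,
                    "is_indel": event["is_indel"],
                    "source": event["source"],
                }
            )
            if event["source"] == "class" and event["region"] == "exonic":
                score_events.append(event)

    # --- database key sets ------------------------------------------------
    cosmic_keys = {k for k, (c, _) in key_membership.items() if c}
    dbsnp_keys = {k for k, (_, d) in key_membership.items() if d}
    _add_background_keys(
        config, rng, pools, genome, contigs, contig_weights,
        cohort_positions, cosmic_keys, dbsnp_keys,
    )

    # --- functional scores for coding class variants ----------------------
    scores, scores_frame = _draw_scores(score_events, key_membership, index, config, rng)

    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(
        config=config,
        samples=samples,
        genome=genome,
        models=models,
        rna_calls=rna_calls,
        wes_calls=wes_calls,
        normals=normals,
        cosmic_keys=cosmic_keys,
        dbsnp_keys=dbsnp_keys,
        pon_sites=pon_sites,
        scores=scores,
        scores_frame=scores_frame,
        truth=truth,
    )


def _sample_events(config: GeneratorConfig, sample: str, rng: np.random.Generator) -> List[dict]:
    """Stratified event plan for one tumor (class events plus fillers)."""
    events: List[dict] = []
    region_names = [r for r in _REGION_CODES]

    def region_labels(mix_key: str, n: int) -> np.ndarray:
        mix = config.region_mix[mix_key]
        weights = [mix.get(r, 0.0) for r in region_names]
        return _spread(region_names, _allocate(n, weights), rng)

    spectrum = {
        p: (list(SUBSTITUTION_TYPES),
            np.asarray([config.spectrum[p][t] for t in SUBSTITUTION_TYPES]))
        for p in ("RNA", "WES")
    }

    def substitutions(platform: str, n: int) -> np.ndarray:
        types, w = spectrum[platform]
        return rng.choice(types, size=n, p=w / w.sum())

    # ---- intended-PASS class events
    for cls_name in ("RNA_ONLY", "INTERSECTION", "WES_ONLY"):
        n = config.class_counts.get(cls_name, 0)
        if n == 0:
            continue
        platforms = _CLASS_PLATFORMS[cls_name]
        n_indel = _allocate(n, [config.indel_fraction[cls_name],
                                1 - config.indel_fraction[cls_name]])[0]
        indel_flags = _spread([True, False], np.array([n_indel, n - n_indel]), rng)
        strata = {}
        for platform in platforms:
            wkey = cls_name if len(platforms) == 1 else f"{cls_name}:{platform}"
            strata[platform] = _spread(
                ["low", "mid", "high"], _allocate(n, config.af_weights[wkey]), rng
            )
        if cls_name == "RNA_ONLY":
            regions = np.empty(n, dtype=object)
            for stratum in ("low", "mid", "high"):
                idx = np.flatnonzero(strata["RNA"] == stratum)
                regions[idx] = region_labels(f"RNA_ONLY:{stratum}", len(idx))
        else:
            regions = region_labels(cls_name, n)
        spectrum_platform = "RNA" if cls_name == "RNA_ONLY" else "WES"
        substs = substitutions(spectrum_platform, n)
        for i in range(n):
            events.append(
                {
                    "sample": sample,
                    "class": cls_name,
                    "truth": "somatic",
                    "source": "class",
                    "platforms": platforms,
                    "is_indel": bool(indel_flags[i]),
                    "strata": {p: strata[p][i] for p in platforms},
                    "region": regions[i],
                    "subst": substs[i],
                }
            )

    # ---- fillers: TLOD failures (artifacts)
    for platform, count_key, mix_key in (
        ("RNA", "tlod_fail_rna", "ARTIFACT:RNA"),
        ("WES", "tlod_fail_wes", "ARTIFACT:WES"),
    ):
        n = config.filler_counts.get(count_key, 0)
        if n == 0:
            continue
        regions = region_labels(mix_key, n)
        strata_labels = _spread(
            ["low", "mid", "high"], _allocate(n, config.af_weights["ARTIFACT"]), rng
        )
        n_indel = _allocate(n, [config.indel_fraction["ARTIFACT"],
                                1 - config.indel_fraction["ARTIFACT"]])[0]
        indel_flags = _spread([True, False], np.array([n_indel, n - n_indel]), rng)
        substs = substitutions(platform, n)
        for i in range(n):
            events.append(
                {
                    "sample": sample,
                    "class": None,
                    "truth": "artifact",
                    "source": "tlod_fail",
                    "platforms": (platform,),
                    "is_indel": bool(indel_flags[i]),
                    "strata": {platform: strata_labels[i]},
                    "region": regions[i],
                    "subst": substs[i],
                }
            )

    # ---- fillers: germline variants seen by both platforms
    n = config.filler_counts.get("germline", 0)
    if n:
        regions = region_labels("GERMLINE", n)
        strata_labels = _spread(
            ["low", "mid", "high"], _allocate(n, config.af_weights["GERMLINE"]), rng
        )
        n_indel = _allocate(n, [config.indel_fraction["GERMLINE"],
                                1 - config.indel_fraction["GERMLINE"]])[0]
        indel_flags = _spread([True, False], np.array([n_indel, n - n_indel]), rng)
        n_dbsnp = _allocate(n, [config.germline_dbsnp_prob,
                                1 - config.germline_dbsnp_prob])[0]
        dbsnp_flags = _spread([True, False], np.array([n_dbsnp, n - n_dbsnp]), rng)
        substs = substitutions("WES", n)
        for i in range(n):
            events.append(
                {
                    "sample": sample,
                    "class": None,
                    "truth": "germline",
                    "source": "germline",
                    "platforms": ("RNA", "WES"),
                    "is_indel": bool(indel_flags[i]),
                    "strata": {"RNA": strata_labels[i], "WES": strata_labels[i]},
                    "region": regions[i],
                    "subst": substs[i],
                    "force_dbsnp": bool(dbsnp_flags[i]),
                }
            )

    # ---- fillers: panel-of-normals hits (site indices drawn jointly so
    # a site is hit at most once per sample)
    n_pon_rna = config.filler_counts.get("pon_rna", 0)
    n_pon_wes = config.filler_counts.get("pon_wes", 0)
    n_pon_total = min(n_pon_rna + n_pon_wes, config.pon_n_sites)
    joint_indices = (
        rng.choice(config.pon_n_sites, size=n_pon_total, replace=False)
        if n_pon_total
        else np.array([], dtype=int)
    )
    for platform, offset, count in (
        ("RNA", 0, min(n_pon_rna, n_pon_total)),
        ("WES", min(n_pon_rna, n_pon_total), n_pon_total - min(n_pon_rna, n_pon_total)),
    ):
        site_indices = joint_indices[offset : offset + count]
        n = len(site_indices)
        if n == 0:
            continue
        for i in range(n):
            events.append(
                {
                    "sample": sample,
                    "class": None,
                    "truth": "artifact",
                    "source": "pon",
                    "pon_site": int(site_indices[i]),
                    "platforms": (platform,),
                    "is_indel": False,
                    "strata": {platform: "mid"},
                    "region": "intronic",
                    "subst": "C>T",
                }
            )
    return events


def _indel_alleles(
    seq: str, pos: int, config: GeneratorConfig, rng: np.random.Generator
) -> Tuple[str, str]:
    length = int(
        rng.choice(config.indel_lengths,
                   p=np.asarray(config.indel_length_weights)
                   / np.sum(config.indel_length_weights))
    )
    anchor = seq[pos - 1]
    if rng.random() < 0.5 and pos + length <= len(seq):  # deletion
        return anchor + seq[pos : pos + length], anchor
    insert = "".join(rng.choice(list(_BASES), size=length).tolist())
    return anchor, anchor + insert


def _depth_context(platform: str, region: str, stratum: str) -> str:
    if platform == "WES":
        return "wes"
    if region == "exonic":
        return "rna_coding_lowaf" if stratum == "low" else "rna_coding"
    return "rna_noncoding"


def _negative_binomial(
    mean: float, dispersion: float, rng: np.random.Generator
) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _tumor_call(
    event: dict,
    platform: str,
    sample: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    tumor_only: bool,
) -> VariantCall:
    stratum = event["strata"][platform]
    mean, dispersion = config.coverage[_depth_context(platform, event["region"], stratum)]
    depth = max(config.min_depth, _negative_binomial(mean, dispersion, rng))
    a, b = config.af_shapes[stratum]
    af_draw = rng.beta(a, b)
    lo, hi = _stratum_alt_range(stratum, depth)
    alt_reads = int(np.clip(round(af_draw * depth), lo, hi))

    source = event["source"]
    if source == "tlod_fail":
        tlod = float(rng.uniform(0.2, 6.29))
    else:
        tlod = 6.31 + config.tlod_slope * alt_reads + float(rng.exponential(config.tlod_noise))
    if tumor_only:
        nlod = None
    elif source == "germline":
        nlod = float(rng.uniform(0.0, 2.19))
    else:
        nlod = config.nlod_pass_floor + float(rng.exponential(config.nlod_pass_scale))

    labels: set = set()
    if source == "tlod_fail" and rng.random() < config.passthrough_label_prob:
        labels.add("clustered_events")

    return VariantCall(
        sample_id=sample,
        platform=Platform(platform),
        contig=event["contig"],
        position=event["position"],
        ref_allele=event["ref"],
        alt_allele=event["alt"],
        alt_reads=alt_reads,
        depth=depth,
        tlod=round(tlod, 3),
        nlod=None if nlod is None else round(nlod, 3),
        filter_labels=labels,
    )


def _normal_call(
    normal_id: str,
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> VariantCall:
    mean, dispersion = config.coverage["normal"]
    depth = max(config.min_depth, _negative_binomial(mean, dispersion, rng))
    lo, hi = _stratum_alt_range("mid", depth)
    alt_reads = int(np.clip(round(rng.beta(2, 3) * depth), lo, hi))
    return VariantCall(
        sample_id=normal_id,
        platform=Platform.WES,
        contig=contig,
        position=pos,
        ref_allele=ref,
        alt_allele=alt,
        alt_reads=alt_reads,
        depth=depth,
        tlod=round(6.31 + 0.4 * alt_reads, 3),
        nlod=None,
        filter_labels=set(),
    )


def _assign_membership(
    events: List[dict],
    config: GeneratorConfig,
    rng: np.random.Generator,
    key_membership: Dict[VariantKey, Tuple[bool, bool]],
) -> None:
    """Stratified COSMIC/dbSNP assignment per (class, coding) group.

    Keys already assigned in an earlier sample keep their membership so
    the global database key sets stay consistent.
    """
    class_events = [e for e in events if e["source"] == "class"]
    for cls_name in ("RNA_ONLY", "INTERSECTION", "WES_ONLY"):
        for coding in (True, False):
            group = [
                e for e in class_events
                if e["class"] == cls_name and (e["region"] == "exonic") == coding
            ]
            if not group:
                continue
            probs = config.membership[f"{cls_name}:{'coding' if coding else 'noncoding'}"]
            labels = _spread(_MEMBERSHIP_LEVELS, _allocate(len(group), probs), rng)
            for event, label in zip(group, labels):
                key = event["key"]
                if key not in key_membership:
                    key_membership[key] = (
                        label in ("COSMIC_only", "both"),
                        label in ("dbSNP_only", "both"),
                    )
    for event in events:
        if event["source"] == "germline":
            key = event["key"]
            if key not in key_membership:
                key_membership[key] = (False, bool(event.get("force_dbsnp")))
        elif event["source"] in ("tlod_fail", "pon"):
            key_membership.setdefault(event["key"], (False, False))


def _add_background_keys(
    config: GeneratorConfig,
    rng: np.random.Generator,
    pools: _PositionPools,
    genome: Dict[str, str],
    contigs: List[str],
    contig_weights: np.ndarray,
    cohort_positions: set,
    cosmic_keys: set,
    dbsnp_keys: set,
) -> None:
    """Database entries not seen in the cohort, with a small configured
    COSMIC/dbSNP overlap (fraction of dbSNP keys also in COSMIC)."""
    n_both = int(round(config.cosmic_dbsnp_overlap * config.dbsnp_background))
    plan = [
        ("dbsnp", config.dbsnp_background - n_both),
        ("cosmic", max(config.cosmic_background - n_both, 0)),
        ("both", n_both),
    ]
    taken = set(cohort_positions)
    for target, count in plan:
        for _ in range(count):
            contig = contigs[rng.choice(len(contigs), p=contig_weights)]
            region = ["exonic", "intronic", "intergenic"][int(rng.choice(3))]
            pos = pools.draw(contig, region, "*", rng, taken)
            taken.add((contig, pos))
            ref = genome[contig][pos - 1]
            alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
            key = VariantKey.make(contig, pos, ref, alt)
            if target in ("dbsnp", "both"):
                dbsnp_keys.add(key)
            if target in ("cosmic", "both"):
                cosmic_keys.add(key)


def _draw_scores(
    score_events: List[dict],
    key_membership: Dict[VariantKey, Tuple[bool, bool]],
    index: TranscriptIndex,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> Tuple[Dict[VariantKey, ScorePair], pd.DataFrame]:
    """SIFT/FATHMM scores for coding class variants, skewed deleterious
    for COSMIC-only (somatic-evidence) variants.  Gene and AA change come
    from the actual coding-effect annotation on the toy models."""
    scores: Dict[VariantKey, ScorePair] = {}
    rows: List[dict] = []
    protein_cache: Dict[str, str] = {}
    for event in score_events:
        key = event["key"]
        if key in scores:
            continue
        model = index.coding_model(key)
        if model is None:
            continue
        try:
            annotation = annotate_coding_effect(key, model)
        except ValueError:
            continue
        in_cosmic, in_dbsnp = key_membership.get(key, (False, False))
        driver_like = in_cosmic and not in_dbsnp
        if event["is_indel"]:
            p_path = 0.8 if driver_like else 0.3
            fathmm_pred = "pathogenic" if rng.random() < p_path else "neutral"
            sift_pred = "Damaging" if rng.random() < p_path else "Neutral"
            pair = ScorePair(
                is_indel=True,
                sift_score=round(float(rng.uniform(50, 95)), 1),
                sift_pred=sift_pred,
                fathmm_pred=fathmm_pred,
                fathmm_confidence=round(float(rng.uniform(50, 95)), 1),
            )
        else:
            if driver_like:
                sift = float(rng.beta(0.5, 12.0))
                fathmm = float(rng.normal(-2.2, 1.2))
            else:
                sift = float(rng.beta(1.5, 3.0))
                fathmm = float(rng.normal(-0.2, 1.0))
            pair = ScorePair(
                is_indel=False,
                sift_score=round(sift, 3),
                sift_pred="Deleterious" if sift < 0.05 else "Tolerated",
                fathmm_score=round(fathmm, 3),
                fathmm_pred="CANCER" if fathmm < -0.75 else "PASSENGER",
            )
        scores[key] = pair
        rows.append(
            {
                "contig": key.contig,
                "position": key.position,
                "ref": key.ref_allele,
                "alt": key.alt_allele,
                "gene": annotation.gene,
                "aa_change": annotation.aa_change,
                "sift_score": pair.sift_score,
                "sift_pred": pair.sift_pred,
                "fathmm_score": pair.fathmm_score,
                "fathmm_pred": pair.fathmm_pred,
                "score_confidence": pair.fathmm_confidence,
            }
        )
    columns = ["contig", "position", "ref", "alt", "gene", "aa_change",
               "sift_score", "sift_pred", "fathmm_score", "fathmm_pred",
               "score_confidence"]
    frame = pd.DataFrame(rows, columns=columns)
    frame = frame.sort_values(["contig", "position", "ref", "alt"]).reset_index(drop=True)
    return scores, frame
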