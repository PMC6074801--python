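"""End-to-end report assembly: filter -> compare -> annotate -> score ->
stats -> recurrence on a cohort directory.

The pipeline consumes the plain-file cohort layout written by
:meth:`somaticbench.simulate.SyntheticCohort.write` (or any directory
with the same ``manifest.json`` contract) and emits TSV/JSON reports:
per-sample class counts, caller-filter proportions, substitution
spectra, AF/coverage strata per class, significance-ordered platform
overlaps, driver/novel candidate tables and the gene x sample recurrence
matrix with its deterministic clustering order.  Intermediate artifacts
are plain files so every stage can be audited and re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import pandas as pd

from . import compare as compare_mod
from . import stats as stats_mod
from .annotate import TranscriptIndex, annotate_coding_effect, read_transcript_models
from .datasets import gbm_gene_set
from .filters import CallingMode, apply_filter_harness, build_pon, filter_stats
from .model import (
    AA_CHANGING_EFFECTS,
    AnnotatedVariant,
    ComparisonClass,
    Platform,
    Region,
    Thresholds,
    read_calls,
    read_key_set,
    read_score_sidecar,
    write_calls,
)
from .recurrence import build_matrix, cluster_order, recurrent_genes
from .scores import GeneSet, best_gbm_filter, novel_candidate_filter

logger = logging.getLogger("somaticbench")

__all__ = ["RunConfig", "run_pipeline", "load_thresholds"]


def load_thresholds(path: Union[str, Path, None]) -> Thresholds:
    """Thresholds from a JSON mapping overriding any default field.

    Unknown keys are rejected so typos cannot silently keep a default.
    """
    if path is None:
        return Thresholds()
    data = json.loads(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(Thresholds)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    return Thresholds(**data)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (echoed to the log)."""

    input_dir: Path
    output_dir: Path
    thresholds: Thresholds = field(default_factory=Thresholds)
    mode: Optional[str] = None  # taken from the manifest when None
    pass_only: bool = True
    apply_pon: bool = True
    min_alt_reads: int = 2
    gene_set: Optional[GeneSet] = None

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)


def _aa_changing(variant: AnnotatedVariant) -> bool:
    return variant.effect in AA_CHANGING_EFFECTS


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write the report bundle.

    Returns the cohort-level summary that is also written to
    ``cohort_summary.json``.  Any stage failure raises with the stage
    named, leaving previously written artifacts in place.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    logger.info("thresholds in effect: %s", dataclasses.asdict(config.thresholds))

    stage = "load"
    try:
        manifest = json.loads((config.input_dir / "manifest.json").read_text())
        mode = CallingMode(config.mode or manifest.get("mode", "TUMOR_NORMAL"))
        models = read_transcript_models(
            config.input_dir / manifest["transcripts"],
            config.input_dir / manifest["genome"],
        )
        index = TranscriptIndex(models)
        cosmic = read_key_set(config.input_dir / manifest["databases"]["cosmic"])
        dbsnp = read_key_set(config.input_dir / manifest["databases"]["dbsnp"])
        sidecar = read_score_sidecar(config.input_dir / manifest["scores"])
        gene_set = config.gene_set or gbm_gene_set()

        stage = "panel_of_normals"
        normal_sets = [
            list(read_calls(config.input_dir / path, normal_id, Platform.WES))
            for normal_id, path in sorted(manifest.get("normals", {}).items())
        ]
        pon = (
            build_pon(normal_sets, min_samples=config.thresholds.pon_min_samples)
            if normal_sets
            else None
        )

        per_sample_rows: List[dict] = []
        overlap_rows: List[dict] = []
        annotated: List[AnnotatedVariant] = []
        all_rna: List = []
        all_wes: List = []
        strata_calls: Dict[str, list] = {c.value: [] for c in ComparisonClass}

        for sample, paths in sorted(manifest["samples"].items()):
            stage = f"filter[{sample}]"
            rna = apply_filter_harness(
                read_calls(config.input_dir / paths["rna"], sample, Platform.RNA),
                dbsnp, cosmic, pon, config.thresholds, mode, config.apply_pon,
            )
            wes = apply_filter_harness(
                read_calls(config.input_dir / paths["wes"], sample, Platform.WES),
                dbsnp, cosmic, pon, config.thresholds, mode, config.apply_pon,
            )
            all_rna.extend(rna)
            all_wes.extend(wes)

            stage = f"compare[{sample}]"
            classes = compare_mod.classify_three_way(rna, wes, pass_only=config.pass_only)
            for cls, count in compare_mod.class_counts(classes).items():
                per_sample_rows.append(
                    {"sample": sample, "class": cls.value, "count": count}
                )
            rna_pass = [c for c in rna if c.is_pass]
            wes_pass = [c for c in wes if c.is_pass]

            stage = f"annotate[{sample}]"
            by_key = {}
            for call in rna_pass + wes_pass:  # RNA call preferred as representative
                by_key.setdefault(call.key, call)
            sample_annotated = []
            for key, call in by_key.items():
                assignment = index.region_of(key)
                variant = AnnotatedVariant(
                    call=call,
                    gene=assignment.gene,
                    flanking_genes=assignment.flanking_genes
                    if assignment.region is Region.INTERGENIC
                    else None,
                    region=assignment.region,
                    in_cosmic=key in cosmic,
                    in_dbsnp=key in dbsnp,
                    scores=sidecar.get(key),
                    comparison_class=classes.get(key),
                )
                if assignment.region is Region.EXONIC:
                    model = index.coding_model(key)
                    if model is not None:
                        try:
                            effect = annotate_coding_effect(key, model)
                            variant.effect = effect.effect
                            variant.aa_change = effect.aa_change
                            variant.gene = effect.gene
                        except ValueError:
                            variant.effect = None
                else:
                    variant.effect = None
                sample_annotated.append(variant)
                if variant.comparison_class is not None:
                    strata_calls[variant.comparison_class.value].append(variant)
            annotated.extend(sample_annotated)

            coding = {v.key for v in sample_annotated if v.region is Region.EXONIC}
            aa = {v.key for v in sample_annotated if _aa_changing(v)}
            overlap_rows.append(
                {
                    "sample": sample,
                    "wes_pass_in_rna": compare_mod.overlap_fraction(wes_pass, rna_pass),
                    "wes_coding_in_rna": compare_mod.overlap_fraction(
                        wes_pass, rna_pass, lambda c: c.key in coding
                    ),
                    "wes_aa_changing_in_rna": compare_mod.overlap_fraction(
                        wes_pass, rna_pass, lambda c: c.key in aa
                    ),
                }
            )

        stage = "stats"
        pd.DataFrame(per_sample_rows).to_csv(out / "class_counts.tsv", sep="\t", index=False)
        filter_frame = pd.DataFrame(
            [
                {"platform": "RNA", "label": label, "proportion": value}
                for label, value in filter_stats(all_rna).items()
            ]
            + [
                {"platform": "WES", "label": label, "proportion": value}
                for label, value in filter_stats(all_wes).items()
            ]
        )
        filter_frame.to_csv(out / "filter_stats.tsv", sep="\t", index=False)
        spectra = {
            "RNA": stats_mod.mutation_spectrum(all_rna, pass_only=config.pass_only),
            "WES": stats_mod.mutation_spectrum(all_wes, pass_only=config.pass_only),
        }
        pd.DataFrame(
            {platform: profile.proportions for platform, profile in spectra.items()}
        ).rename_axis("substitution").to_csv(out / "spectrum.tsv", sep="\t")
        strata_report = {}
        for cls_value, variants in strata_calls.items():
            if not variants:
                continue
            strata = stats_mod.af_coverage_strata(
                [v.call for v in variants],
                regions=[v.region for v in variants],
            )
            strata_report[cls_value] = {
                "n": strata.n,
                "fractions": strata.fractions,
                "high_cov_low_af": strata.high_cov_low_af,
            }
        (out / "strata.json").write_text(json.dumps(strata_report, indent=2))
        chrom = stats_mod.chromosome_distribution([c for c in all_rna if c.is_pass])
        (out / "chromosome_distribution.json").write_text(json.dumps(chrom, indent=2))
        overlap_frame = pd.DataFrame(overlap_rows)
        overlap_frame.to_csv(out / "overlap.tsv", sep="\t", index=False)

        stage = "score_filters"
        scored = [
            v for v in annotated
            if v.scores is not None and v.gene is not None and v.effect is not None
        ]
        best = best_gbm_filter(scored, gene_set, config.thresholds)
        novel = novel_candidate_filter(
            scored, gene_set, config.thresholds, min_alt_reads=config.min_alt_reads
        )
        write_calls(list(best), out / "candidates_best.tsv")
        write_calls(list(novel), out / "candidates_novel.tsv")

        stage = "recurrence"
        matrix = build_matrix(annotated)
        matrix.to_frame().rename_axis("gene").to_csv(out / "recurrence.tsv", sep="\t")
        recurrent = recurrent_genes(matrix, config.thresholds.recurrence_min_samples)
        orders = cluster_order(matrix)
        (out / "cluster_orders.json").write_text(
            json.dumps({"rows": orders[0], "columns": orders[1]}, indent=2)
        )

        summary = {
            "n_samples": len(manifest["samples"]),
            "mode": mode.value,
            "class_counts": pd.DataFrame(per_sample_rows)
            .groupby("class")["count"].sum().to_dict(),
            "overlap_averages": {
                col: compare_mod.cohort_average(overlap_frame[col])
                for col in ("wes_pass_in_rna", "wes_coding_in_rna", "wes_aa_changing_in_rna")
            },
            "rna_editing_mass": {
                platform: profile.transition_mass() for platform, profile in spectra.items()
            },
            "n_best_candidates": len(best),
            "n_novel_candidates": len(novel),
            "n_recurrent_genes": len(recurrent),
        }
        (out / "cohort_summary.json").write_text(json.dumps(summary, indent=2))
        return summary
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
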