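"""The synthetic cohort generator: determinism, presets, conservation,
parameter recovery and round trips through the VCF reader."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pytest

from somaticbench.compare import classify_three_way
from somaticbench.filters import apply_filter_harness
from somaticbench.model import ComparisonClass, Platform, read_calls
from somaticbench.simulate import (
    GeneratorConfig,
    preset,
    simulate_cohort,
)
from somaticbench.stats import af_coverage_strata

from conftest import small_config


class TestPresets:
    def test_default_preset_is_a_nine_tumor_cohort(self):
        config = preset("tcga-gbm-default")
        assert config.n_samples == 9
        assert config.mode == "TUMOR_NORMAL"
        assert config.class_counts["RNA_ONLY"] >= 3000

    def test_uniform_null_has_flat_spectrum(self):
        config = preset("uniform-null")
        for platform in ("RNA", "WES"):
            assert all(
                v == pytest.approx(1 / 12) for v in config.spectrum[platform].values()
            )

    def test_sd01_like_is_tumor_only_with_chr7_excess(self):
        config = preset("sd01-like")
        assert config.mode == "TUMOR_ONLY"
        assert config.contig_weights[6] > config.contig_weights[0]

    def test_unknown_preset_lists_available_names(self):
        with pytest.raises(ValueError, match="tcga-gbm-default"):
            preset("no-such-preset")

    def test_invalid_configs_rejected_before_generation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(class_counts={"RNA_ONLY": -1})
        with pytest.raises(ValueError):
            GeneratorConfig(af_weights={"RNA_ONLY": (0.5, 0.2, 0.2)})
        with pytest.raises(ValueError):
            GeneratorConfig(mode="NOT_A_MODE")


class TestDeterminism:
    def test_same_seed_writes_byte_identical_files(self, tmp_path):
        dirs = []
        for run in ("a", "b"):
            out = tmp_path / run
            simulate_cohort(small_config(seed=5)).write(out)
            dirs.append(out)
        files = sorted(
            p.relative_to(dirs[0]) for p in dirs[0].rglob("*") if p.is_file()
        )
        assert files, "no files written"
        for rel in files:
            assert (dirs[0] / rel).read_bytes() == (dirs[1] / rel).read_bytes(), rel

    def test_different_seeds_differ(self):
        a = simulate_cohort(small_config(seed=1))
        b = simulate_cohort(small_config(seed=2))
        keys_a = {c.key for c in a.rna_calls[a.samples[0]]}
        keys_b = {c.key for c in b.rna_calls[b.samples[0]]}
        assert keys_a != keys_b


class TestStructure:
    def test_truth_rows_match_distinct_keys_per_sample(self, small_cohort):
        for sample in small_cohort.samples:
            keys = {c.key for c in small_cohort.rna_calls[sample]} | {
                c.key for c in small_cohort.wes_calls[sample]
            }
            n_truth = (small_cohort.truth["sample_id"] == sample).sum()
            assert len(keys) == n_truth

    def test_intended_classes_realized_after_filtering(self, small_cohort):
        config = small_cohort.config
        pon = small_cohort.build_pon()
        sample = small_cohort.samples[0]
        rna = apply_filter_harness(
            list(small_cohort.rna_calls[sample]), small_cohort.dbsnp_keys,
            small_cohort.cosmic_keys, pon,
        )
        wes = apply_filter_harness(
            list(small_cohort.wes_calls[sample]), small_cohort.dbsnp_keys,
            small_cohort.cosmic_keys, pon,
        )
        classes = classify_three_way(rna, wes, pass_only=True)
        counts = {cls: 0 for cls in ComparisonClass}
        for cls in classes.values():
            counts[cls] += 1
        assert counts[ComparisonClass.RNA_ONLY] == config.class_counts["RNA_ONLY"]
        assert counts[ComparisonClass.INTERSECTION] == config.class_counts["INTERSECTION"]
        assert counts[ComparisonClass.WES_ONLY] == config.class_counts["WES_ONLY"]

    def test_intersection_only_config_yields_no_exclusive_classes(self):
        config = small_config(seed=8)
        config.class_counts = {"RNA_ONLY": 0, "INTERSECTION": 50, "WES_ONLY": 0}
        config.filler_counts = {k: 0 for k in config.filler_counts}
        cohort = simulate_cohort(config)
        sample = cohort.samples[0]
        classes = classify_three_way(
            cohort.rna_calls[sample], cohort.wes_calls[sample], pass_only=False
        )
        values = set(classes.values())
        assert values == {ComparisonClass.INTERSECTION}

    def test_outputs_parse_through_the_vcf_reader(self, small_cohort, tmp_path):
        manifest = small_cohort.write(tmp_path)
        sample = small_cohort.samples[0]
        back = read_calls(
            tmp_path / manifest["samples"][sample]["rna"], sample, Platform.RNA
        )
        original = small_cohort.rna_calls[sample]
        assert len(back) == len(original)
        assert {c.key for c in back} == {c.key for c in original}
        by_key = {c.key: c for c in original}
        for call in back:
            match = by_key[call.key]
            assert (call.alt_reads, call.depth) == (match.alt_reads, match.depth)
            assert call.tlod == pytest.approx(match.tlod, abs=1e-3)

    def test_truth_table_is_joinable_to_calls(self, small_cohort):
        truth = small_cohort.truth
        sample = small_cohort.samples[0]
        call = small_cohort.rna_calls[sample][0]
        rows = truth[
            (truth.sample_id == sample)
            & (truth.contig == call.contig)
            & (truth.position == call.position)
        ]
        assert len(rows) == 1


class TestTumorOnlyPreset:
    def test_sd01_like_cohort_lacks_nlod_and_skews_to_chr7(self):
        from somaticbench.filters import CallingMode
        from somaticbench.stats import chromosome_distribution

        config = preset("sd01-like", seed=4)
        config.class_counts = {"RNA_ONLY": 600, "INTERSECTION": 60, "WES_ONLY": 400}
        config.filler_counts = {"tlod_fail_rna": 80, "tlod_fail_wes": 40,
                                "germline": 150, "pon_rna": 15, "pon_wes": 15}
        cohort = simulate_cohort(config)
        sample = cohort.samples[0]
        rna = apply_filter_harness(
            cohort.rna_calls[sample], cohort.dbsnp_keys, cohort.cosmic_keys,
            cohort.build_pon(), mode=CallingMode.TUMOR_ONLY,
        )
        assert all(call.nlod is None for call in rna)
        passing = [call for call in rna if call.is_pass]
        dist = chromosome_distribution(passing)
        others = [v for contig, v in dist.items() if contig != "chr7"]
        assert dist["chr7"] > 2 * max(others)
        # without a matched normal, germline variants pass the caller
        dbsnp_fraction = sum(c.key in cohort.dbsnp_keys for c in passing) / len(passing)
        assert dbsnp_fraction > 0.2


class TestParameterRecovery:
    @pytest.mark.parametrize("n_per_class", [400, 1600])
    def test_rna_only_af_spike_within_binomial_error(self, n_per_class):
        """The configured AF > 0.95 mass is recovered within 3 binomial
        standard errors at two cohort sizes (and converges by design)."""
        config = small_config(seed=13)
        config.n_samples = 2
        config.class_counts = {"RNA_ONLY": n_per_class, "INTERSECTION": 20,
                               "WES_ONLY": 50}
        cohort = simulate_cohort(config)
        target = config.af_weights["RNA_ONLY"][2]
        rna_only_truth = cohort.truth[
            (cohort.truth.comparison_class == "RNA_ONLY")
        ]
        calls = []
        wanted = {
            (r.sample_id, r.contig, r.position)
            for r in rna_only_truth.itertuples()
        }
        for sample in cohort.samples:
            calls.extend(
                c for c in cohort.rna_calls[sample]
                if (c.sample_id, c.contig, c.position) in wanted
            )
        fraction = af_coverage_strata(calls).fractions["af_gt_0.95"]
        n = len(calls)
        se = np.sqrt(target * (1 - target) / n)
        assert abs(fraction - target) <= max(3 * se, 1.5 / n)
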