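"""Emulated caller acceptance logic: TLOD/NLOD rules, the dbSNP/COSMIC
exception, panel-of-normals construction and filter proportions."""

from __future__ import annotations

import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somaticbench.filters import (
    CallingMode,
    build_pon,
    decide_filters,
    filter_stats,
)
from somaticbench.model import Platform, Thresholds, VariantCall


def make_call(tlod=10.0, nlod=3.0, contig="chr1", position=100, labels=()):
    return VariantCall(
        sample_id="T01", platform=Platform.RNA, contig=contig, position=position,
        ref_allele="A", alt_allele="G", alt_reads=10, depth=50,
        tlod=tlod, nlod=nlod, filter_labels=set(labels),
    )


def normal_call(normal_id, contig, position):
    return VariantCall(
        sample_id=normal_id, platform=Platform.WES, contig=contig, position=position,
        ref_allele="A", alt_allele="G", alt_reads=10, depth=40, tlod=8.0,
    )


class TestDecideFilters:
    """The five canonical acceptance-rule cases."""

    def test_confident_somatic_passes(self):
        decision = decide_filters(make_call(tlod=10.0, nlod=3.0),
                                  in_dbsnp=False, in_cosmic=False, pon=None)
        assert decision.labels == {"PASS"}

    def test_low_tlod_fails_tumor_evidence(self):
        decision = decide_filters(make_call(tlod=5.0),
                                  in_dbsnp=False, in_cosmic=False, pon=None)
        assert "t_lod_fstar" in decision.labels

    def test_dbsnp_raises_nlod_requirement(self):
        decision = decide_filters(make_call(tlod=10.0, nlod=3.0),
                                  in_dbsnp=True, in_cosmic=False, pon=None)
        assert "germline_risk" in decision.labels  # 3.0 <= 5.5

    def test_cosmic_cancels_the_dbsnp_raise(self):
        decision = decide_filters(make_call(tlod=10.0, nlod=3.0),
                                  in_dbsnp=True, in_cosmic=True, pon=None)
        assert decision.labels == {"PASS"}  # back to the 2.2 requirement

    def test_panel_of_normals_membership_fails(self):
        pon = build_pon(
            [[normal_call("N1", "chr1", 100)], [normal_call("N2", "chr1", 100)]],
            min_samples=2,
        )
        decision = decide_filters(make_call(), in_dbsnp=False, in_cosmic=False, pon=pon)
        assert "panel_of_normals" in decision.labels

    def test_boundary_comparisons_are_strict(self):
        at_tlod = decide_filters(make_call(tlod=6.3), False, False, None)
        assert "t_lod_fstar" in at_tlod.labels
        at_nlod = decide_filters(make_call(nlod=2.2), False, False, None)
        assert "germline_risk" in at_nlod.labels

    def test_alt_allele_in_normal_below_two(self):
        decision = decide_filters(make_call(nlod=1.5), False, False, None)
        assert "alt_allele_in_normal" in decision.labels
        assert "germline_risk" in decision.labels  # subsumed at defaults

    def test_passthrough_labels_retained_verbatim(self):
        call = make_call(labels={"clustered_events"})
        decision = decide_filters(call, False, False, None)
        assert "clustered_events" in decision.labels
        assert "PASS" not in decision.labels

    def test_tumor_only_mode_ignores_nlod(self):
        call = make_call(tlod=10.0, nlod=None)
        decision = decide_filters(call, in_dbsnp=True, in_cosmic=False, pon=None,
                                  mode=CallingMode.TUMOR_ONLY)
        assert decision.labels == {"PASS"}

    def test_missing_scores_raise(self):
        with pytest.raises(ValueError):
            decide_filters(make_call(tlod=None), False, False, None)
        with pytest.raises(ValueError):
            decide_filters(make_call(nlod=None), False, False, None,
                           mode=CallingMode.TUMOR_NORMAL)

    @given(
        tlod=st.floats(0.1, 30), delta=st.floats(0.0, 20),
        nlod=st.floats(0.0, 20),
        in_dbsnp=st.booleans(), in_cosmic=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_scores_and_cosmic(self, tlod, delta, nlod, in_dbsnp, in_cosmic):
        """Raising TLOD never removes PASS; raising NLOD never adds
        germline_risk; adding COSMIC membership only moves toward PASS."""
        base = decide_filters(make_call(tlod=tlod, nlod=nlod), in_dbsnp, in_cosmic, None)
        higher = decide_filters(make_call(tlod=tlod + delta, nlod=nlod + delta),
                                in_dbsnp, in_cosmic, None)
        if base.is_pass:
            assert higher.is_pass
        if "germline_risk" in higher.labels:
            assert "germline_risk" in base.labels
        with_cosmic = decide_filters(make_call(tlod=tlod, nlod=nlod), in_dbsnp, True, None)
        if base.is_pass:
            assert with_cosmic.is_pass


class TestPanelOfNormals:
    def test_two_of_twelve_included_one_excluded(self):
        sets = [[normal_call(f"N{i}", "chr1", 100 + 10 * (i % 3))] for i in range(12)]
        shared = [normal_call("N1", "chr2", 500), normal_call("N2", "chr2", 500)]
        sets[0].append(shared[0])
        sets[1].append(shared[1])
        singleton = normal_call("N3", "chr3", 900)
        sets[2].append(singleton)
        pon = build_pon(sets, min_samples=2)
        assert shared[0].key in pon
        assert singleton.key not in pon
        assert pon.n_normals == 12

    def test_duplicates_within_one_normal_count_once(self):
        duplicated = [normal_call("N1", "chr1", 100), normal_call("N1", "chr1", 100)]
        pon = build_pon([duplicated, []], min_samples=2)
        assert len(pon) == 0

    def test_empty_normals_give_empty_pon(self):
        assert len(build_pon([[], []], min_samples=2)) == 0

    def test_zero_normal_samples_error(self):
        with pytest.raises(ValueError):
            build_pon([], min_samples=2)

    def test_order_independence(self):
        sets = [
            [normal_call("N1", "chr1", 100), normal_call("N1", "chr1", 200)],
            [normal_call("N2", "chr1", 100)],
            [normal_call("N3", "chr1", 200)],
        ]
        forward = build_pon(sets, 2).keys
        backward = build_pon(sets[::-1], 2).keys
        assert forward == backward


class TestFilterStats:
    def test_pass_proportion(self):
        calls = [make_call(position=100 + i) for i in range(10)]
        for call in calls[:4]:
            call.filter_labels = {"PASS"}
        for call in calls[4:]:
            call.filter_labels = {"t_lod_fstar"}
        stats = filter_stats(calls)
        assert stats["PASS"] == pytest.approx(0.4)
        assert stats["t_lod_fstar"] == pytest.approx(0.6)

    def test_all_failing_one_filter(self):
        calls = [make_call(position=i + 1) for i in range(5)]
        for call in calls:
            call.filter_labels = {"t_lod_fstar"}
        stats = filter_stats(calls)
        assert stats == {"t_lod_fstar": 1.0, "PASS": 0.0}

    def test_matches_brute_force_on_random_labels(self):
        rng = random.Random(11)
        labels = ["t_lod_fstar", "germline_risk", "panel_of_normals", "clustered_events"]
        calls = []
        for i in range(400):
            call = make_call(position=i + 1)
            chosen = {l for l in labels if rng.random() < 0.3}
            call.filter_labels = chosen or {"PASS"}
            calls.append(call)
        stats = filter_stats(calls)
        tally = Counter()
        n_pass = 0
        for call in calls:
            if call.filter_labels == {"PASS"}:
                n_pass += 1
            for label in call.filter_labels - {"PASS"}:
                tally[label] += 1
        assert stats["PASS"] == pytest.approx(n_pass / 400)
        for label, count in tally.items():
            assert stats[label] == pytest.approx(count / 400)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            filter_stats([])
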