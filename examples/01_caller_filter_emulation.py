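"""Emulate the caller's acceptance thresholds on hand-built calls.

A tumor variant passes with TLOD > 6.3 (evidence of presence in the
tumor) and NLOD > 2.2 (evidence of absence from the matched normal).
dbSNP membership raises the NLOD requirement to 5.5 — unless the variant
is also in COSMIC, which restores the somatic requirement.
"""

from somaticbench import Platform, VariantCall, build_pon, decide_filters

def call(tlod, nlod):
    return VariantCall("tumor1", Platform.RNA, "chr7", 55_191_822, "C", "T",
                       alt_reads=12, depth=80, tlod=tlod, nlod=nlod)

normals = [
    [VariantCall(f"N{i}", Platform.WES, "chr7", 55_191_822, "C", "T",
                 alt_reads=8, depth=40, tlod=9.0)]
    for i in (1, 2)
]
pon = build_pon(normals, min_samples=2)

cases = [
    ("confident somatic", call(10.0, 3.0), False, False, None),
    ("weak tumor evidence (TLOD 5.0)", call(5.0, 3.0), False, False, None),
    ("in dbSNP, NLOD 3.0 < 5.5", call(10.0, 3.0), True, False, None),
    ("in dbSNP AND COSMIC (exception)", call(10.0, 3.0), True, True, None),
    ("recurrent in 2 normals (PoN)", call(10.0, 3.0), False, False, pon),
]

for label, variant, in_dbsnp, in_cosmic, panel in cases:
    decision = decide_filters(variant, in_dbsnp, in_cosmic, panel)
    print(f"{label:35s} -> {sorted(decision.labels)}")

# Expected: the first and fourth cases PASS; the others carry the named
# filter that fired (t_lod_fstar, germline_risk, panel_of_normals).
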