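# Methods

This note documents the models, conventions and design decisions behind
`somaticbench`: what is computed, with which defaults and why, what the
synthetic cohort generator does and does not emulate, and where the
design was genuinely open.

## Variant identity

All cross-platform set algebra runs on normalized keys
`(contig, position, ref, alt)`. Normalization trims shared suffix bases
first, then shared prefix bases (advancing the position), and restores a
single anchor base when an allele would empty — preferentially the last
trimmed *suffix* base, so that alternative spellings of the same indel
inside a repeat run (`GCC>GC` at 50, `CC>C` at 51) map to one canonical
form. Normalization is idempotent (property-tested). Contig names are
harmonized by treating `7` and `chr7` as the same contig; the input
spelling is preserved on output.

Multi-allelic records are split into one call per (record, alternate
allele), and all counts downstream are per alt allele. Allele fraction
is always `alt_reads / depth` when read counts are present; a recorded
AF annotation is used only when they are absent (the tables that define
AF define it as altered reads over total reads).

## Caller-filter emulation

Only filters that are pure functions of the caller's published scores
are recomputed:

| filter | fires when | default |
|---|---|---|
| `t_lod_fstar` | TLOD ≤ `tlod_pass` | 6.3 |
| `germline_risk` | NLOD ≤ effective requirement | 2.2, raised to 5.5 for dbSNP variants not in COSMIC |
| `alt_allele_in_normal` | NLOD < `nlod_alt_in_normal` | 2.0 |
| `panel_of_normals` | key called in ≥ `pon_min_samples` normals | 2 |

All comparisons are **strict**, exactly as the thresholds are printed
("TLOD > 6.3" passes only above 6.3; a score at the boundary fails).
The sign convention of `alt_allele_in_normal` is ambiguous in its prose
description ("enough evidence of presence in the normal, NLOD threshold
2.0"); since NLOD scores confidence of *absence* from the normal, the
filter fires at *low* NLOD. At default thresholds it is therefore
subsumed by `germline_risk`; both labels are still reported
independently. Alignment-dependent filters
(`homologous_mapping_event`, `clustered_events`, `str_contraction`,
`multi_event_alt_allele_in_normal`) require read-level data and are
passed through from the input FILTER column verbatim. In tumor-only
mode only the TLOD rule applies (no NLOD is available); panel-of-normals
application is a flag in both modes.

## Comparison and cohort averaging

Three-way classification defaults to PASS calls (decision exactly
`{PASS}`); a flag compares everything. Cohort-level proportions are
unweighted means of per-sample proportions, except the AF-stratum
fractions, which are pooled over samples (that is how the corresponding
cohort quantities are defined); both modes are available.
`overlap_fraction` returns `None` — not 0 — when its predicate selects
an empty reference subset.

## Annotation

Region precedence across overlapping transcripts is
exonic > splicing > UTR > intronic > intergenic; "exonic" means
CDS-overlapping, "UTR" exonic-but-not-CDS, and "splicing" within
`splice_window` bases (default 2, the common annotator convention)
inside an intron. Intergenic variants report their two flanking genes.
Coding effects are computed by strand-aware codon substitution and
translation on the transcript model; amino-acid positions start at 1 at
the initiator methionine, stop codons are written `X`, frameshifts as
`<refAA><pos>fs` and in-frame indels as `<refAA><pos>del`/`ins`. For
indels the affected codon is the one containing the first changed base
after the shared anchor. Strand consistency (a minus-strand model of the
reverse-complemented locus yields identical effects) is property-tested.

## Functional filters

SIFT retains SNVs strictly below 0.05; FATHMM with cancer weights
retains strictly below −0.75 (the CANCER call). Indels are scored
categorically (SIFT-indel `Damaging`, FATHMM-indel `pathogenic` with a
confidence %); FATHMM-indel only scores indels shorter than 20 bp —
longer indels are *unscorable*, counted, and treated as not retained,
never silently dropped.

The driver criterion is a conjunction (gene set ∧ COSMIC-only ∧
AA-changing ∧ SIFT ∧ FATHMM); the novel-candidate criterion swaps
COSMIC-only for unknown-to-both and the score conjunction for a
disjunction, and adds `min_alt_reads ≥ 2` as an artifact-plausibility
guard. The read-support cutoff is not quantified in the criterion's
prose description; 2 is this package's default, configurable and logged.
The packaged 29-gene GBM set keeps the curated symbols verbatim,
including `ARF` and `P16`, which are both aliases of CDKN2A products —
user gene symbols must match the curated spellings.

Recurrent identical indels called RNA-only in many tumors but never
supported by WES are a known artifact mode; `somaticbench` expresses
this as a transparent flag (`suspect_recurrent_indel`, default ≥ 9
samples) rather than a silent exclusion.

## Statistics

The substitution spectrum is a multinomial over the 12 ordered ref>alt
types with **no strand collapsing**, because RNA editing (A-to-I, read
as A>G/T>C) is strand-asymmetric and is precisely the signal of
interest. AF strata use strict inequalities at the printed bounds
(0.05, 0.50, 0.95); values exactly at a bound fall into the middle
stratum. The joint (AF < 0.05, coverage > 500) cell is reported
separately as the high-coverage/low-AF region most likely to hide
somatic mutations missed by the other platform.

Cross-platform detectability is the closed-form binomial
`P(≥1 variant read) = 1 − (1 − AF)^coverage`, nondecreasing in both
arguments and verified against Monte-Carlo binomial simulation. For the
canonical worked input (AF = 22/4792, coverage 101) the exact value is
0.372; a rounded 0.39 is sometimes quoted for this configuration in the
literature, but it is not what the stated computation yields, and
`somaticbench` reports the exact value.

Recurrence counts coding variants per gene per sample (multiple
variants in one gene and sample count individually) and selects genes
altered in ≥ 5 of 9 tumors. The heatmap ordering convention is not
standardized anywhere, so the package fixes one: naive average-linkage
agglomeration on Euclidean distances with lexicographic tie-breaking,
which makes the order a pure function of the matrix. Tests cross-check
the merge tree against `scipy.cluster.hierarchy` on tie-free inputs
(leaf orientation is a convention and is not compared).

## Synthetic cohort generator

The generator emulates the *statistical structure* of a paired
nine-tumor RNA/WES comparison, not reads or alignments. Per tumor it
plans a set of variant events and realizes them on a toy genome (ten
200 kb contigs, eight tiled genes each: six 300 bp exons, 900 bp
introns, 150 bp terminal UTRs; start/stop codons stamped and internal
in-frame stops scrubbed so every model translates cleanly).

Key design choices:

* **Stratified allocation.** Class sizes, AF strata, region mixes and
  membership classes are allocated by largest-remainder rounding within
  each sample; randomness shapes only the within-stratum values,
  positions and substitution types. The generator's contract is to
  realize its configured cohort-level masses at finite n, so allocation
  noise is deliberately excluded; between-run variation is confined to
  within-stratum draws.
* **Exact strata under recomputed AF.** Depth is drawn per
  (platform, region) from a negative binomial clamped at ≥ 21 (the
  smallest depth at which every AF stratum contains an integer read
  count), and alt reads are drawn inside the intended stratum's integer
  range, shaped by the configured Beta component (low ≈ Beta(1.2, 40),
  bulk ≈ Beta(2, 3), high ≈ Beta(40, 1)). Recomputing AF = alt/depth can
  therefore never move a call across a stratum boundary.
* **Intended-PASS guarantees.** Somatic class events get
  TLOD = 6.31 + 0.4·alt_reads + Exp(2) and NLOD = 5.51 + Exp(3), so they
  pass the harness regardless of dbSNP membership; filler events are
  constructed to fail exactly one filter each (low-TLOD artifacts,
  low-NLOD germline variants emitted to both platforms, panel-of-normals
  hits drawn from the shared site list). A fraction of artifacts carries
  a pass-through label (`clustered_events`) to exercise label retention.
* **Coupled AF/region/coverage structure.** RNA-only region mix is
  conditioned on the AF stratum: the high-AF spike is predominantly
  intronic/intergenic at low coverage (negative binomial mean 40), the
  low-AF spike predominantly coding at high coverage (mean 1000,
  dispersion 1.2, putting about half of the low-AF spike above 500×).
  WES coverage is mean 150, dispersion 8.
* **Membership by construction.** COSMIC-like and dbSNP-like key sets
  are generated jointly with the variants (per class × coding group),
  plus background keys with a 0.15% dbSNP-in-COSMIC overlap. Tumor event
  positions are unique cohort-wide so each event's membership is exact.
* **Spectra.** WES uses a C>T/G>A-dominant somatic-like spectrum
  (A>G + T>C mass 0.12); RNA-only events use an editing-boosted spectrum
  (A>G + T>C mass 0.42); intersection events, being DNA variants, use
  the WES spectrum.
* **Determinism.** One seeded PCG64 stream drives everything; the same
  configuration writes byte-identical files (tested).

The default preset (`tcga-gbm-default`) encodes the reference cohort
conditions: 9 tumors; per sample 3,200 RNA-only, 141 intersection and
1,995 WES-only intended-PASS events — sizes chosen so the WES-PASS-in-RNA
overlap is 141/2136 = 6.60% and every pooled stratum estimate has small
binomial error; AF stratum masses (36.3%, 25.5%, 38.2%) for RNA-only and
(22.8%, 76.7%, 0.5%) for WES-only; 89.7% of intersection events coding
with membership (87.7% COSMIC-only, 4.3% dbSNP-only, 2% both); 12
normals contributing a 300-site panel. `uniform-null` removes all class
structure (for false-positive checks of the downstream statistics);
`sd01-like` is a single tumor-only pair with no NLOD, elevated germline
content that passes the caller, a chromosome-7 excess and a
transition-heavy spectrum.

**What the generator does not emulate** — and hence what passing tests
do and do not show about real data: no read-level error processes
(sequencing error, mapping bias, strand bias), no exome-capture boundary
geometry (platform exclusivity is assigned, not caused by coverage), no
linkage between nearby variants, no real genome coordinates or gene
lengths, and functional scores drawn from stylized distributions rather
than computed from sequence. Tests on synthetic cohorts validate the
*bookkeeping and statistics* of the pipeline under known truth; they do
not validate caller accuracy on real tumors.

## Numerical conventions and degenerate inputs

Strict comparisons at every printed threshold; empty call sets raise in
the statistics operations (an empty spectrum or stratum table would be
meaningless) but degrade gracefully in the pipeline (an empty RNA call
set yields an all-WES-only comparison); undefined fractions are `None`,
never 0; VCF floats survive a round trip to float32 precision (~1e-3),
which is far below any threshold margin; positions are 1-based
throughout with closed intervals, matching VCF and GFF3.

## Problem sizes

The test suite generates small cohorts (2 tumors, a few hundred events)
for structural checks and the full default preset (9 tumors, ~60,000
calls) once for the cohort-statistics round trip; the acceptance script
regenerates that cohort from its seed. Monte-Carlo oracles use 10^5
draws. These sizes keep every estimate's sampling error well inside the
tolerances while the whole suite runs in well under a minute.
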