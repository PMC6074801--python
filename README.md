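# somaticbench

Benchmarking somatic-mutation detection from tumor **RNA-seq** against
**whole-exome sequencing (WES)**.

Most cancer-genomics pipelines call somatic mutations from WES of a
tumor/normal pair. RNA-seq of the same tumor can also reveal mutations —
with much deeper coverage of highly expressed genes (where oncogenes
live) but with confounders of its own: RNA editing, low allele-fraction
artifacts, and coverage that collapses outside expressed exons.
`somaticbench` is a library for asking, quantitatively, what each
platform sees that the other misses. It is aimed at method developers
and analysts who have paired call sets (e.g. MuTect2 output from
glioblastoma tumors) and want the downstream comparison machinery
without re-running alignment or assembly.

## What it computes

* **Caller-filter emulation** — the threshold-expressible acceptance
  logic of a tumor/normal caller. A variant is PASS when
  `TLOD > 6.3` and `NLOD > 2.2`; dbSNP membership raises the NLOD
  requirement to 5.5 *unless* the variant is also in COSMIC. Panel of
  normals: sites called in ≥ 2 normal samples. Alignment-dependent
  filters are passed through verbatim, never recomputed.
* **Three-way comparison** — every variant key of a tumor is classified
  RNA-only / intersection / WES-only on normalized
  `(contig, pos, ref, alt)` identities, with overlap fractions by
  variant significance (all PASS, coding, protein-altering).
* **Annotation** — genomic region (exonic/splicing/UTR/intronic/
  intergenic with flanking genes), strand-aware coding effect with AA
  notation (`A702S`, `V296fs`), and COSMIC/dbSNP membership
  (COSMIC-only being the strongest somatic evidence).
* **Functional filters** — SIFT (`< 0.05` deleterious) and
  cancer-weighted FATHMM (`< −0.75` CANCER) with the two headline
  criteria: *best GBM-related mutations* (29-gene set ∧ COSMIC-only ∧
  AA-changing ∧ retained by **both** scores) and *candidate novel
  mutations* (gene set ∧ unknown to both databases ∧ retained by
  **either** score ∧ ≥ 2 supporting reads).
* **Cohort statistics** — strand-specific substitution spectrum (RNA
  editing reads as A>G/T>C), allele-fraction/coverage strata, binomial
  detectability `P(≥1 read) = 1 − (1 − AF)^coverage`, per-chromosome
  distribution, and gene×sample recurrence with a deterministic
  average-linkage ordering.
* **Synthetic cohorts** — a seeded generator that emulates the cohort
  structure of a nine-tumor paired GBM comparison (bimodal RNA-only AF,
  class-dependent database membership, editing-skewed spectrum,
  significance-ordered overlap) with complete ground truth, so the
  entire pipeline is testable without controlled-access data.

## Worked example

```python
from somaticbench import best_gbm_filter, gbm_gene_set
from somaticbench.datasets import gbm_driver_candidates, driver_decoys

report = best_gbm_filter(gbm_driver_candidates() + driver_decoys(), gbm_gene_set())
print(len(report))          # 11
print(report.rejected)      # each decoy rejected for its single violation
```

Running `python examples/03_candidate_selection.py` prints:

```
driver criterion: 11 of 17 records retained
  EGFR     A702S    RNA_ONLY     sample=SD01
  ...
novel criterion: 9 of 14 records retained
  ...
  EGFR     L718R    RNA_ONLY     alt_reads=22
```

Eleven driver candidates survive the conjunctive criterion (3 found by
RNA-seq only, 6 by both platforms, 2 by WES only) and nine novel
candidates survive the disjunctive one (8 RNA-only, 1 WES-only) — the
decoys, each violating exactly one clause, are all rejected.
`python examples/04_cohort_statistics.py` shows the cohort-level
structure on synthetic data:

```
A>G + T>C mass (RNA editing reads as these transitions):
  RNA-seq: 0.400   WES: 0.129
RNA-only allele-fraction strata (bimodal by construction):
  af_lt_0.05   0.363
  af_gt_0.95   0.382
P(>=1 variant read | AF=22/4792, WES coverage=101) = 0.372
```

The last line is the detectability argument in one number: a variant
supported by 22 of 4,792 RNA-seq reads has only a 37% chance of showing
even a single read at typical WES depth.

There is also a thin CLI (`somaticbench simulate|filter|compare|annotate|
score|stats|recur|report`) wrapping the same functions for shell use;
`somaticbench report --input <cohort dir> -o <out>` runs every stage and
writes the TSV/JSON report bundle.

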