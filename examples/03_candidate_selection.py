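"""Select driver and novel candidates from the bundled GBM records.

The driver criterion is conjunctive: 29-gene set AND COSMIC-only AND
protein-altering AND deleterious by SIFT (< 0.05) AND by cancer-weighted
FATHMM (< -0.75).  The novel criterion asks for variants unknown to both
databases, retained by either score, with at least two supporting reads.
"""

from somaticbench import best_gbm_filter, gbm_gene_set, novel_candidate_filter
from somaticbench.datasets import (
    driver_decoys,
    gbm_driver_candidates,
    gbm_novel_candidates,
    novel_decoys,
)

gene_set = gbm_gene_set()
print(f"gene set: {gene_set.name} ({len(gene_set)} genes)\n")

driver_input = gbm_driver_candidates() + driver_decoys()
best = best_gbm_filter(driver_input, gene_set)
print(f"driver criterion: {len(best)} of {len(driver_input)} records retained")
for v in best:
    print(f"  {v.gene:8s} {v.aa_change:8s} {v.comparison_class.value:12s} "
          f"sample={v.call.sample_id}")
print(f"  rejections: {best.rejected}\n")

novel_input = gbm_novel_candidates() + novel_decoys()
novel = novel_candidate_filter(novel_input, gene_set, min_alt_reads=2)
print(f"novel criterion: {len(novel)} of {len(novel_input)} records retained")
for v in novel:
    print(f"  {v.gene:8s} {v.aa_change:8s} {v.comparison_class.value:12s} "
          f"alt_reads={v.call.alt_reads}")
# Note CDKN2C V130A survives through the SIFT branch alone (FATHMM calls
# it PASSENGER) — the novel criterion is a disjunction over the scores.
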