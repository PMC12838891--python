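"""Refine a disease gene set against pooled comorbidity panels.

Generates thirteen synthetic comorbidity panels and a 102-gene disease set
with a planted 58-gene overlap, pools the panels, and builds the refined set
(overlap genes plus 8 retained disease-unique genes) with per-gene
provenance.
"""

from comolead.genesets import aggregate_pool, refine_set
from comolead.synth import make_gene_universe, paper_overlap_spec

panels, osa, truth = make_gene_universe(paper_overlap_spec(seed=1))
pool, report = aggregate_pool(panels)
retained = sorted(g for g, v in truth.items() if v == "osa_unique_retained")
refined = refine_set(pool, osa, retained)

print(f"pooled {len(panels)} panels -> {len(pool)} unique genes")
print(report.to_string(index=False))
print(f"disease set: {len(osa)} genes; overlap with pool: {refined.n_overlap}")
print(f"refined set: {len(refined)} genes "
      f"({refined.n_overlap} comorbidity-overlap + {refined.n_unique} disease-unique)")
# The refined set is the gene list that seeds the association network:
# genes tied to the comorbidity burden plus the retained disease-only genes.
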