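"""Network statistics, dense-module detection and overrepresentation.

Builds a planted-module interaction graph, reports its global statistics,
recovers the planted modules with MCODE, and runs a hypergeometric
enrichment of one module against synthetic annotation terms.
"""

from comolead.genesets import GeneSet
from comolead.network import enrichment, graph_stats, mcode
from comolead.synth import PlantedGraphSpec, make_modular_graph

g = make_modular_graph(PlantedGraphSpec(n_modules=3, module_size=6,
                                        p_in=0.95, p_out=0.02, seed=10))
s = graph_stats(g)
print(f"graph: {s.n_nodes} nodes, {s.n_edges} edges, "
      f"avg degree {s.avg_degree:.2f}, avg clustering {s.avg_local_clustering:.3f}")

modules = mcode(g)  # published defaults: degree 2, score cutoff 0.2, 2-core
for rank, m in enumerate(modules, 1):
    print(f"module {rank}: score {m.score:.2f}, members {sorted(m.members)}")

background = GeneSet("bg", frozenset(g.nodes))
terms = {
    f"planted_block_{b}": GeneSet(f"planted_block_{b}",
                                  frozenset(v for v in g.nodes if v.startswith(f"M{b}")))
    for b in range(3)
}
query = GeneSet("q", modules[0].members)
for r in enrichment(query, terms, background):
    print(f"{r.term}: overlap {r.overlap}/{r.term_size}, p={r.p_value:.2e}, fdr={r.fdr:.2e}")
# A tiny p for exactly one planted term confirms the top detected module is
# a planted block rather than a chance-dense subgraph.
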