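"""Network analytics: stats, MCODE, co-expression, enrichment."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from comolead.genesets import GeneSet
from comolead.network import (
    McodeParams,
    coexpression_partners,
    correlation_r2,
    enrichment,
    graph_stats,
    mcode,
    read_edgelist_tsv,
    shared_partners,
    write_edgelist_tsv,
)
from comolead.synth import ExprBlockSpec, PlantedGraphSpec, make_expression_matrix, make_modular_graph


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_best_subsets(g, min_size=2):
    """All subsets maximizing density x size, by exhaustive enumeration."""
    best, winners = -1.0, []
    nodes = list(g.nodes)
    for r in range(min_size, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            sub = g.subgraph(subset)
            n = sub.number_of_nodes()
            score = 2.0 * sub.number_of_edges() / (n * (n - 1)) * n
            if score > best + 1e-12:
                best, winners = score, [frozenset(subset)]
            elif abs(score - best) <= 1e-12:
                winners.append(frozenset(subset))
    return best, winners


def brute_force_hypergeom_tail(N, K, n, k):
    """P(overlap >= k) by enumerating all C(N, n) query draws."""
    population = range(N)
    successes = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(population, n):
        total += 1
        hits += len(successes.intersection(draw)) >= k
    return hits / total


# ---------------------------------------------------------------------------
# Graph statistics
# ---------------------------------------------------------------------------

class TestGraphStats:
    def test_triangle(self):
        s = graph_stats(nx.complete_graph(3))
        assert s.avg_degree == 2.0
        assert s.avg_local_clustering == 1.0

    def test_three_node_path_has_zero_clustering(self):
        s = graph_stats(nx.path_graph(3))
        assert s.avg_local_clustering == 0.0

    def test_66_nodes_171_edges_average_degree(self):
        g = nx.gnm_random_graph(66, 171, seed=5)
        s = graph_stats(g)
        assert round(s.avg_degree, 2) == 5.18

    def test_degree_identity_exact_before_rounding(self):
        for seed in range(5):
            g = nx.gnm_random_graph(30, 70, seed=seed)
            s = graph_stats(g)
            assert s.avg_degree * s.n_nodes == 2 * s.n_edges

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            graph_stats(nx.Graph())


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------

def two_cliques_and_path():
    """Two disjoint 5-cliques bridged by a 3-node path (13 nodes total)."""
    g = nx.Graph()
    a = [f"a{i}" for i in range(5)]
    b = [f"b{i}" for i in range(5)]
    g.add_edges_from(itertools.combinations(a, 2))
    g.add_edges_from(itertools.combinations(b, 2))
    bridge = ["p0", "p1", "p2"]
    g.add_edges_from([(a[0], bridge[0]), (bridge[0], bridge[1]),
                      (bridge[1], bridge[2]), (bridge[2], b[0])])
    return g, frozenset(a), frozenset(b)


class TestMcode:
    def test_top_two_modules_are_the_cliques(self):
        g, a, b = two_cliques_and_path()
        mods = mcode(g)
        assert {mods[0].members, mods[1].members} == {a, b}

    def test_agrees_with_brute_force_densest_enumeration(self):
        g, a, b = two_cliques_and_path()
        best, winners = brute_force_best_subsets(g, min_size=4)
        assert set(winners) == {a, b}  # the enumeration itself
        mods = mcode(g)
        assert mods[0].members in winners
        assert math.isclose(mods[0].score, best)

    def test_edgeless_graph_yields_no_modules(self):
        g = nx.empty_graph(6)
        assert mcode(g) == []

    @pytest.mark.parametrize("k", [4, 5, 6])
    def test_single_clique_recovered_whole(self, k):
        g = nx.complete_graph(k)
        mods = mcode(g)
        assert len(mods) == 1
        assert mods[0].members == frozenset(g.nodes)
        assert math.isclose(mods[0].score, float(k))  # density 1 x size k

    def test_planted_modules_recovered_exactly_over_seeds(self):
        from sklearn.metrics import adjusted_rand_score

        for seed in range(20):
            spec = PlantedGraphSpec(n_modules=3, module_size=6,
                                    p_in=1.0, p_out=0.0, seed=seed)
            g = make_modular_graph(spec)
            mods = mcode(g)
            label_of = {v: i for i, m in enumerate(mods) for v in m.members}
            nodes = sorted(g.nodes)
            truth = [g.nodes[v]["module"] for v in nodes]
            pred = [label_of.get(v, -1) for v in nodes]
            assert adjusted_rand_score(truth, pred) == 1.0

    def test_params_validation(self):
        with pytest.raises(ValueError):
            McodeParams(k_core=1)
        with pytest.raises(ValueError):
            McodeParams(degree_cutoff=0)


# ---------------------------------------------------------------------------
# Co-expression
# ---------------------------------------------------------------------------

class TestCoexpression:
    def test_duplicated_row_is_a_partner(self):
        expr = make_expression_matrix(ExprBlockSpec(n_genes=4, n_samples=20, seed=1))
        expr.loc["DUP"] = expr.loc["G0000"]
        assert "DUP" in coexpression_partners(expr, "G0000")

    def test_exact_anticorrelation_included_by_absolute_rule(self):
        expr = make_expression_matrix(ExprBlockSpec(n_genes=4, n_samples=20, seed=1))
        expr.loc["NEG"] = -expr.loc["G0000"]
        assert "NEG" in coexpression_partners(expr, "G0000")

    def test_type_one_error_rate_under_independence(self):
        expr = make_expression_matrix(
            ExprBlockSpec(n_genes=1000, n_samples=200, block_correlation=0.0, seed=8)
        )
        partners = coexpression_partners(expr, "G0000", r_thresh=0.5, p_thresh=0.01)
        assert len(partners) / 999 < 0.01

    def test_zero_variance_query_rejected_by_name(self):
        expr = make_expression_matrix(ExprBlockSpec(n_genes=3, n_samples=10, seed=2))
        expr.loc["FLAT"] = 1.0
        with pytest.raises(ValueError, match="FLAT"):
            coexpression_partners(expr, "FLAT")

    def test_shared_partner_in_common_block(self):
        assign = {"A": 0, "B": 0, "C": 0, **{f"N{i}": i + 1 for i in range(5)}}
        expr = make_expression_matrix(
            ExprBlockSpec(n_genes=8, n_samples=200, block_assignments=assign,
                          block_correlation=0.99, seed=3)
        )
        assert "C" in shared_partners(expr, "A", "B")

    def test_disjoint_blocks_share_nothing(self):
        assign = {"A": 0, "B": 1, **{f"N{i}": 2 + i for i in range(6)}}
        expr = make_expression_matrix(
            ExprBlockSpec(n_genes=8, n_samples=100, block_assignments=assign,
                          block_correlation=0.0, seed=4)
        )
        assert shared_partners(expr, "A", "B") == frozenset()

    def test_idempotent_when_both_queries_equal(self):
        expr = make_expression_matrix(
            ExprBlockSpec(n_genes=6, n_samples=100, block_correlation=0.9, seed=5)
        )
        assert shared_partners(expr, "G0000", "G0000") == coexpression_partners(expr, "G0000")


class TestCorrelationR2:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        assert correlation_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_orthogonalized_pair_is_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        xc = x - x.mean()
        y = y - y.mean() - (y - y.mean()) @ xc / (xc @ xc) * xc  # force sample r = 0
        assert correlation_r2(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_common_factor_rho_half_gives_quarter(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal(10_000)
        rho = 0.5
        x = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(10_000)
        y = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(10_000)
        assert correlation_r2(x, y) == pytest.approx(0.25, abs=0.03)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlation_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def _gs(name, genes):
    return GeneSet(name=name, genes=frozenset(genes))


class TestEnrichment:
    def test_disjoint_term_has_p_one(self):
        bg = _gs("bg", {f"g{i}" for i in range(10)})
        res = enrichment(_gs("q", {"g0", "g1"}), {"t": _gs("t", {"g8", "g9"})}, bg)
        assert res[0].p_value == 1.0

    def test_complete_overlap_exact_p(self):
        bg = _gs("bg", {f"g{i}" for i in range(10)})
        term = _gs("t", {f"g{i}" for i in range(5)})
        res = enrichment(_gs("q", set(term.genes)), {"t": term}, bg)
        assert res[0].p_value == pytest.approx(1 / 252)

    def test_matches_brute_force_enumeration_on_small_backgrounds(self):
        bg_genes = [f"g{i}" for i in range(12)]
        bg = _gs("bg", set(bg_genes))
        term = _gs("t", set(bg_genes[:5]))
        for qsize in (3, 5, 7):
            query = _gs("q", set(bg_genes[2:2 + qsize]))
            res = enrichment(query, {"t": term}, bg)
            k = len(query.genes & term.genes)
            expected = brute_force_hypergeom_tail(12, 5, qsize, k) if k else 1.0
            assert res[0].p_value == pytest.approx(expected, rel=1e-10)

    def test_equal_pvalues_share_their_fdr(self):
        bg = _gs("bg", {f"g{i}" for i in range(10)})
        terms = {f"t{j}": _gs(f"t{j}", {f"g{j}", f"g{j+1}"}) for j in range(4)}
        res = enrichment(_gs("q", {"g0", "g1", "g2", "g3", "g4"}), terms, bg)
        same_p = {r.term: r for r in res if r.overlap == 2}
        assert len(same_p) >= 2
        ps = {r.p_value for r in same_p.values()}
        assert len(ps) == 1
        # BH with m identical p-values (and no smaller ones) leaves them at p
        if len(same_p) == len(res):
            assert all(r.fdr == pytest.approx(r.p_value) for r in res)

    def test_bh_fdr_monotone_in_sorted_order(self):
        rng = np.random.default_rng(2)
        bg = _gs("bg", {f"g{i}" for i in range(15)})
        terms = {
            f"t{j}": _gs(f"t{j}", set(rng.choice(sorted(bg.genes), size=rng.integers(2, 8),
                                                 replace=False)))
            for j in range(8)
        }
        res = enrichment(_gs("q", {f"g{i}" for i in range(6)}), terms, bg)
        fdrs = [r.fdr for r in res]  # sorted by p ascending
        assert fdrs == sorted(fdrs)
        assert all(0.0 <= f <= 1.0 for f in fdrs)

    def test_query_outside_background_rejected(self):
        bg = _gs("bg", {"g0"})
        with pytest.raises(ValueError):
            enrichment(_gs("q", {"zz"}), {}, bg)


# ---------------------------------------------------------------------------
# Edge-list IO
# ---------------------------------------------------------------------------

class TestEdgelistIO:
    def test_round_trip_and_confidence_filter(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t0.9\nB\tC\t0.2\nC\tD\t0.41\n")
        g = read_edgelist_tsv(path, confidence_threshold=0.4)
        assert set(map(frozenset, g.edges)) == {frozenset({"A", "B"}), frozenset({"C", "D"})}
        out = tmp_path / "out.tsv"
        write_edgelist_tsv(g, out)
        assert nx.utils.graphs_equal(read_edgelist_tsv(out), g)

    def test_self_loop_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tA\n")
        with pytest.raises(ValueError, match="line 1"):
            read_edgelist_tsv(path)
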