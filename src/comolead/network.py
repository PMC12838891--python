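"""Protein-association network analytics.

Graph statistics, MCODE dense-module detection, Pearson co-expression partner
queries with the t-transform significance test, and hypergeometric
overrepresentation with Benjamini-Hochberg FDR control.

Graphs are plain :class:`networkx.Graph` objects; an optional ``weight`` edge
attribute holds an association confidence in [0, 1].
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet

__all__ = [
    "NetworkStats",
    "McodeParams",
    "Module",
    "EnrichmentResult",
    "graph_stats",
    "mcode",
    "coexpression_partners",
    "shared_partners",
    "correlation_r2",
    "enrichment",
    "read_edgelist_tsv",
    "write_edgelist_tsv",
    "write_modules_tsv",
    "write_enrichment_tsv",
]


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_local_clustering: float


@dataclass(frozen=True)
class McodeParams:
    """MCODE parameters; the published defaults are degree cutoff 2,
    node score cutoff 0.2, k-core 2, haircut on, fluff off."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False

    def __post_init__(self) -> None:
        if self.degree_cutoff < 1:
            raise ValueError("degree_cutoff must be >= 1")
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must be in [0, 1]")
        if self.fluff:
            raise NotImplementedError("fluff expansion is not supported (nodes stay in <=1 module)")


@dataclass(frozen=True)
class Module:
    """A detected dense module: member nodes, score = density x size, rank."""

    members: frozenset[str]
    score: float
    seed: str

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    overlap: int
    term_size: int
    query_size: int
    background_size: int
    p_value: float
    fdr: float


# ---------------------------------------------------------------------------
# Graph statistics
# ---------------------------------------------------------------------------

def graph_stats(g: nx.Graph) -> NetworkStats:
    """Node/edge counts, average degree 2E/N, and mean local clustering.

    Nodes of degree < 2 contribute a clustering coefficient of 0 to the mean
    (they are not excluded), which is the convention behind the usual
    "average local clustering coefficient" report.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph_stats requires a non-empty graph")
    n, e = g.number_of_nodes(), g.number_of_edges()
    return NetworkStats(
        n_nodes=n,
        n_edges=e,
        avg_degree=2.0 * e / n,
        avg_local_clustering=nx.average_clustering(g),
    )


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------

def _highest_kcore(sub: nx.Graph) -> tuple[int, nx.Graph]:
    """Return (k, subgraph) for the highest-k non-empty k-core of ``sub``."""
    if sub.number_of_nodes() == 0:
        return 0, sub
    core_nums = nx.core_number(sub)
    k = max(core_nums.values())
    core = sub.subgraph([v for v, c in core_nums.items() if c >= k])
    return k, core


def _density(sub: nx.Graph) -> float:
    n = sub.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * sub.number_of_edges() / (n * (n - 1))


def _vertex_weights(g: nx.Graph, degree_cutoff: int) -> dict[str, float]:
    """MCODE vertex weighting.

    For each node v with degree >= the cutoff, take the closed neighborhood
    N[v], extract its highest k-core, and weight v by k multiplied by the
    density of that core (the core-clustering coefficient).  Low-degree nodes
    weigh 0.
    """
    weights: dict[str, float] = {}
    for v in g:
        if g.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = g.subgraph([v, *g.neighbors(v)])
        k, core = _highest_kcore(nbhd)
        weights[v] = k * _density(core)
    return weights


def mcode(g: nx.Graph, params: McodeParams | None = None) -> list[Module]:
    """Detect densely connected modules with the MCODE procedure.

    Vertices are weighted by the highest-k-core density of their closed
    neighborhood; complexes grow greedily from the highest-weighted unused
    seed, admitting neighbors whose weight is at least
    ``(1 - node_score_cutoff)`` times the seed weight.  Each node belongs to
    at most one module.  Complexes that do not contain a ``k_core``-core are
    discarded; the optional haircut iteratively strips members with fewer
    than two connections inside the complex.  Modules are ranked by
    score = density x size (descending), ties broken by lexicographic seed id.
    """
    params = params or McodeParams()
    if g.number_of_nodes() == 0:
        return []
    weights = _vertex_weights(g, params.degree_cutoff)
    # deterministic seed order: weight desc, then node id
    order = sorted(g.nodes, key=lambda v: (-weights[v], str(v)))
    assigned: set[str] = set()
    modules: list[Module] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = (1.0 - params.node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for u in sorted(g.neighbors(v), key=str):
                if u in members or u in assigned:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    frontier.append(u)
        sub = g.subgraph(members).copy()
        # must contain at least a k-core of the requested order
        if not nx.k_core(sub, k=params.k_core):
            continue
        if params.haircut:
            while True:
                low = [v for v in sub if sub.degree(v) < 2]
                if not low or sub.number_of_nodes() - len(low) < 2:
                    break
                sub.remove_nodes_from(low)
        if sub.number_of_nodes() < 2:
            continue
        assigned.update(members)  # consumed even if trimmed by haircut
        modules.append(
            Module(
                members=frozenset(sub.nodes),
                score=_density(sub) * sub.number_of_nodes(),
                seed=seed,
            )
        )
    modules.sort(key=lambda m: (-m.score, str(m.seed)))
    return modules


# ---------------------------------------------------------------------------
# Co-expression
# ---------------------------------------------------------------------------

def _pearson_with_p(x: np.ndarray, others: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r of x against each row of ``others`` plus the
    two-tailed p from the t transform with n-2 degrees of freedom."""
    n = x.shape[0]
    xc = x - x.mean()
    oc = others - others.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc @ xc) * (oc * oc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (oc @ xc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(t) & ~np.isnan(r), 0.0, p)  # |r| == 1 exactly
    return r, p


def coexpression_partners(
    expr: pd.DataFrame,
    gene: str,
    r_thresh: float = 0.5,
    p_thresh: float = 0.01,
) -> frozenset[str]:
    """Genes whose expression correlates with ``gene`` at |r| > r_thresh and
    two-tailed p < p_thresh (t transform, n-2 df).

    ``expr`` is genes x samples.  The query gene itself is excluded.
    """
    if gene not in expr.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expr.loc[gene].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError(f"query gene {gene!r} has zero variance")
    others = expr.drop(index=gene)
    r, p = _pearson_with_p(x, others.to_numpy(dtype=float))
    keep = (np.abs(r) > r_thresh) & (p < p_thresh)
    return frozenset(others.index[keep])


def shared_partners(
    expr: pd.DataFrame,
    gene_a: str,
    gene_b: str,
    r_thresh: float = 0.5,
    p_thresh: float = 0.01,
) -> frozenset[str]:
    """Intersection of the co-expression partner sets of two query genes."""
    pa = coexpression_partners(expr, gene_a, r_thresh, p_thresh)
    if gene_a == gene_b:
        return pa
    pb = coexpression_partners(expr, gene_b, r_thresh, p_thresh)
    return (pa & pb) - {gene_a, gene_b}


def correlation_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Coefficient of determination: the squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.shape[0] < 3:
        raise ValueError("x and y must be equal-length vectors of length >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for constant input")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


# ---------------------------------------------------------------------------
# Overrepresentation
# ---------------------------------------------------------------------------

def enrichment(
    query: GeneSet,
    terms: Mapping[str, GeneSet],
    background: GeneSet,
) -> list[EnrichmentResult]:
    """Hypergeometric overrepresentation of ``query`` in each term set.

    p = P(X >= overlap) drawing |query| genes from a |background| population
    containing |term| successes; at overlap 0 the upper tail is 1 by
    convention.  FDR is Benjamini-Hochberg over all terms tested.  Results
    are sorted by p ascending, ties by term name.
    """
    if not query.genes <= background.genes:
        raise ValueError("query must be a subset of the background")
    for name, t in terms.items():
        if not t.genes <= background.genes:
            raise ValueError(f"term {name!r} not contained in the background")
    if not terms:
        return []
    N = len(background)
    n = len(query)
    names, pvals, rows = [], [], []
    for name in sorted(terms):
        K = len(terms[name])
        k = len(query.genes & terms[name].genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        names.append(name)
        pvals.append(min(p, 1.0))
        rows.append((name, k, K))
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            term=name, overlap=k, term_size=K, query_size=n,
            background_size=N, p_value=p, fdr=float(q),
        )
        for (name, k, K), p, q in zip(rows, pvals, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_edgelist_tsv(
    path: str | os.PathLike,
    confidence_threshold: float = 0.4,
) -> nx.Graph:
    """Read a 2- or 3-column TSV edge list.

    A third numeric column is an association confidence; edges at or below
    ``confidence_threshold`` are dropped (STRING-style medium-confidence
    filtering).  Self-loops are rejected.
    """
    g = nx.Graph()
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"line {i}: expected >=2 tab-separated columns")
        a, b = parts[0].strip(), parts[1].strip()
        if a == b:
            raise ValueError(f"line {i}: self-loop {a!r}")
        if len(parts) >= 3:
            w = float(parts[2])
            if w <= confidence_threshold:
                continue
            g.add_edge(a, b, weight=w)
        else:
            g.add_edge(a, b)
    return g


def write_edgelist_tsv(g: nx.Graph, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for a, b, data in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            if "weight" in data:
                fh.write(f"{a}\t{b}\t{data['weight']:g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def write_modules_tsv(modules: Iterable[Module], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("module_id\trank\tscore\tmembers\n")
        for rank, m in enumerate(modules, start=1):
            fh.write(f"M{rank}\t{rank}\t{m.score:.4f}\t{';'.join(sorted(m.members))}\n")


def write_enrichment_tsv(results: Iterable[EnrichmentResult], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("term\toverlap\tterm_size\tquery_size\tbackground_size\tp_value\tfdr\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.overlap}\t{r.term_size}\t{r.query_size}\t"
                f"{r.background_size}\t{r.p_value:.6g}\t{r.fdr:.6g}\n"
            )
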