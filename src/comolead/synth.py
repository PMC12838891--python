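"""Synthetic input generators for every stage of the pipeline.

The pipeline's real inputs — curated comorbidity gene panels, a
protein-association network, co-expression matrices, compound structures and
a docking-score table — are not deposited anywhere, so this module generates
stand-ins with the exact count/overlap/correlation structure the analysis
assumes: gene universes with a prescribed comorbidity/disease overlap,
graphs with planted dense modules, expression matrices with common-factor
correlated blocks, and a small catalog of molecules carrying specific
structural alerts.  All generators are pure functions of their spec: the
same seed yields byte-identical output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .docking import DockingRecord, packaged_table
from .genesets import GeneSet

__all__ = [
    "OverlapSpec",
    "PlantedGraphSpec",
    "ExprBlockSpec",
    "paper_overlap_spec",
    "make_gene_universe",
    "make_modular_graph",
    "make_expression_matrix",
    "make_alert_compounds",
    "table1_fixture",
    "write_expression_tsv",
    "write_compounds_smi",
]

#: Comorbidity panel labels and sizes of the thirteen contributing panels.
CONTRIBUTING_PANELS = (
    ("arrhythmia", 76),
    ("atrial_fibrillation", 43),
    ("chronic_kidney_disease", 164),
    ("heart_failure", 101),
    ("hypertension", 232),
    ("hypoxia", 471),
    ("inflammation", 593),
    ("oxidative_stress", 607),
    ("reactive_oxygen_species", 319),
    ("respiratory_control", 113),
    ("sleep_related_phenotypes", 120),
    ("stroke", 100),
    ("type_2_diabetes", 95),
)


@dataclass(frozen=True)
class OverlapSpec:
    """Counts that fix the comorbidity/disease gene-set geometry.

    ``pool_panel_sizes`` gives the per-comorbidity panel sizes; the panels
    are drawn from a shared universe of ``pool_universe_size`` symbols (the
    post-deduplication pool size), so panels overlap one another.  The
    disease set has ``osa_size`` genes of which exactly ``overlap_size``
    also occur in the pooled panels, and ``unique_retained`` of the
    disease-unique remainder are flagged for retention in the refined set.
    """

    pool_panel_sizes: tuple[int, ...]
    osa_size: int
    overlap_size: int
    unique_retained: int
    seed: int = 0
    pool_universe_size: int | None = None

    def __post_init__(self) -> None:
        if not self.pool_panel_sizes or any(s <= 0 for s in self.pool_panel_sizes):
            raise ValueError("pool_panel_sizes must be positive integers")
        if self.osa_size <= 0:
            raise ValueError("osa_size must be positive")
        if self.overlap_size < 0 or self.overlap_size > self.osa_size:
            raise ValueError("need 0 <= overlap_size <= osa_size")
        universe = self.universe_size
        if universe < max(self.pool_panel_sizes):
            raise ValueError("pool universe smaller than the largest panel")
        if self.overlap_size > universe:
            raise ValueError("overlap_size exceeds the pool universe")
        if self.unique_retained < 0 or self.unique_retained > self.osa_size - self.overlap_size:
            raise ValueError("need 0 <= unique_retained <= osa_size - overlap_size")

    @property
    def universe_size(self) -> int:
        if self.pool_universe_size is not None:
            return self.pool_universe_size
        return sum(self.pool_panel_sizes)


def paper_overlap_spec(seed: int = 0) -> OverlapSpec:
    """The packaged default geometry: thirteen contributing panels, a
    2460-symbol deduplicated pool, a 102-gene disease set overlapping the
    pool in 58 genes, and 8 retained disease-unique genes (refined set 66)."""
    return OverlapSpec(
        pool_panel_sizes=tuple(s for _, s in CONTRIBUTING_PANELS),
        osa_size=102,
        overlap_size=58,
        unique_retained=8,
        seed=seed,
        pool_universe_size=2460,
    )


def make_gene_universe(
    spec: OverlapSpec,
) -> tuple[list[GeneSet], GeneSet, dict[str, str]]:
    """Generate comorbidity panels, the disease set, and the provenance truth.

    Symbols are synthetic and role-coded: ``CMG####`` for pool genes,
    ``OSA###`` for disease-unique genes.  The truth map labels each disease
    gene ``comorbidity_overlap``, ``osa_unique_retained`` or
    ``osa_unique_dropped``; the refined-set ground truth is the union of the
    first two classes.
    """
    rng = np.random.default_rng(spec.seed)
    universe = np.array([f"CMG{i:04d}" for i in range(spec.universe_size)])
    names = (
        [name for name, _ in CONTRIBUTING_PANELS]
        if len(spec.pool_panel_sizes) == len(CONTRIBUTING_PANELS)
        else [f"comorbidity_{i+1}" for i in range(len(spec.pool_panel_sizes))]
    )
    panels = []
    for name, size in zip(names, spec.pool_panel_sizes):
        members = rng.choice(universe, size=size, replace=False)
        panels.append(GeneSet(name=name, genes=frozenset(members), source="comorbidity"))
    pool_union = sorted(set().union(*(p.genes for p in panels)))
    if spec.overlap_size > len(pool_union):
        raise ValueError(
            f"overlap_size {spec.overlap_size} exceeds the realized panel union "
            f"({len(pool_union)} genes)"
        )
    shared = rng.choice(np.array(pool_union), size=spec.overlap_size, replace=False)
    n_unique = spec.osa_size - spec.overlap_size
    unique = [f"OSA{i:03d}" for i in range(n_unique)]
    retained = set(rng.choice(np.array(unique), size=spec.unique_retained, replace=False)) if unique else set()
    truth: dict[str, str] = {g: "comorbidity_overlap" for g in shared}
    for g in unique:
        truth[g] = "osa_unique_retained" if g in retained else "osa_unique_dropped"
    osa = GeneSet(name="osa", genes=frozenset(truth), source="osa")
    return panels, osa, truth


@dataclass(frozen=True)
class PlantedGraphSpec:
    """A planted-partition graph: ``n_modules`` blocks of ``module_size``
    nodes, intra-module edge probability ``p_in``, inter-module ``p_out``."""

    n_modules: int
    module_size: int
    p_in: float
    p_out: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 1 or self.module_size < 3:
            raise ValueError("need n_modules >= 1 and module_size >= 3")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")


def make_modular_graph(spec: PlantedGraphSpec) -> nx.Graph:
    """Planted-module graph with node ids ``M{module}_N{index}``; node
    attribute ``module`` records the planted block."""
    rng = np.random.default_rng(spec.seed)
    g = nx.Graph()
    nodes = []
    for m in range(spec.n_modules):
        for i in range(spec.module_size):
            v = f"M{m}_N{i:02d}"
            g.add_node(v, module=m)
            nodes.append((v, m))
    for i, (u, mu) in enumerate(nodes):
        for v, mv in nodes[i + 1:]:
            p = spec.p_in if mu == mv else spec.p_out
            if p == 1.0 or (p > 0.0 and rng.random() < p):
                g.add_edge(u, v)
    return g


@dataclass(frozen=True)
class ExprBlockSpec:
    """Correlated-block expression matrix spec.

    Each block shares one latent factor: for correlation rho and unit-sd
    noise, gene = sqrt(rho) * factor + sqrt(1-rho) * noise_sd * eps, giving
    expected within-block Pearson r of rho / (rho + (1-rho) * noise_sd^2)
    — exactly ``block_correlation`` at the default noise_sd of 1.
    """

    n_genes: int
    n_samples: int
    block_assignments: Mapping[str, int] = field(default_factory=dict)
    block_correlation: float | Mapping[int, float] = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("need n_samples >= 3")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.block_assignments:
            if len(self.block_assignments) != self.n_genes:
                raise ValueError("every gene must be assigned to exactly one block")
        rhos = (self.block_correlation.values()
                if isinstance(self.block_correlation, Mapping)
                else [self.block_correlation])
        if any(not 0.0 <= r < 1.0 for r in rhos):
            raise ValueError("block correlations must lie in [0, 1)")

    def assignments(self) -> dict[str, int]:
        if self.block_assignments:
            return dict(self.block_assignments)
        return {f"G{i:04d}": 0 for i in range(self.n_genes)}

    def rho(self, block: int) -> float:
        if isinstance(self.block_correlation, Mapping):
            return self.block_correlation.get(block, 0.0)
        return self.block_correlation


def make_expression_matrix(spec: ExprBlockSpec) -> pd.DataFrame:
    """Genes x samples matrix with common-factor correlated blocks."""
    rng = np.random.default_rng(spec.seed)
    assign = spec.assignments()
    blocks = sorted(set(assign.values()))
    factors = {b: rng.standard_normal(spec.n_samples) for b in blocks}
    rows = {}
    for gene in assign:  # insertion order: deterministic
        b = assign[gene]
        rho = spec.rho(b)
        eps = rng.standard_normal(spec.n_samples)
        rows[gene] = (np.sqrt(rho) * factors[b]
                      + np.sqrt(1.0 - rho) * spec.noise_sd * eps)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"S{j:03d}" for j in range(spec.n_samples)])


#: (name, SMILES, expected alert names) — alert-bearing molecules + controls.
_ALERT_COMPOUNDS = (
    ("tetramethylammonium", "C[N+](C)(C)C", ("quaternary_nitrogen",)),
    ("methyl_vinyl_ketone", "C=CC(C)=O", ("michael_acceptor",)),
    ("trans_stilbene", "c1ccc(/C=C/c2ccccc2)cc1", ("stilbene",)),
    ("ethanol", "CCO", ()),
    ("benzene", "c1ccccc1", ()),
    ("melatonin", "CC(=O)NCCc1c[nH]c2ccc(OC)cc12", ()),
)


def make_alert_compounds() -> list[tuple[str, str, tuple[str, ...]]]:
    """Catalog of (name, SMILES, expected alerts): at least one molecule per
    packaged structural alert plus alert-free controls."""
    return [(n, s, a) for n, s, a in _ALERT_COMPOUNDS]


def table1_fixture() -> list[DockingRecord]:
    """The packaged 20-row docking-score table (compound, kinase target,
    Vina score in kcal/mol, cavity volume in cubic Angstrom)."""
    return packaged_table()


def write_expression_tsv(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def write_compounds_smi(path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, smiles, _ in make_alert_compounds():
            fh.write(f"{smiles}\t{name}\n")
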