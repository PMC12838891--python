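"""Comorbidity gene-panel aggregation and refined-set construction.

The refinement step pools gene panels collected for individual comorbidities
of a disease of interest, intersects the pooled panel with the disease's own
gene set, and combines the intersection with an explicitly supplied subset of
disease-unique genes to form a *refined set*.  Every gene in the refined set
carries provenance: either it entered through the comorbidity overlap or it
was retained as disease-unique.  The refined set is the substrate of the
downstream protein-association network analysis.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GeneSet",
    "RefinedSet",
    "PHENOTYPE_LABELS",
    "aggregate_pool",
    "refine_set",
    "assign_phenotypes",
    "read_gmt",
    "write_gmt",
    "read_panel_tsv",
    "write_panel_tsv",
    "read_refined_tsv",
    "write_refined_tsv",
]

#: The seven sleep-phenotype labels used to annotate the refined set.
PHENOTYPE_LABELS = (
    "apnea_hs-rev17",
    "daytime_sleepiness_hs-rev2",
    "intrathoracic_hs-rev2",
    "obstructive_sleep_apnea_hs-rev3",
    "sleep_apnea_hs-rev5",
    "sleep_disorder_hs-rev68",
    "sleep_fragmentation_hs-rev5",
)

_SOURCES = ("comorbidity", "osa", "derived")


def _normalize(symbols: Iterable[str]) -> frozenset[str]:
    """Upper-case and strip symbols; mixed-case collisions collapse."""
    out = set()
    for s in symbols:
        s = str(s).strip().upper()
        if not s:
            raise ValueError("empty gene symbol after normalization")
        out.add(s)
    return frozenset(out)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with a source tag.

    Symbols are case-normalized (upper-cased, whitespace-stripped) at
    construction so that downstream set arithmetic is symbol-safe.
    """

    name: str
    genes: frozenset[str]
    source: str = "derived"

    def __post_init__(self) -> None:
        if self.source not in _SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {_SOURCES}")
        object.__setattr__(self, "genes", _normalize(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().upper() in self.genes


@dataclass
class RefinedSet:
    """Refined gene set with per-gene provenance and optional phenotypes.

    ``provenance`` maps every member symbol to ``"comorbidity_overlap"`` or
    ``"osa_unique"``; the two classes partition the set.
    """

    genes: frozenset[str]
    provenance: dict[str, str]
    phenotype_assignment: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.provenance) != set(self.genes):
            raise ValueError("provenance must be defined for exactly the member genes")
        bad = {v for v in self.provenance.values()} - {"comorbidity_overlap", "osa_unique"}
        if bad:
            raise ValueError(f"unknown provenance classes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_overlap(self) -> int:
        return sum(1 for v in self.provenance.values() if v == "comorbidity_overlap")

    @property
    def n_unique(self) -> int:
        return sum(1 for v in self.provenance.values() if v == "osa_unique")


def aggregate_pool(panels: list[GeneSet]) -> tuple[GeneSet, pd.DataFrame]:
    """Union comorbidity panels into a deduplicated pool with a contribution report.

    Returns the pooled :class:`GeneSet` and a per-panel report with the raw
    panel size and the number of genes appearing in no other panel
    (``unique_contribution``).  Panels contributing zero unique genes are
    flagged, mirroring the exclusion of non-contributing comorbidities from
    the aggregated pool.
    """
    if not panels:
        raise ValueError("aggregate_pool requires at least one panel")
    for p in panels:
        if p.source != "comorbidity":
            raise ValueError(f"panel {p.name!r} has source {p.source!r}, expected 'comorbidity'")

    membership: Counter[str] = Counter()
    for p in panels:
        membership.update(p.genes)
    pool = GeneSet(
        name="comorbidity_pool",
        genes=frozenset(membership),
        source="derived",
    )
    rows = []
    for p in panels:
        unique = sum(1 for g in p.genes if membership[g] == 1)
        rows.append(
            {
                "panel": p.name,
                "size": len(p),
                "unique_contribution": unique,
                "zero_unique": unique == 0,
            }
        )
    report = pd.DataFrame(rows, columns=["panel", "size", "unique_contribution", "zero_unique"])
    return pool, report


def refine_set(
    pool: GeneSet,
    osa: GeneSet,
    unique_retained: Iterable[str] | str = "all",
) -> RefinedSet:
    """Build the refined set: (osa ∩ pool) plus an explicit disease-unique subset.

    ``unique_retained`` is either the sentinel ``"all"`` (keep every
    disease-unique gene) or an iterable of symbols that must lie in
    ``osa \\ pool``.  The retained subset is an explicit argument because the
    filter that selects which disease-unique genes survive is a curation
    decision, not a computation.
    """
    overlap = osa.genes & pool.genes
    osa_unique = osa.genes - pool.genes
    if isinstance(unique_retained, str) and unique_retained == "all":
        retained = osa_unique
    else:
        retained = _normalize(unique_retained) if unique_retained else frozenset()
        stray = retained - osa.genes
        if stray:
            raise ValueError(f"retained symbols not in the disease set: {sorted(stray)}")
        in_pool = retained & pool.genes
        if in_pool:
            raise ValueError(
                f"retained symbols already in the comorbidity pool: {sorted(in_pool)}"
            )
    provenance = {g: "comorbidity_overlap" for g in overlap}
    provenance.update({g: "osa_unique" for g in retained})
    return RefinedSet(genes=frozenset(provenance), provenance=provenance)


def assign_phenotypes(
    refined: RefinedSet,
    phenotype_map: Mapping[str, Iterable[str]],
) -> tuple[RefinedSet, dict[str, int], frozenset[str]]:
    """Annotate refined genes with phenotype labels.

    ``phenotype_map`` maps a phenotype label to the symbols it covers (these
    must be a subset of the refined set or they are ignored as out-of-set).
    Returns the annotated set, a per-phenotype tally (a gene belonging to k
    phenotypes counts once in each of the k tallies), and the uncovered genes.
    """
    normalized = {ph: _normalize(genes) if genes else frozenset() for ph, genes in phenotype_map.items()}
    assignment: dict[str, list[str]] = {}
    tally: dict[str, int] = {}
    for ph, genes in normalized.items():
        covered = genes & refined.genes
        tally[ph] = len(covered)
        for g in covered:
            assignment.setdefault(g, []).append(ph)
    annotated = RefinedSet(
        genes=refined.genes,
        provenance=dict(refined.provenance),
        phenotype_assignment={g: tuple(sorted(v)) for g, v in assignment.items()},
    )
    uncovered = refined.genes - set(assignment)
    return annotated, tally, frozenset(uncovered)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, member symbols)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line needs >=3 tab-separated fields: {line!r}")
        name, _desc, *genes = parts
        sets.append(GeneSet(name=name, genes=frozenset(g for g in genes if g.strip()),
                            source="comorbidity"))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | os.PathLike, description: str = "na") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *sorted(s.genes)]) + "\n")


def read_panel_tsv(path: str | os.PathLike, source: str = "comorbidity") -> GeneSet:
    """Read a one-symbol-per-line panel with a ``#name=`` header."""
    name = Path(path).stem
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#name="):
            name = line[len("#name="):].strip()
        elif not line.startswith("#"):
            genes.append(line)
    return GeneSet(name=name, genes=frozenset(genes), source=source)


def write_panel_tsv(panel: GeneSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"#name={panel.name}\n")
        for g in sorted(panel.genes):
            fh.write(g + "\n")


def write_refined_tsv(refined: RefinedSet, path: str | os.PathLike) -> None:
    """Write symbol, provenance, phenotypes (semicolon-joined) as TSV."""
    with open(path, "w") as fh:
        fh.write("symbol\tprovenance\tphenotypes\n")
        for g in sorted(refined.genes):
            phenos = ";".join(refined.phenotype_assignment.get(g, ()))
            fh.write(f"{g}\t{refined.provenance[g]}\t{phenos}\n")


def read_refined_tsv(path: str | os.PathLike) -> RefinedSet:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    provenance = dict(zip(df["symbol"], df["provenance"]))
    assignment = {
        g: tuple(p.split(";"))
        for g, p in zip(df["symbol"], df["phenotypes"])
        if p
    }
    return RefinedSet(
        genes=frozenset(provenance),
        provenance=provenance,
        phenotype_assignment=assignment,
    )
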