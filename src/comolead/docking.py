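"""Docking-score table ingestion and comparative binding arithmetic.

Consumes tables of AutoDock-Vina scores (kcal/mol; more negative = stronger
predicted binding) for a compound series against the two kinase targets CK1δ
(PDB 3UYS) and PINK1 (PDB 5OAT), and answers the comparative questions a
lead-optimization campaign asks: best binder per target, binding-energy
improvement of a derivative over its reference, and the balanced dual-target
ranking across the series.  Docking itself is never run here.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "RT_KCAL_MOL",
    "TARGETS",
    "GENERATIONS",
    "DockingRecord",
    "ImprovementReport",
    "load_table",
    "packaged_table",
    "best_binder",
    "improvement",
    "dual_summary",
]

#: RT at 298.15 K in kcal/mol (R = 1.98720425e-3 kcal/(mol.K)).
RT_KCAL_MOL = 0.5925

#: target label -> PDB code
TARGETS = {"CK1D": "3UYS", "PINK1": "5OAT"}

_TARGET_ALIASES = {
    "CK1D": "CK1D", "CK1DELTA": "CK1D", "CK1δ": "CK1D", "CK1Δ": "CK1D",
    "3UYS": "CK1D", "CSNK1D": "CK1D",
    "PINK1": "PINK1", "5OAT": "PINK1",
}

#: compound code -> design generation
GENERATIONS = {
    "GLA": "natural", "LIC": "natural", "LID": "natural", "MLT": "natural",
    "IC261": "reference", "PF670462": "reference",
    "ICLID": "second_gen", "PFLID": "second_gen",
    "ICL": "third_gen", "PFL": "third_gen",
}

_COMPOUND_ALIASES = {"PF-670462": "PF670462", "ICL-81": "ICL", "ICL-89": "ICL",
                     "PFL-112": "PFL", "ICLID85": "ICLID", "PFLID98": "PFLID"}


def normalize_target(label: str) -> str:
    key = _TARGET_ALIASES.get(label.strip().upper())
    if key is None:
        raise ValueError(f"unknown target label {label!r}")
    return key


def normalize_compound(code: str) -> str:
    code = code.strip()
    return _COMPOUND_ALIASES.get(code, code.upper())


@dataclass(frozen=True)
class DockingRecord:
    """One docking result row: compound vs target with Vina score and the
    search-cavity volume."""

    compound: str
    target: str
    vina_score: float  # kcal/mol; negative favourable
    pocket_volume: float  # cubic Angstrom
    generation: str = "natural"

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.pocket_volume <= 0:
            raise ValueError("pocket_volume must be positive")

    @property
    def favorable(self) -> bool:
        return self.vina_score < 0


@dataclass(frozen=True)
class ImprovementReport:
    """Binding-energy improvement of ``compound`` over ``reference``.

    ``delta`` = vina(reference) - vina(compound) in kcal/mol; positive means
    the compound binds more strongly.  ``fold_ki_estimate`` = exp(|delta|/RT)
    is the implied multiplicative change in the inhibition constant.
    """

    compound: str
    reference: str
    target: str
    delta: float
    fold_ki_estimate: float

    @property
    def delta_1dp(self) -> float:
        """Delta rounded to the 1-decimal reporting convention."""
        return round(self.delta, 1)


def load_table(path: str | os.PathLike, generations: dict[str, str] | None = None) -> list[DockingRecord]:
    """Parse a docking CSV with header compound,target,vina_kcal_mol,volume_A3.

    Generation labels are inferred from the packaged compound-code map,
    overridable via ``generations``.  Row-level problems raise with the line
    number; a non-negative score is kept but flagged via ``favorable``.
    """
    genmap = dict(GENERATIONS)
    if generations:
        genmap.update({normalize_compound(k): v for k, v in generations.items()})
    records: list[DockingRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"compound", "target", "vina_kcal_mol", "volume_A3"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"docking CSV must have header columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            try:
                compound = normalize_compound(row["compound"])
                target = normalize_target(row["target"])
                score = float(row["vina_kcal_mol"])
                volume = float(row["volume_A3"])
            except (ValueError, KeyError) as exc:
                raise ValueError(f"line {i}: {exc}") from exc
            records.append(
                DockingRecord(
                    compound=compound, target=target, vina_score=score,
                    pocket_volume=volume,
                    generation=genmap.get(compound, "natural"),
                )
            )
    if not records:
        raise ValueError("docking table contains no data rows")
    return records


def packaged_table() -> list[DockingRecord]:
    """The packaged 20-row docking-score table for the ten-compound series."""
    with resources.as_file(resources.files("comolead") / "data" / "docking_scores.csv") as p:
        return load_table(p)


def best_binder(
    records: list[DockingRecord],
    target: str,
    subset: str | None = None,
) -> DockingRecord:
    """Most negative Vina score for ``target``; ``subset`` filters by
    generation.  Ties break lexicographically on the compound code."""
    target = normalize_target(target)
    pool = [r for r in records if r.target == target]
    if subset is not None:
        pool = [r for r in pool if r.generation == subset]
    if not pool:
        raise ValueError(f"no records for target {target!r} (subset={subset!r})")
    return min(pool, key=lambda r: (r.vina_score, r.compound))


def _lookup(records: list[DockingRecord], compound: str, target: str) -> DockingRecord:
    hits = [r for r in records if r.compound == compound and r.target == target]
    if not hits:
        raise ValueError(f"no record for compound {compound!r} on target {target!r}")
    return hits[0]


def improvement(
    records: list[DockingRecord],
    compound: str,
    reference: str,
    target: str,
) -> ImprovementReport:
    """Binding-energy delta of ``compound`` relative to ``reference``."""
    target = normalize_target(target)
    compound = normalize_compound(compound)
    reference = normalize_compound(reference)
    rc = _lookup(records, compound, target)
    rr = _lookup(records, reference, target)
    delta = rr.vina_score - rc.vina_score
    return ImprovementReport(
        compound=compound, reference=reference, target=target,
        delta=delta, fold_ki_estimate=math.exp(abs(delta) / RT_KCAL_MOL),
    )


def dual_summary(records: list[DockingRecord]) -> pd.DataFrame:
    """Per-compound dual-target table ranked by balanced binding.

    Compounds with scores on both targets get ``worse_of_two`` = the larger
    (less favourable) of the two scores; sorting that column ascending puts
    the best balanced dual binder first.  Single-target compounds are flagged
    and left unranked.
    """
    by_compound: dict[str, dict[str, DockingRecord]] = {}
    for r in records:
        by_compound.setdefault(r.compound, {})[r.target] = r
    rows = []
    for compound in sorted(by_compound):
        recs = by_compound[compound]
        ck = recs.get("CK1D")
        pk = recs.get("PINK1")
        both = ck is not None and pk is not None
        rows.append(
            {
                "compound": compound,
                "generation": next(iter(recs.values())).generation,
                "ck1d_score": ck.vina_score if ck else float("nan"),
                "pink1_score": pk.vina_score if pk else float("nan"),
                "worse_of_two": max(ck.vina_score, pk.vina_score) if both else float("nan"),
                "dual": both,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["dual", "worse_of_two", "compound"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df
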