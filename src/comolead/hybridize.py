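"""Scaffold hybridization: port detection, linker-based merging, 3D embedding.

A hybrid inhibitor is built by joining two parent scaffolds at *connection
ports* — substructure-defined sites where a substituent (e.g. a methoxy
group) is removed or an aromatic C-H is substituted — either directly or
through a small spacer fragment.  Merging forms single bonds only, removes
the detachable atoms, re-perceives aromaticity, and verifies valences and
connectivity, so every emitted hybrid is a chemically sane single-component
molecule.  3D coordinates come from distance-geometry embedding followed by
UFF minimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import canonical_smiles, mol_from_smiles

__all__ = [
    "PortSpec",
    "Port",
    "Linker",
    "PORT_LIBRARY",
    "LINKER_LIBRARY",
    "EmbedResult",
    "find_ports",
    "merge_scaffolds",
    "embed_3d",
    "min_nonbonded_distance",
    "parent_catalog",
    "hybrid_reconstructions",
]


@dataclass(frozen=True)
class PortSpec:
    """A connection-port definition.

    ``pattern`` is a SMARTS substructure; ``attach`` indexes the matched atom
    that becomes the new bond site and ``detach`` the matched atoms removed
    at merge time.  The attach atom must not be detached.
    """

    name: str
    pattern: str
    attach: int = 0
    detach: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.attach in self.detach:
            raise ValueError("attach atom cannot be detached")
        if Chem.MolFromSmarts(self.pattern) is None:
            raise ValueError(f"invalid port pattern {self.pattern!r}")


@dataclass(frozen=True)
class Port:
    """A concrete port site on a molecule: attach-atom index plus the atom
    indices removed when the port is used."""

    attach_atom: int
    detach_atoms: tuple[int, ...]
    spec_name: str


@dataclass(frozen=True)
class Linker:
    """A spacer fragment with exactly two open attachment points, written as
    SMILES with two dummy atoms ([*:1] ... [*:2])."""

    name: str
    smiles: str

    def fragment(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValueError(f"invalid linker SMILES {self.smiles!r}")
        dummies = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 2:
            raise ValueError(f"linker {self.name!r} must have exactly two attachment points")
        return mol

    @property
    def n_heavy(self) -> int:
        return sum(1 for a in self.fragment().GetAtoms() if a.GetAtomicNum() > 1)


#: Packaged port definitions; extensible by constructing PortSpec directly.
PORT_LIBRARY: dict[str, PortSpec] = {
    "methoxy": PortSpec("methoxy", "[c][OX2][CH3]", attach=0, detach=(1, 2)),
    "aromatic_ch": PortSpec("aromatic_ch", "[cH]", attach=0, detach=()),
    "carboxyl": PortSpec("carboxyl", "[#6][CX3](=[OX1])[OX2H1]", attach=0, detach=(1, 2, 3)),
    "phenol_oh": PortSpec("phenol_oh", "[c][OX2H1]", attach=1, detach=()),
}

#: Packaged spacer fragments.
LINKER_LIBRARY: dict[str, Linker] = {
    "methylene": Linker("methylene", "[*:1]C[*:2]"),
    "ethylene": Linker("ethylene", "[*:1]CC[*:2]"),
    "ether": Linker("ether", "[*:1]OC[*:2]"),
    "amide": Linker("amide", "[*:1]C(=O)N[*:2]"),
}


def find_ports(mol: Chem.Mol, spec: PortSpec) -> list[Port]:
    """All non-overlapping port sites for ``spec`` on ``mol``.

    Overlapping substructure matches are resolved greedily in ascending
    atom-index order; sites are returned sorted by attach-atom index.
    """
    patt = Chem.MolFromSmarts(spec.pattern)
    matches = sorted(mol.GetSubstructMatches(patt, uniquify=True))
    used: set[int] = set()
    ports = []
    for match in matches:
        if used & set(match):
            continue
        used.update(match)
        ports.append(
            Port(
                attach_atom=match[spec.attach],
                detach_atoms=tuple(match[i] for i in spec.detach),
                spec_name=spec.name,
            )
        )
    ports.sort(key=lambda p: p.attach_atom)
    return ports


def merge_scaffolds(
    mol_a: Chem.Mol,
    port_a: Port,
    mol_b: Chem.Mol,
    port_b: Port,
    linker: Linker | str = "direct",
) -> Chem.Mol:
    """Join two parents at their ports, directly or through a linker.

    Detachable atoms are removed, single bonds are formed
    attachA-linker-attachB (or attachA-attachB when direct), and the result
    is sanitized.  Self-merging (the same molecule object on both sides) is
    rejected; a valence violation or a disconnected product raises.
    """
    if mol_a is mol_b:
        raise ValueError("self-merging a molecule with itself is not allowed")
    combined = Chem.RWMol(Chem.CombineMols(mol_a, mol_b))
    off_b = mol_a.GetNumAtoms()
    attach_a = port_a.attach_atom
    attach_b = port_b.attach_atom + off_b
    to_remove = list(port_a.detach_atoms) + [i + off_b for i in port_b.detach_atoms]

    if isinstance(linker, str):
        if linker != "direct":
            raise ValueError("linker must be a Linker or the string 'direct'")
        bonds = [(attach_a, attach_b)]
    else:
        frag = linker.fragment()
        off_l = combined.GetNumAtoms()
        combined = Chem.RWMol(Chem.CombineMols(combined, frag))
        dummies = [a.GetIdx() + off_l for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
        ends = []
        for d in dummies:
            nbrs = [n.GetIdx() for n in combined.GetAtomWithIdx(d).GetNeighbors()]
            ends.append(nbrs[0])
        bonds = [(attach_a, ends[0]), (ends[1], attach_b)]
        to_remove.extend(dummies)

    for i, j in bonds:
        combined.AddBond(i, j, Chem.BondType.SINGLE)
    combined.BeginBatchEdit()
    for idx in to_remove:
        combined.RemoveAtom(idx)
    combined.CommitBatchEdit()

    product = combined.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Chem.AtomValenceException as exc:
        raise ValueError(f"valence violation after merge: {exc}") from exc
    if len(Chem.GetMolFrags(product)) != 1:
        raise RuntimeError("merge produced a disconnected molecule")
    name_a = mol_a.GetProp("_Name") if mol_a.HasProp("_Name") else "A"
    name_b = mol_b.GetProp("_Name") if mol_b.HasProp("_Name") else "B"
    product.SetProp("_Name", f"{name_a}+{name_b}")
    # round-trip through the canonical string form for a clean graph
    return mol_from_smiles(canonical_smiles(product), product.GetProp("_Name"))


@dataclass
class EmbedResult:
    mol: Chem.Mol  # with explicit hydrogens; conformer 0 holds coordinates
    success: bool
    message: str = ""


def embed_3d(mol: Chem.Mol, seed: int = 0) -> EmbedResult:
    """Distance-geometry 3D embedding (ETKDG) plus UFF minimization.

    Deterministic for a given seed.  Embedding failure is reported in the
    result rather than raised, so batch pipelines can continue.
    """
    molh = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    conf_id = AllChem.EmbedMolecule(molh, params)
    if conf_id < 0:
        return EmbedResult(mol=molh, success=False, message="distance-geometry embedding failed")
    try:
        AllChem.UFFOptimizeMolecule(molh, maxIters=500)
    except Exception as exc:  # force-field setup failure
        return EmbedResult(mol=molh, success=False, message=f"UFF minimization failed: {exc}")
    return EmbedResult(mol=molh, success=True)


def min_nonbonded_distance(mol: Chem.Mol) -> float:
    """Smallest interatomic distance (Angstrom) between non-bonded atom pairs."""
    conf = mol.GetConformer()
    pos = conf.GetPositions()
    n = mol.GetNumAtoms()
    bonded = {(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()}
    bonded |= {(j, i) for i, j in bonded}
    best = np.inf
    for i in range(n):
        d = np.linalg.norm(pos[i + 1:] - pos[i], axis=1)
        for k, dist in enumerate(d, start=i + 1):
            if (i, k) not in bonded:
                best = min(best, dist)
    return float(best)


# ---------------------------------------------------------------------------
# Packaged parents and stand-in hybrids
# ---------------------------------------------------------------------------

def parent_catalog() -> dict[str, Chem.Mol]:
    """Public-structure parents used to demonstrate hybridization.

    IC261 (benzofuran-class CK1δ inhibitor, trimethoxyphenyl oxindole),
    PF-670462 (imidazole/pyrimidin-amine dual CK1δ/ε inhibitor), and a
    simplified 2-aryl-indazole phenol standing in for the nigellidine
    alkaloid scaffold (synthetic stand-in: the alkaloid's full fused ring
    system is not reproduced).
    """
    return {
        "IC261": mol_from_smiles(
            "COc1cc(OC)c(C=C2C(=O)Nc3ccccc23)c(OC)c1", "IC261"
        ),
        "PF670462": mol_from_smiles(
            "Nc1nccc(-c2c(-c3ccc(F)cc3)ncn2C2CCCCC2)n1", "PF670462"
        ),
        "nigellidine_scaffold": mol_from_smiles(
            "Oc1ccc(-n2cc3ccccc3n2)cc1", "nigellidine_scaffold"
        ),
    }


def hybrid_reconstructions(seed: int = 7) -> dict[str, Chem.Mol]:
    """Synthetic stand-in hybrids for the unpublished designed inhibitors.

    The published hybrids have no public structures; these reconstructions
    merge the named public parents through the packaged ports/linkers purely
    to exercise the pipeline, and claim no fidelity to the originals.
    """
    parents = parent_catalog()
    ic, pf, lid = (parents["IC261"], parents["PF670462"],
                   parents["nigellidine_scaffold"])
    iclid_like = merge_scaffolds(
        ic, find_ports(ic, PORT_LIBRARY["methoxy"])[0],
        lid, find_ports(lid, PORT_LIBRARY["aromatic_ch"])[0],
        "direct",
    )
    iclid_like.SetProp("_Name", "ICLID_standin")
    pflid_like = merge_scaffolds(
        pf, find_ports(pf, PORT_LIBRARY["aromatic_ch"])[0],
        lid, find_ports(lid, PORT_LIBRARY["aromatic_ch"])[0],
        LINKER_LIBRARY["ethylene"],
    )
    pflid_like.SetProp("_Name", "PFLID_standin")
    return {"ICLID_standin": iclid_like, "PFLID_standin": pflid_like}
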