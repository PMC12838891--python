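"""Small-molecule parsing and serialization helpers (RDKit-backed)."""

from __future__ import annotations

import os
from typing import Iterable

from rdkit import Chem

__all__ = [
    "mol_from_smiles",
    "canonical_smiles",
    "read_smiles_file",
    "write_smiles_file",
    "read_sdf",
    "write_sdf",
]


def mol_from_smiles(smiles: str, name: str | None = None) -> Chem.Mol:
    """Parse and sanitize a SMILES string; raises ValueError on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if name is not None:
        mol.SetProp("_Name", name)
    return mol


def canonical_smiles(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def read_smiles_file(path: str | os.PathLike) -> list[Chem.Mol]:
    """One SMILES per line, optional whitespace-separated name."""
    mols = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else None
            mols.append(mol_from_smiles(smiles, name))
    return mols


def write_smiles_file(mols: Iterable[Chem.Mol], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for mol in mols:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            fh.write(f"{Chem.MolToSmiles(mol)}\t{name}".rstrip() + "\n")


def read_sdf(path: str | os.PathLike) -> list[Chem.Mol]:
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    mols = [m for m in supplier if m is not None]
    if not mols:
        raise ValueError(f"no parseable molecules in {path}")
    return mols


def write_sdf(mols: Iterable[Chem.Mol], path: str | os.PathLike) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for mol in mols:
            writer.write(mol)
    finally:
        writer.close()
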