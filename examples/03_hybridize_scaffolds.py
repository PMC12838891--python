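"""Merge two parent scaffolds into a hybrid through a connection port.

Detects a methoxy port on the first parent (the methoxy is removed and its
ring carbon becomes the bond site), an aromatic C-H port on the second, and
joins them through an ethylene linker; then embeds 3D coordinates.
"""

from comolead.chem import canonical_smiles, mol_from_smiles
from comolead.hybridize import (
    LINKER_LIBRARY, PORT_LIBRARY, embed_3d, find_ports, merge_scaffolds,
    parent_catalog,
)

parents = parent_catalog()
ic261 = parents["IC261"]
scaffold = parents["nigellidine_scaffold"]

ports_a = find_ports(ic261, PORT_LIBRARY["methoxy"])
ports_b = find_ports(scaffold, PORT_LIBRARY["aromatic_ch"])
print(f"IC261 methoxy ports: {len(ports_a)}; scaffold aromatic C-H ports: {len(ports_b)}")

hybrid = merge_scaffolds(ic261, ports_a[0], scaffold, ports_b[0],
                         LINKER_LIBRARY["ethylene"])
print(f"hybrid: {canonical_smiles(hybrid)}")
print(f"heavy atoms: {ic261.GetNumHeavyAtoms()} + {scaffold.GetNumHeavyAtoms()}"
      f" + 2 (linker) - 2 (detached OCH3) = {hybrid.GetNumHeavyAtoms()}")

res = embed_3d(hybrid, seed=11)
print(f"3D embedding: success={res.success}, atoms with H: {res.mol.GetNumAtoms()}")
# The hybrid keeps both parents' pharmacophores on a single valence-valid
# molecular graph, ready for export to SDF and downstream docking.
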