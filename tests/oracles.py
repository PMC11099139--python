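"""Brute-force oracles kept independent of the implementation paths.

The scaffold oracle never calls the package's scaffold code: it prunes the
molecular graph directly — iteratively deleting terminal (single-neighbor)
atoms that are not in a ring, then restoring atoms multiply-bonded to the
surviving ring/linker skeleton — and canonicalizes the remainder.
"""

from rdkit import Chem


def murcko_scaffold_oracle(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    ring_atoms = {a.GetIdx() for a in mol.GetAtoms() if a.IsInRing()}
    if not ring_atoms:
        return ""
    adjacency = {
        a.GetIdx(): {n.GetIdx() for n in a.GetNeighbors()} for a in mol.GetAtoms()
    }
    keep = set(adjacency)
    changed = True
    while changed:
        changed = False
        for idx in sorted(keep):
            if idx in ring_atoms:
                continue
            if len(adjacency[idx] & keep) <= 1:
                keep.discard(idx)
                changed = True
    # restore atoms attached to the skeleton through a multiple bond
    restored = set()
    for bond in mol.GetBonds():
        if bond.GetBondTypeAsDouble() > 1.0:
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i in keep and j not in keep:
                restored.add(j)
            elif j in keep and i not in keep:
                restored.add(i)
    keep |= restored
    editable = Chem.RWMol(mol)
    for idx in sorted(set(adjacency) - keep, reverse=True):
        editable.RemoveAtom(idx)
    scaffold = editable.GetMol()
    Chem.SanitizeMol(scaffold)
    return Chem.MolToSmiles(scaffold)
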