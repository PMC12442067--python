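"""SMILES import and export for benzenoids (via RDKit).

Export assigns one Kekulé structure to the carbon graph and lets RDKit
perceive aromaticity, so any Kekuléan benzenoid (helicenes included)
can be written.  Import embeds an all-carbon aromatic ring system back
onto the hexagon lattice by propagating ring orientations across fused
bonds; molecules that are not pure fused-hexagon systems are rejected.
"""

from __future__ import annotations

from rdkit import Chem

from .benzenoid import Benzenoid, BenzenoidError, from_dualist
from .clar import enumerate_kekule


def to_smiles(b: Benzenoid) -> str:
    """Canonical aromatic SMILES of a benzenoid."""
    cg = b.carbon_graph()
    kekule = enumerate_kekule(cg)
    if not kekule:
        raise BenzenoidError(f"{b.name or 'molecule'} is non-Kekuléan")
    double = {frozenset(e) for e in next(iter(kekule)).double_bonds}
    mol = Chem.RWMol()
    index = {}
    for atom in cg.graph.nodes:
        index[atom] = mol.AddAtom(Chem.Atom(6))
    for u, v in cg.graph.edges:
        order = (Chem.BondType.DOUBLE if frozenset((u, v)) in double
                 else Chem.BondType.SINGLE)
        mol.AddBond(index[u], index[v], order)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def from_smiles(smiles: str, name: str = "") -> Benzenoid:
    """Embed an aromatic SMILES string onto the hexagon lattice.

    The molecule must be a fused system of aromatic all-carbon
    six-membered rings (degree 2 or 3 carbons only).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise BenzenoidError(f"unparsable SMILES: {smiles!r}")
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C" or not atom.GetIsAromatic():
            raise BenzenoidError("only fused aromatic carbon rings supported")
        if atom.GetDegree() not in (2, 3):
            raise BenzenoidError("substituents are not supported")
    rings = [tuple(r) for r in Chem.GetSymmSSSR(mol)]
    if any(len(r) != 6 for r in rings):
        raise BenzenoidError("non-hexagonal ring found")
    n = len(rings)
    # ring adjacency: two rings sharing a bond are fused
    ring_bonds: list[set[frozenset[int]]] = []
    for r in rings:
        ring_bonds.append({frozenset((r[i], r[(i + 1) % 6])) for i in range(6)})
    # cyclic atom order per ring, as returned by the SSSR perception
    order = [list(r) for r in rings]

    # Propagate orientations: ring 0 takes its perceived order with the
    # bond (order[0][k], order[0][k+1]) assigned lattice direction k;
    # every fused neighbour is aligned across the shared bond so that
    # all rings are traversed with the same rotational sense.
    slot: list[list[int] | None] = [None] * n  # slot[i][d] = atom at vertex d
    slot[0] = order[0][:]
    edges: list[tuple[int, int, int]] = []
    queue = [0]
    placed = {0}
    while queue:
        i = queue.pop(0)
        for j in range(n):
            shared = ring_bonds[i] & ring_bonds[j]
            if i == j or not shared:
                continue
            if len(shared) > 1:
                raise BenzenoidError("rings sharing more than one bond")
            u, v = tuple(next(iter(shared)))
            # direction of the shared bond as seen from ring i
            d = next(k for k in range(6)
                     if {slot[i][k], slot[i][(k + 1) % 6]} == {u, v})
            if slot[i][d] == v:
                u, v = v, u  # u sits at vertex d, v at vertex d+1
            if j not in placed:
                # align ring j: vertex d+4 holds u, vertex d+3 holds v
                cyc = order[j]
                p = cyc.index(u)
                fwd = cyc[p:] + cyc[:p]
                rev = [cyc[p]] + cyc[:p][::-1] + cyc[p + 1:][::-1]
                chosen = fwd if fwd[1] != v else rev
                if chosen[1] == v:
                    raise BenzenoidError("cannot orient fused ring")
                start = (d + 4) % 6
                s = [0] * 6
                for k in range(6):
                    s[(start + k) % 6] = chosen[k]
                if s[(d + 3) % 6] != v:
                    raise BenzenoidError("inconsistent ring fusion")
                slot[j] = s
                placed.add(j)
                queue.append(j)
            if i < j:
                edges.append((i, j, d))
    if len(placed) != n:
        raise BenzenoidError("disconnected ring system")
    b = from_dualist(sorted(set(edges)), n, name)
    if b.carbon_graph().n_atoms != mol.GetNumAtoms():
        raise BenzenoidError("embedding does not reproduce the molecule")
    return b
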