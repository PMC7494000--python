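"""Molecular graphs with implicit hydrogens.

Molecules are undirected graphs over heavy atoms only; every atom is assumed
saturated with hydrogens up to its maximum valence, so the only valence
inconsistency that can arise is *hypervalence* (the sum of explicit bond
orders exceeding the allowed maximum).  Bond orders are integers in
{1, 2, 3}; an absent record means "no bond" (order 0).  Aromaticity is kept
implicit: graphs are stored in Kekulé form and aromatic perception happens
only when a canonical identity key is computed.

Atom indices are stable for the lifetime of a molecule: removing an atom
leaves a hole instead of re-indexing, so recorded edit actions stay
interpretable after later edits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Union

from rdkit import Chem

__all__ = [
    "DEFAULT_VALENCES",
    "AtomNode",
    "ValenceTable",
    "MolecularGraph",
    "MolGraphError",
    "ParseError",
]

#: Default maximum valences (sum of explicit bond orders).  A single maximum
#: per element; expanded valence states of S and P are excluded by default so
#: that action filtering stays unambiguous.  Configurable per run.
DEFAULT_VALENCES: dict[str, int] = {
    "C": 4, "N": 3, "O": 2, "F": 1, "P": 3, "S": 2, "Cl": 1, "Br": 1,
}

_BOND_ORDERS = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}


class MolGraphError(ValueError):
    """Invalid molecular-graph operation or state."""


class ParseError(MolGraphError):
    """SMILES input that cannot become a single valid connected graph."""


@dataclass
class AtomNode:
    """A heavy atom.

    ``max_valence_override`` is set for formally charged input atoms, whose
    allowed valence is fixed at parse time (explicit bonds + implicit Hs);
    edit actions never create charges nor touch the bonds of charged atoms,
    so the override is constant over the atom's lifetime.
    """

    index: int
    element: str
    formal_charge: int = 0
    mutable: bool = True
    max_valence_override: Optional[int] = None


class ValenceTable(Mapping[str, int]):
    """Map element symbol -> maximum allowed sum of explicit bond orders."""

    def __init__(self, valences: Optional[Mapping[str, int]] = None):
        table = dict(DEFAULT_VALENCES if valences is None else valences)
        for el, v in table.items():
            if v < 1:
                raise ValueError(f"max valence of {el} must be >= 1, got {v}")
        self._table = table

    def __getitem__(self, element: str) -> int:
        return self._table[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._table)

    def __len__(self) -> int:
        return len(self._table)

    def max_valence(self, atom: AtomNode) -> int:
        if atom.max_valence_override is not None:
            return atom.max_valence_override
        try:
            return self._table[atom.element]
        except KeyError:
            raise MolGraphError(
                f"element {atom.element!r} has no valence entry"
            ) from None


class MolecularGraph:
    """Heavy-atom molecular graph with integer bond orders.

    The graph owns its atoms and bonds; all edit helpers return nothing and
    mutate in place, so callers that need persistence copy first.
    """

    def __init__(self, valences: Optional[ValenceTable] = None,
                 provenance: Optional[str] = None):
        self.valences = valences if isinstance(valences, ValenceTable) \
            else ValenceTable(valences)
        self.provenance = provenance
        self._atoms: dict[int, AtomNode] = {}
        # adjacency map atom -> {neighbour: order}; orders always 1..3
        self._adj: dict[int, dict[int, int]] = {}
        self._next_index = 0

    # -- construction -----------------------------------------------------

    @classmethod
    def from_smiles(cls, smiles: str,
                    valences: Optional[ValenceTable] = None,
                    mutable: bool = True) -> "MolecularGraph":
        """Parse a SMILES string into a kekulised heavy-atom graph.

        Rejects unparsable, multi-fragment and hypervalent input.  Formal
        charges are preserved; charged atoms get a fixed valence override
        equal to their parsed total connectivity (bonds + implicit Hs).
        """
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ParseError(f"cannot parse SMILES {smiles!r}")
        if len(Chem.GetMolFrags(mol)) != 1:
            raise ParseError(f"multi-fragment input {smiles!r}")
        Chem.Kekulize(mol, clearAromaticFlags=True)
        g = cls(valences)
        index_of: dict[int, int] = {}
        for atom in mol.GetAtoms():
            override = None
            if atom.GetFormalCharge() != 0:
                override = int(sum(
                    b.GetBondTypeAsDouble() for b in atom.GetBonds()
                )) + atom.GetTotalNumHs()
            index_of[atom.GetIdx()] = g.add_atom(
                atom.GetSymbol(), formal_charge=atom.GetFormalCharge(),
                mutable=mutable, max_valence_override=override)
        for bond in mol.GetBonds():
            order = int(bond.GetBondTypeAsDouble())
            if order not in (1, 2, 3):
                raise ParseError(
                    f"unsupported bond order {bond.GetBondTypeAsDouble()} "
                    f"in {smiles!r}")
            g.set_bond(index_of[bond.GetBeginAtomIdx()],
                       index_of[bond.GetEndAtomIdx()], order)
        for idx, atom in g.atoms():
            if g.bond_order_sum(idx) > g.max_valence(idx):
                raise ParseError(
                    f"atom {atom.element}{idx} in {smiles!r} exceeds its "
                    f"maximum valence {g.max_valence(idx)}")
        return g

    def copy(self) -> "MolecularGraph":
        g = MolecularGraph(self.valences, self.provenance)
        g._atoms = {i: AtomNode(a.index, a.element, a.formal_charge,
                                a.mutable, a.max_valence_override)
                    for i, a in self._atoms.items()}
        g._adj = {i: dict(nbrs) for i, nbrs in self._adj.items()}
        g._next_index = self._next_index
        return g

    # -- atoms & bonds ----------------------------------------------------

    def add_atom(self, element: str, formal_charge: int = 0,
                 mutable: bool = True,
                 max_valence_override: Optional[int] = None) -> int:
        idx = self._next_index
        self._atoms[idx] = AtomNode(idx, element, formal_charge, mutable,
                                    max_valence_override)
        self._adj[idx] = {}
        self._next_index += 1
        return idx

    def remove_atom(self, index: int) -> None:
        self._require_atom(index)
        del self._atoms[index]
        for nb in self._adj.pop(index):
            del self._adj[nb][index]

    def atoms(self) -> Iterable[tuple[int, AtomNode]]:
        return sorted(self._atoms.items())

    def atom(self, index: int) -> AtomNode:
        self._require_atom(index)
        return self._atoms[index]

    @property
    def atom_indices(self) -> list[int]:
        return sorted(self._atoms)

    @property
    def n_atoms(self) -> int:
        return len(self._atoms)

    def bonds(self) -> Iterable[tuple[int, int, int]]:
        """Yield (i, j, order) with i < j, deterministically ordered."""
        return sorted((i, j, o) for i, nbrs in self._adj.items()
                      for j, o in nbrs.items() if i < j)

    @property
    def n_bonds(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def bond_order(self, i: int, j: int) -> int:
        return self._adj.get(i, {}).get(j, 0)

    def set_bond(self, i: int, j: int, order: int) -> None:
        self._require_atom(i)
        self._require_atom(j)
        if i == j:
            raise MolGraphError("bond endpoints must be distinct")
        if order not in (0, 1, 2, 3):
            raise MolGraphError(f"bond order must be 0..3, got {order}")
        if order == 0:
            self._adj[i].pop(j, None)
            self._adj[j].pop(i, None)
        else:
            self._adj[i][j] = order
            self._adj[j][i] = order

    def neighbours(self, index: int) -> list[int]:
        self._require_atom(index)
        return sorted(self._adj[index])

    def bond_order_sum(self, index: int) -> int:
        self._require_atom(index)
        return sum(self._adj[index].values())

    # -- valence ----------------------------------------------------------

    def max_valence(self, index: int) -> int:
        return self.valences.max_valence(self.atom(index))

    def free_valence(self, index: int) -> int:
        """Remaining bonding capacity; implicit-H count for neutral atoms."""
        return self.max_valence(index) - self.bond_order_sum(index)

    # -- validity ---------------------------------------------------------

    def connected_components(self) -> list[set[int]]:
        remaining = set(self._atoms)
        comps = []
        while remaining:
            seed = remaining.pop()
            comp, frontier = {seed}, [seed]
            while frontier:
                for nb in self.neighbours(frontier.pop()):
                    if nb not in comp:
                        comp.add(nb)
                        frontier.append(nb)
            remaining -= comp
            comps.append(comp)
        return comps

    def is_connected(self) -> bool:
        return self.n_atoms >= 1 and len(self.connected_components()) == 1

    def validity_violations(self) -> list[str]:
        out = []
        if self.n_atoms == 0:
            out.append("empty graph")
        elif not self.is_connected():
            out.append(
                f"disconnected: {len(self.connected_components())} components")
        for idx, atom in self.atoms():
            excess = self.bond_order_sum(idx) - self.max_valence(idx)
            if excess > 0:
                out.append(f"hypervalent {atom.element}{idx} "
                           f"(+{excess} over {self.max_valence(idx)})")
        return out

    def is_valid(self) -> bool:
        """True iff connected, non-empty and free of hypervalence."""
        return not self.validity_violations()

    def would_disconnect(
            self, removal: Union[int, tuple[int, int]]) -> bool:
        """Would deleting an atom, or zeroing a bond, split the graph?

        ``removal`` is an atom index or an ``(i, j)`` bond pair.  Returns
        True as well when removing the last atom (the empty graph counts as
        disconnected during evolution).
        """
        g = self.copy()
        if isinstance(removal, int):
            g.remove_atom(removal)
            return g.n_atoms == 0 or not g.is_connected()
        i, j = removal
        if g.bond_order(i, j) == 0:
            return False
        g.set_bond(i, j, 0)
        return not g.is_connected()

    # -- SMILES interchange ----------------------------------------------

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        mol = Chem.RWMol()
        order_of: dict[int, int] = {}
        for idx, atom in self.atoms():
            a = Chem.Atom(atom.element)
            a.SetFormalCharge(atom.formal_charge)
            order_of[idx] = mol.AddAtom(a)
        for i, j, order in self.bonds():
            mol.AddBond(order_of[i], order_of[j], _BOND_ORDERS[order])
        mol = mol.GetMol()
        if sanitize:
            Chem.SanitizeMol(mol)
        return mol

    def to_smiles(self) -> str:
        """Canonical aromatic SMILES (the molecule's identity key)."""
        return Chem.MolToSmiles(self.to_rdkit())

    canonical_key = to_smiles

    # -- misc -------------------------------------------------------------

    def _require_atom(self, index: int) -> None:
        if index not in self._atoms:
            raise MolGraphError(f"no atom with index {index}")

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (f"MolecularGraph({self.n_atoms} atoms, {self.n_bonds} bonds, "
                f"{self.to_smiles()!r})")
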