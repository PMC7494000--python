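"""The seven atom-level edit actions on molecular graphs.

Three primary actions (append atom, remove atom, change bond) suffice to
reach the whole valence-consistent search space; four secondary actions
(substitute atom type, insert carbon, cut atom, move group) are shortcuts
composed of primary effects and do not extend the reachable space.

Actions are filtered *a priori*, i.e. an action is only enumerated when its
application is guaranteed to yield a valid graph:

1. no dislocation — an action may not split the graph into several
   connected components (nor empty it);
2. no hypervalence — bond-order sums stay within each element's maximum;
3. charged atoms — no action may add, delete or re-order a bond incident to
   a formally charged atom, and none may substitute it; the single exception
   is removing the charged atom itself, so ionic subgraphs are either
   conserved or dropped whole;
4. frozen atoms — substitute/cut apply only to mutable atoms, change-bond /
   insert-carbon / move-group only to atom pairs with at least one mutable
   member, and remove only to mutable atoms.

``enumerate_actions`` is the single source of legality:
``apply_action`` trusts its input and validates the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, FrozenSet, Sequence

import networkx as nx

from .graph import MolecularGraph, MolGraphError

__all__ = [
    "ActionType", "Action", "ActionContext",
    "enumerate_actions", "apply_action", "bridge_groups",
    "max_valence_check",
]


class ActionType(Enum):
    """The 7 edit kinds; values are the short labels used on tree edges."""

    APPEND_ATOM = "Ad"
    REMOVE_ATOM = "Rm"
    CHANGE_BOND = "Ch"
    SUBSTITUTE_ATOM_TYPE = "Sub"
    INSERT_CARBON = "In"
    CUT_ATOM = "Ct"
    MOVE_GROUP = "Mv"

    @property
    def label(self) -> str:
        return self.value


PRIMARY_ACTIONS = (ActionType.APPEND_ATOM, ActionType.REMOVE_ATOM,
                   ActionType.CHANGE_BOND)
SECONDARY_ACTIONS = (ActionType.SUBSTITUTE_ATOM_TYPE, ActionType.INSERT_CARBON,
                     ActionType.CUT_ATOM, ActionType.MOVE_GROUP)


@dataclass(frozen=True)
class Action:
    """One concrete graph edit.

    ``params`` layout per type:

    - APPEND_ATOM: (anchor_index, element)
    - REMOVE_ATOM: (atom_index,)
    - CHANGE_BOND: (i, j, new_order)   with i < j
    - SUBSTITUTE_ATOM_TYPE: (atom_index, new_element)
    - INSERT_CARBON: (i, j)            the bonded pair, i < j
    - CUT_ATOM: (atom_index,)
    - MOVE_GROUP: (bridge_i, bridge_j, attach_index, dest_index)
      where (bridge_i, bridge_j) is the bridge bond, ``attach_index`` is the
      bridge endpoint belonging to the moved side, and ``dest_index`` the
      new attachment atom on the kept side.
    """

    type: ActionType
    params: tuple

    def serialise(self) -> str:
        p = self.params
        t = self.type
        if t is ActionType.CHANGE_BOND:
            return f"Ch({p[0]},{p[1]},→{p[2]})"
        return f"{t.label}({','.join(str(x) for x in p)})"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.serialise()


@dataclass
class ActionContext:
    """Search-space definition: atoms, size cap, frozen atoms, extra filters.

    ``extra_filters`` is an ordered list of predicates
    ``(graph, action) -> bool``; an action survives only if every predicate
    returns True.  ``action_types`` restricts the active subset of the 7
    actions (e.g. primary-only runs).
    """

    allowed_elements: FrozenSet[str] = frozenset({"C", "N", "O", "F"})
    max_heavy_atoms: int = 38
    frozen_atoms: FrozenSet[int] = frozenset()
    extra_filters: Sequence[Callable[[MolecularGraph, Action], bool]] = ()
    action_types: tuple[ActionType, ...] = tuple(ActionType)

    def __post_init__(self) -> None:
        self.allowed_elements = frozenset(self.allowed_elements)
        self.frozen_atoms = frozenset(self.frozen_atoms)
        if self.max_heavy_atoms < 1:
            raise ValueError("max_heavy_atoms must be >= 1")

    def is_mutable(self, graph: MolecularGraph, index: int) -> bool:
        return graph.atom(index).mutable and index not in self.frozen_atoms


def max_valence_check(graph: MolecularGraph, index: int, delta: int) -> bool:
    """Can atom ``index`` accept ``delta`` more units of bond order?"""
    return graph.bond_order_sum(index) + delta <= graph.max_valence(index)


def _charged(graph: MolecularGraph, index: int) -> bool:
    return graph.atom(index).formal_charge != 0


def _nx_graph(graph: MolecularGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(graph.atom_indices)
    g.add_edges_from((i, j) for i, j, _ in graph.bonds())
    return g


def bridge_groups(
        graph: MolecularGraph,
) -> list[tuple[tuple[int, int], tuple[frozenset[int], frozenset[int]]]]:
    """All bridge bonds with the two atom sets they separate.

    A *functional group* in the edit-action sense is a subgraph attached to
    the rest of the molecule by exactly one bond, i.e. one side of a bridge.
    Returns ``((i, j), (side_i, side_j))`` with ``i < j``; ``side_i``
    contains ``i``.  Ring bonds are never bridges.
    """
    if graph.n_atoms < 2:
        return []
    out = []
    for a, b in sorted(tuple(sorted(e)) for e in nx.bridges(_nx_graph(graph))):
        # BFS from a skipping the bridge itself gives side_a; side_b is the
        # complement (the graph is connected)
        side_a = {a}
        stack = [a]
        while stack:
            node = stack.pop()
            for nb in graph.neighbours(node):
                if nb not in side_a and not (node == a and nb == b):
                    side_a.add(nb)
                    stack.append(nb)
        side_b = frozenset(i for i in graph.atom_indices if i not in side_a)
        out.append(((a, b), (frozenset(side_a), side_b)))
    return out


# ---------------------------------------------------------------------------
# enumeration

def enumerate_actions(graph: MolecularGraph, action_type: ActionType,
                      ctx: ActionContext) -> list[Action]:
    """All legal actions of one type, in deterministic order.

    Every returned action, applied to ``graph``, yields a valid connected
    graph within ``ctx.max_heavy_atoms``; the dislocation, hypervalence,
    charged-atom and frozen-atom filters are all pre-applied, so no
    trial application is needed.
    """
    actions = _ENUMERATORS[action_type](graph, ctx)
    if ctx.extra_filters:
        actions = [a for a in actions
                   if all(f(graph, a) for f in ctx.extra_filters)]
    return actions


def _enum_append(graph: MolecularGraph, ctx: ActionContext) -> list[Action]:
    if graph.n_atoms >= ctx.max_heavy_atoms:
        return []
    out = []
    for idx, _atom in graph.atoms():
        if _charged(graph, idx):
            continue  # would add a bond on a charged atom
        if graph.free_valence(idx) < 1:
            continue
        for el in sorted(ctx.allowed_elements):
            out.append(Action(ActionType.APPEND_ATOM, (idx, el)))
    return out


def _enum_remove(graph: MolecularGraph, ctx: ActionContext) -> list[Action]:
    if graph.n_atoms <= 1:
        return []  # the last atom can never be removed
    cut_vertices = set(nx.articulation_points(_nx_graph(graph)))
    out = []
    for idx, _atom in graph.atoms():
        if not ctx.is_mutable(graph, idx):
            continue
        # removal of a charged atom is allowed; deleting the bonds of a
        # charged *neighbour* is not
        if any(_charged(graph, nb) for nb in graph.neighbours(idx)):
            continue
        if idx in cut_vertices:
            continue
        out.append(Action(ActionType.REMOVE_ATOM, (idx,)))
    return out


def _enum_change_bond(graph: MolecularGraph,
                      ctx: ActionContext) -> list[Action]:
    out = []
    # a bond deletion disconnects the graph exactly when the bond is a bridge
    bridges = {tuple(sorted(e)) for e in nx.bridges(_nx_graph(graph))} \
        if graph.n_bonds else set()
    indices = graph.atom_indices
    free = {i: graph.free_valence(i) for i in indices}
    for ai, i in enumerate(indices):
        for j in indices[ai + 1:]:
            if _charged(graph, i) or _charged(graph, j):
                continue
            if not (ctx.is_mutable(graph, i) or ctx.is_mutable(graph, j)):
                continue
            current = graph.bond_order(i, j)
            for new in range(4):
                if new == current:
                    continue
                delta = new - current
                if delta > 0 and (free[i] < delta or free[j] < delta):
                    continue
                if new == 0 and (i, j) in bridges:
                    continue
                out.append(Action(ActionType.CHANGE_BOND, (i, j, new)))
    return out


def _enum_substitute(graph: MolecularGraph,
                     ctx: ActionContext) -> list[Action]:
    out = []
    for idx, atom in graph.atoms():
        if not ctx.is_mutable(graph, idx) or _charged(graph, idx):
            continue
        used = graph.bond_order_sum(idx)
        for el in sorted(ctx.allowed_elements):
            if el == atom.element:
                continue
            if graph.valences.get(el, 0) < used:
                continue
            out.append(Action(ActionType.SUBSTITUTE_ATOM_TYPE, (idx, el)))
    return out


def _enum_insert_carbon(graph: MolecularGraph,
                        ctx: ActionContext) -> list[Action]:
    # the inserted atom is always carbon, which must be in the search space
    if "C" not in ctx.allowed_elements:
        return []
    if graph.n_atoms >= ctx.max_heavy_atoms:
        return []
    out = []
    for i, j, _order in graph.bonds():
        if _charged(graph, i) or _charged(graph, j):
            continue
        if not (ctx.is_mutable(graph, i) or ctx.is_mutable(graph, j)):
            continue
        out.append(Action(ActionType.INSERT_CARBON, (i, j)))
    return out


def _enum_cut(graph: MolecularGraph, ctx: ActionContext) -> list[Action]:
    out = []
    for idx, _atom in graph.atoms():
        if not ctx.is_mutable(graph, idx) or _charged(graph, idx):
            continue
        nbs = graph.neighbours(idx)
        if len(nbs) != 2:
            continue
        n1, n2 = nbs
        if graph.bond_order(n1, n2) != 0:
            continue  # neighbours already bonded: cut would stack bonds
        if _charged(graph, n1) or _charged(graph, n2):
            continue
        # replacement bond is single; neighbour bond sums can only shrink
        out.append(Action(ActionType.CUT_ATOM, (idx,)))
    return out


def _enum_move_group(graph: MolecularGraph,
                     ctx: ActionContext) -> list[Action]:
    out = []
    groups = bridge_groups(graph)
    if not groups:
        return out
    free = {i: graph.free_valence(i) for i in graph.atom_indices}
    charged = {i for i in graph.atom_indices if _charged(graph, i)}
    mutable = {i for i in graph.atom_indices if ctx.is_mutable(graph, i)}
    for (a, b), (side_a, side_b) in groups:
        order = graph.bond_order(a, b)
        if a in charged or b in charged:
            continue
        for attach, kept_side in ((b, side_a), (a, side_b)):
            anchor = a if attach == b else b
            if anchor not in mutable and attach not in mutable:
                continue
            for dest in sorted(kept_side):
                if dest == anchor or dest in charged:
                    continue
                if attach not in mutable and dest not in mutable:
                    continue
                if free[dest] < order:
                    continue
                i, j = min(a, b), max(a, b)
                out.append(Action(ActionType.MOVE_GROUP,
                                  (i, j, attach, dest)))
    return out


_ENUMERATORS = {
    ActionType.APPEND_ATOM: _enum_append,
    ActionType.REMOVE_ATOM: _enum_remove,
    ActionType.CHANGE_BOND: _enum_change_bond,
    ActionType.SUBSTITUTE_ATOM_TYPE: _enum_substitute,
    ActionType.INSERT_CARBON: _enum_insert_carbon,
    ActionType.CUT_ATOM: _enum_cut,
    ActionType.MOVE_GROUP: _enum_move_group,
}


# ---------------------------------------------------------------------------
# application

def apply_action(graph: MolecularGraph, action: Action) -> MolecularGraph:
    """Apply one action, returning a new graph; the input is untouched.

    ``action`` must come from :func:`enumerate_actions` on this graph; the
    result is re-validated and a :class:`MolGraphError` raised on any
    violation, so a stale or hand-built action cannot corrupt a run.
    """
    g = graph.copy()
    t, p = action.type, action.params
    if t is ActionType.APPEND_ATOM:
        anchor, el = p
        new = g.add_atom(el)
        g.set_bond(anchor, new, 1)
    elif t is ActionType.REMOVE_ATOM:
        g.remove_atom(p[0])
    elif t is ActionType.CHANGE_BOND:
        i, j, new_order = p
        if g.bond_order(i, j) == new_order:
            raise MolGraphError(f"change-bond to identical order: {action}")
        g.set_bond(i, j, new_order)
    elif t is ActionType.SUBSTITUTE_ATOM_TYPE:
        idx, el = p
        g.atom(idx).element = el
    elif t is ActionType.INSERT_CARBON:
        i, j = p
        if g.bond_order(i, j) == 0:
            raise MolGraphError(f"insert-carbon on non-bond: {action}")
        new = g.add_atom("C")
        g.set_bond(i, j, 0)
        g.set_bond(i, new, 1)
        g.set_bond(j, new, 1)
    elif t is ActionType.CUT_ATOM:
        idx = p[0]
        nbs = g.neighbours(idx)
        if len(nbs) != 2:
            raise MolGraphError(f"cut on atom without exactly 2 bonds: "
                                f"{action}")
        if g.bond_order(nbs[0], nbs[1]) != 0:
            raise MolGraphError(
                f"cut between neighbours that already share a bond: {action}")
        g.remove_atom(idx)
        g.set_bond(nbs[0], nbs[1], 1)
    elif t is ActionType.MOVE_GROUP:
        i, j, attach, dest = p
        order = g.bond_order(i, j)
        if order == 0:
            raise MolGraphError(f"move-group on non-bond: {action}")
        g.set_bond(i, j, 0)
        g.set_bond(attach, dest, order)
    else:  # pragma: no cover - exhaustive enum
        raise MolGraphError(f"unknown action type {t}")
    violations = g.validity_violations()
    if violations:
        raise MolGraphError(
            f"action {action} produced an invalid graph: {violations}")
    return g
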