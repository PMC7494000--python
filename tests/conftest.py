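"""Shared fixtures and independent brute-force oracles.

The oracles re-derive action legality from first principles (apply every
syntactically possible edit, then post-check the result) so they stay
independent of the a-priori filter logic they are used to verify.
"""

from __future__ import annotations

import itertools
import random

import pytest

from molevo import (Action, ActionContext, ActionType, MolecularGraph,
                    MolGraphError, apply_action, draw_mutation, MutationSpec)


@pytest.fixture
def ctx_cnof() -> ActionContext:
    return ActionContext(allowed_elements=frozenset("CNOF"),
                         max_heavy_atoms=38)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240916)


def random_graphs(n_graphs: int, max_atoms: int = 12,
                  seed: int = 7, elements: str = "CNOF",
                  ) -> list[MolecularGraph]:
    """Random valid molecules grown by random-action walks from methane."""
    rng = random.Random(seed)
    ctx = ActionContext(allowed_elements=frozenset(elements),
                        max_heavy_atoms=max_atoms)
    spec = MutationSpec(max_actions=1)
    out = []
    for _ in range(n_graphs):
        g = MolecularGraph.from_smiles("C")
        for _ in range(rng.randrange(1, 2 * max_atoms)):
            g, _actions = draw_mutation(g, spec, ctx, rng)
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# brute-force action oracle

def _components_after_bond_removal(graph: MolecularGraph,
                                   i: int, j: int) -> int:
    g = graph.copy()
    g.set_bond(i, j, 0)
    return len(g.connected_components())


def _syntactic_actions(graph: MolecularGraph, t: ActionType,
                       ctx: ActionContext) -> list[Action]:
    """Every parameter combination the action definition admits, with no
    validity pre-filtering beyond the definition itself."""
    idx = graph.atom_indices
    out: list[Action] = []
    if t is ActionType.APPEND_ATOM:
        out = [Action(t, (i, el))
               for i in idx for el in sorted(ctx.allowed_elements)]
    elif t is ActionType.REMOVE_ATOM:
        out = [Action(t, (i,)) for i in idx]
    elif t is ActionType.CHANGE_BOND:
        for i, j in itertools.combinations(idx, 2):
            for new in range(4):
                if new != graph.bond_order(i, j):
                    out.append(Action(t, (i, j, new)))
    elif t is ActionType.SUBSTITUTE_ATOM_TYPE:
        out = [Action(t, (i, el)) for i in idx
               for el in sorted(ctx.allowed_elements)
               if el != graph.atom(i).element]
    elif t is ActionType.INSERT_CARBON:
        out = [Action(t, (i, j)) for i, j, _ in graph.bonds()]
    elif t is ActionType.CUT_ATOM:
        out = [Action(t, (i,)) for i in idx]
    elif t is ActionType.MOVE_GROUP:
        # definition: the moved group is one side of a *bridge* bond, the
        # destination a different atom of the kept side; bridge-ness and
        # side membership are derived by component recount, not reused code
        for i, j, order in graph.bonds():
            if _components_after_bond_removal(graph, i, j) != 2:
                continue
            g = graph.copy()
            g.set_bond(i, j, 0)
            comps = g.connected_components()
            side = {a: (0 if a in comps[0] else 1) for a in idx}
            for attach, anchor in ((j, i), (i, j)):
                for dest in idx:
                    if side[dest] == side[attach] or dest == anchor:
                        continue
                    out.append(Action(t, (i, j, attach, dest)))
    return out


def _respects_policy_filters(graph: MolecularGraph, action: Action,
                             ctx: ActionContext) -> bool:
    """Charged-atom and frozen-atom rules, restated from the definitions."""
    t, p = action.type, action.params
    charged = {i for i, a in graph.atoms() if a.formal_charge != 0}
    mutable = {i for i, a in graph.atoms()
               if a.mutable and i not in ctx.frozen_atoms}
    if t is ActionType.APPEND_ATOM:
        return p[0] not in charged
    if t is ActionType.REMOVE_ATOM:
        i = p[0]
        return (i in mutable
                and not any(nb in charged for nb in graph.neighbours(i)))
    if t is ActionType.CHANGE_BOND:
        i, j = p[0], p[1]
        return (not {i, j} & charged) and bool({i, j} & mutable)
    if t is ActionType.SUBSTITUTE_ATOM_TYPE:
        return p[0] in mutable and p[0] not in charged
    if t is ActionType.INSERT_CARBON:
        i, j = p
        return (not {i, j} & charged) and bool({i, j} & mutable)
    if t is ActionType.CUT_ATOM:
        i = p[0]
        nbs = graph.neighbours(i)
        return (i in mutable and i not in charged
                and not any(nb in charged for nb in nbs))
    if t is ActionType.MOVE_GROUP:
        i, j, attach, dest = p
        anchor = i if attach == j else j
        if {i, j, dest} & charged:
            return False
        return bool({anchor, attach} & mutable) \
            and bool({attach, dest} & mutable)
    raise AssertionError(t)


def oracle_enumerate(graph: MolecularGraph, t: ActionType,
                     ctx: ActionContext) -> set[Action]:
    """Apply-and-check oracle: every syntactically possible action whose
    application yields a valid graph within the size cap and which passes
    the charged/frozen policy rules."""
    ok: set[Action] = set()
    for action in _syntactic_actions(graph, t, ctx):
        if not _respects_policy_filters(graph, action, ctx):
            continue
        try:
            result = apply_action(graph, action)
        except MolGraphError:
            continue
        if result.n_atoms > ctx.max_heavy_atoms:
            continue
        if result.is_valid():
            ok.add(action)
    return ok
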