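"""Action space: enumeration under the a-priori filters, application
semantics, and agreement with the brute-force apply-and-check oracle."""

import pytest

from molevo import (Action, ActionContext, ActionType, MolecularGraph,
                    MolGraphError, apply_action, bridge_groups,
                    enumerate_actions, max_valence_check)

from conftest import oracle_enumerate, random_graphs


def parse(smiles: str, **kw) -> MolecularGraph:
    return MolecularGraph.from_smiles(smiles, **kw)


class TestEnumerateExamples:
    def test_append_on_methane(self, ctx_cnof):
        acts = enumerate_actions(parse("C"), ActionType.APPEND_ATOM, ctx_cnof)
        assert {a.params for a in acts} == {(0, "C"), (0, "N"), (0, "O"),
                                            (0, "F")}

    def test_change_bond_on_methane_is_empty(self, ctx_cnof):
        assert enumerate_actions(parse("C"), ActionType.CHANGE_BOND,
                                 ctx_cnof) == []

    def test_change_bond_on_ethane(self, ctx_cnof):
        # single->double and single->triple; single->none would disconnect
        acts = enumerate_actions(parse("CC"), ActionType.CHANGE_BOND,
                                 ctx_cnof)
        assert {a.params for a in acts} == {(0, 1, 2), (0, 1, 3)}

    def test_size_limit_blocks_growth(self):
        ctx = ActionContext(allowed_elements=frozenset("C"),
                            max_heavy_atoms=2)
        g = parse("CC")
        assert enumerate_actions(g, ActionType.APPEND_ATOM, ctx) == []
        assert enumerate_actions(g, ActionType.INSERT_CARBON, ctx) == []

    def test_insert_requires_carbon_in_atom_set(self):
        ctx = ActionContext(allowed_elements=frozenset("NOF"),
                            max_heavy_atoms=9)
        assert enumerate_actions(parse("NO"), ActionType.INSERT_CARBON,
                                 ctx) == []

    def test_last_atom_cannot_be_removed(self, ctx_cnof):
        assert enumerate_actions(parse("C"), ActionType.REMOVE_ATOM,
                                 ctx_cnof) == []


class TestApplyExamples:
    def test_insert_carbon_makes_propane(self, ctx_cnof):
        g = apply_action(parse("CC"), Action(ActionType.INSERT_CARBON,
                                             (0, 1)))
        assert g.to_smiles() == "CCC"

    def test_substitute_makes_ammonia(self, ctx_cnof):
        g = apply_action(parse("C"),
                         Action(ActionType.SUBSTITUTE_ATOM_TYPE, (0, "N")))
        assert g.to_smiles() == "N"

    def test_ring_closure_via_change_bond(self, ctx_cnof):
        g = apply_action(parse("CCCC"),
                         Action(ActionType.CHANGE_BOND, (0, 3, 1)))
        assert g.to_smiles() == "C1CCC1"

    def test_cut_atom_relinks_with_single_bond(self):
        g = apply_action(parse("C=CC"), Action(ActionType.CUT_ATOM, (1,)))
        assert g.to_smiles() == "CC"

    def test_move_group_conserves_bond_order(self):
        # move the =O of but-2-enal... use propan-1-ol's hydroxyl instead:
        # relocate O from C2 to C0 across the chain
        g = parse("CCO")  # C0-C1-O2
        moved = apply_action(g, Action(ActionType.MOVE_GROUP, (1, 2, 2, 0)))
        assert moved.to_smiles() == "OCC"[::-1] or moved.to_smiles() == "CCO"
        # the graph is propan-1-ol's isomer: O now bonded to C0
        assert moved.bond_order(0, 2) == 1 and moved.bond_order(1, 2) == 0

    def test_input_graph_unmodified(self, ctx_cnof):
        g = parse("CC")
        apply_action(g, Action(ActionType.INSERT_CARBON, (0, 1)))
        assert g.to_smiles() == "CC"

    def test_non_enumerable_action_rejected(self):
        with pytest.raises(MolGraphError):
            apply_action(parse("C=O"),
                         Action(ActionType.CHANGE_BOND, (0, 1, 3)))
        with pytest.raises(MolGraphError):
            apply_action(parse("CCC"), Action(ActionType.CUT_ATOM, (0,)))


class TestBridgeGroups:
    def test_pendant_atom(self):
        g = parse("CCCO")
        groups = dict(bridge_groups(g))
        assert frozenset({3}) in groups[(2, 3)]

    def test_cyclohexane_has_no_bridges(self):
        assert bridge_groups(parse("C1CCCCC1")) == []

    def test_toluene_methyl_bridge(self):
        g = parse("Cc1ccccc1")
        sides = {frozenset(len(s) for s in sides)
                 for _, sides in bridge_groups(g)}
        assert sides == {frozenset({1, 6})}


class TestMaxValenceCheck:
    @pytest.mark.parametrize("smiles, idx, delta, ok", [
        ("C", 0, 1, True),
        ("C=O", 1, 1, False),
        ("N", 0, 3, True),
        ("C", 0, 4, True),
        ("C", 0, 5, False),
    ])
    def test_examples(self, smiles, idx, delta, ok):
        assert max_valence_check(parse(smiles), idx, delta) is ok


class TestChargedAtomFilter:
    def test_no_bond_actions_on_charged_atom(self, ctx_cnof):
        g = parse("C[N+](C)(C)C")  # tetramethylammonium
        charged = next(i for i, a in g.atoms() if a.formal_charge)
        for t in ActionType:
            for act in enumerate_actions(g, t, ctx_cnof):
                if t is ActionType.REMOVE_ATOM:
                    continue
                assert charged not in act.params[:2], (t, act)

    def test_charged_atom_can_be_removed_if_terminal(self, ctx_cnof):
        g = parse("CC[O-]")
        charged = next(i for i, a in g.atoms() if a.formal_charge)
        removals = {a.params[0] for a in
                    enumerate_actions(g, ActionType.REMOVE_ATOM, ctx_cnof)}
        assert charged in removals
        # ... but its neutral neighbour may not be touched
        assert 1 not in removals

    def test_substitute_never_touches_charged_atoms(self, ctx_cnof):
        g = parse("CC[NH3+]")
        charged = next(i for i, a in g.atoms() if a.formal_charge)
        subs = enumerate_actions(g, ActionType.SUBSTITUTE_ATOM_TYPE,
                                 ctx_cnof)
        assert all(a.params[0] != charged for a in subs)


class TestFrozenAtomFilter:
    def test_frozen_core_rules(self):
        # furane with every ring atom frozen: the paper's frozen-core setup
        g = parse("c1ccoc1", mutable=False)
        ctx = ActionContext(allowed_elements=frozenset("CNOF"),
                            max_heavy_atoms=9)
        assert enumerate_actions(g, ActionType.SUBSTITUTE_ATOM_TYPE,
                                 ctx) == []
        assert enumerate_actions(g, ActionType.CUT_ATOM, ctx) == []
        assert enumerate_actions(g, ActionType.REMOVE_ATOM, ctx) == []
        assert enumerate_actions(g, ActionType.CHANGE_BOND, ctx) == []
        # appending to a frozen atom is allowed (the filter constrains the
        # five editing actions only)
        appends = enumerate_actions(g, ActionType.APPEND_ATOM, ctx)
        assert appends
        # a mutable substituent bonded to the frozen core re-enables the
        # pair actions that include it
        grown = apply_action(g, appends[0])
        assert enumerate_actions(grown, ActionType.CHANGE_BOND, ctx)


class TestOracleAgreement:
    """Enumeration must equal the brute-force apply-and-check oracle."""

    @pytest.mark.parametrize("smiles", [
        "C", "CC", "C=O", "CCO", "C1CC1", "C=CC#N", "c1ccoc1", "CC(C)=O",
        "C[N+](C)(C)C", "CC[O-]", "FC1CC1F", "N1C=CC=C1",
    ])
    def test_fixed_molecules(self, smiles, ctx_cnof):
        g = parse(smiles)
        for t in ActionType:
            got = set(enumerate_actions(g, t, ctx_cnof))
            want = oracle_enumerate(g, t, ctx_cnof)
            assert got == want, f"{t} mismatch on {smiles}"

    def test_random_molecules(self):
        ctx = ActionContext(allowed_elements=frozenset("CNOF"),
                            max_heavy_atoms=8)
        for g in random_graphs(12, max_atoms=7, seed=5):
            for t in ActionType:
                assert set(enumerate_actions(g, t, ctx)) == \
                    oracle_enumerate(g, t, ctx), (g.to_smiles(), t)

    def test_frozen_random_molecules(self):
        for k, g in enumerate(random_graphs(6, max_atoms=6, seed=9)):
            frozen = frozenset(g.atom_indices[::2])
            ctx = ActionContext(allowed_elements=frozenset("CNOF"),
                                max_heavy_atoms=8, frozen_atoms=frozen)
            for t in ActionType:
                assert set(enumerate_actions(g, t, ctx)) == \
                    oracle_enumerate(g, t, ctx), (g.to_smiles(), t, frozen)


class TestSoundness:
    def test_every_enumerated_action_applies_validly(self):
        ctx = ActionContext(allowed_elements=frozenset("CNOF"),
                            max_heavy_atoms=12)
        for g in random_graphs(10, max_atoms=12, seed=21):
            for t in ActionType:
                for act in enumerate_actions(g, t, ctx):
                    result = apply_action(g, act)  # raises if invalid
                    assert result.is_valid()
                    assert result.n_atoms <= ctx.max_heavy_atoms


class TestReversibility:
    def test_append_remove_roundtrip(self, ctx_cnof):
        for g in random_graphs(6, max_atoms=6, seed=31):
            key = g.to_smiles()
            for act in enumerate_actions(g, ActionType.APPEND_ATOM,
                                         ctx_cnof)[:5]:
                grown = apply_action(g, act)
                new_atom = max(grown.atom_indices)
                back = apply_action(grown, Action(ActionType.REMOVE_ATOM,
                                                  (new_atom,)))
                assert back.to_smiles() == key

    def test_insert_cut_roundtrip(self, ctx_cnof):
        for g in random_graphs(6, max_atoms=6, seed=32):
            key = g.to_smiles()
            for act in enumerate_actions(g, ActionType.INSERT_CARBON,
                                         ctx_cnof)[:5]:
                if g.bond_order(*act.params) != 1:
                    continue  # cut relinks with a single bond only
                grown = apply_action(g, act)
                new_atom = max(grown.atom_indices)
                if grown.bond_order(*act.params) != 0:
                    continue  # neighbours re-bonded elsewhere; cut illegal
                back = apply_action(grown, Action(ActionType.CUT_ATOM,
                                                  (new_atom,)))
                assert back.to_smiles() == key

    def test_change_bond_self_inverse(self, ctx_cnof):
        for g in random_graphs(6, max_atoms=6, seed=33):
            key = g.to_smiles()
            for act in enumerate_actions(g, ActionType.CHANGE_BOND,
                                         ctx_cnof)[:8]:
                i, j, _new = act.params
                old = g.bond_order(i, j)
                there = apply_action(g, act)
                back = apply_action(there, Action(ActionType.CHANGE_BOND,
                                                  (i, j, old)))
                assert back.to_smiles() == key


class TestCountInvariants:
    def test_atom_count_deltas(self, ctx_cnof):
        for g in random_graphs(8, max_atoms=7, seed=41):
            n = g.n_atoms
            deltas = {ActionType.APPEND_ATOM: 1,
                      ActionType.INSERT_CARBON: 1,
                      ActionType.REMOVE_ATOM: -1,
                      ActionType.CUT_ATOM: -1,
                      ActionType.MOVE_GROUP: 0,
                      ActionType.SUBSTITUTE_ATOM_TYPE: 0,
                      ActionType.CHANGE_BOND: 0}
            for t, d in deltas.items():
                for act in enumerate_actions(g, t, ctx_cnof)[:4]:
                    assert apply_action(g, act).n_atoms == n + d

    def test_move_group_preserves_element_multiset(self, ctx_cnof):
        for g in random_graphs(8, max_atoms=7, seed=42):
            elements = sorted(a.element for _, a in g.atoms())
            for act in enumerate_actions(g, ActionType.MOVE_GROUP,
                                         ctx_cnof)[:6]:
                moved = apply_action(g, act)
                assert sorted(a.element
                              for _, a in moved.atoms()) == elements


class TestSerialisation:
    def test_labels(self):
        assert Action(ActionType.APPEND_ATOM, (3, "N")).serialise() \
            == "Ad(3,N)"
        assert Action(ActionType.CHANGE_BOND, (2, 5, 2)).serialise() \
            == "Ch(2,5,→2)"
        assert {t.label for t in ActionType} == \
            {"Ad", "Rm", "Ch", "Sub", "In", "Ct", "Mv"}
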