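"""Random mutations and the first-improver search.

A mutation is a sequence of k actions, k drawn uniformly in
``1..max_actions``.  At each sub-step the action *type* is drawn uniformly
among the types that currently have at least one legal action, then the
concrete action uniformly within that type; both draws are uniform so the
operator makes no assumption about the chemical space.

``find_improver`` repeats the mutation up to ``max_tries`` times and accepts
the first candidate scoring at least the floor (the score of the individual
to be replaced); equal scores are accepted so the search can walk fitness
plateaus.  Candidates already present in the population — or identical to
their own parent — never count as improvers.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from enum import Enum
from typing import Container, Optional

from .actions import Action, ActionContext, apply_action, enumerate_actions
from .graph import MolecularGraph
from .objectives import EvaluationFailure, ObjectiveFunction

__all__ = ["MutationSpec", "MutationStatus", "MutationOutcome",
           "NoLegalAction", "draw_mutation", "find_improver"]


@dataclass
class MutationSpec:
    """Mutation-operator parameters.

    max_actions : most actions composed into one mutation (k is uniform on
        ``1..max_actions``); 2 in the standard profile, 3 for primary-only
        or methane-start runs.
    max_tries : improver-search budget per replacement slot (default 50).
    """

    max_actions: int = 2
    max_tries: int = 50

    def __post_init__(self) -> None:
        if self.max_actions < 1 or self.max_tries < 1:
            raise ValueError("max_actions and max_tries must be >= 1")


class NoLegalAction(RuntimeError):
    """No action type has a legal action at some mutation sub-step."""


class MutationStatus(Enum):
    IMPROVER_FOUND = "improver_found"
    NO_IMPROVER = "no_improver"
    NO_LEGAL_ACTION = "no_legal_action"


@dataclass
class MutationOutcome:
    status: MutationStatus
    result_graph: Optional[MolecularGraph] = None
    result_key: Optional[str] = None
    result_score: Optional[float] = None
    actions_taken: list[Action] = field(default_factory=list)
    evaluations_spent: int = 0
    tries_spent: int = 0


def draw_mutation(graph: MolecularGraph, spec: MutationSpec,
                  ctx: ActionContext, rng: random.Random,
                  ) -> tuple[MolecularGraph, list[Action]]:
    """Draw and apply one random multi-action mutation.

    Raises :class:`NoLegalAction` if at some sub-step no action type has a
    legal action (only possible in heavily constrained contexts).
    Every intermediate graph is valid by construction.
    """
    k = rng.randint(1, spec.max_actions)
    current = graph
    taken: list[Action] = []
    for _ in range(k):
        # rejection-sample the action type: uniform over the types that
        # currently have >= 1 legal action, without enumerating all types
        remaining = sorted(ctx.action_types, key=lambda t: t.name)
        action = None
        while remaining:
            chosen_type = remaining.pop(rng.randrange(len(remaining)))
            actions = enumerate_actions(current, chosen_type, ctx)
            if actions:
                action = rng.choice(actions)
                break
        if action is None:
            raise NoLegalAction(
                f"no legal action on {current.to_smiles()!r}")
        current = apply_action(current, action)
        taken.append(action)
    return current, taken


def find_improver(parent: MolecularGraph, floor_score: float,
                  objective: "ObjectiveFunction", spec: MutationSpec,
                  ctx: ActionContext, rng: random.Random,
                  existing_keys: Container[str] = frozenset(),
                  eval_budget: Optional[int] = None) -> MutationOutcome:
    """First-improver search: mutate ``parent`` until a candidate scores
    ``>= floor_score``, for at most ``spec.max_tries`` tries.

    A candidate is rejected without scoring when its canonical key equals
    the parent's or is already in ``existing_keys``, or when the objective's
    hard constraint (if any) fails.  ``eval_budget`` caps the number of
    *new* objective evaluations this call may trigger (cache hits are free);
    the search stops early once it is exhausted.
    """
    parent_key = parent.to_smiles()
    evals = 0
    tries = 0
    for _ in range(spec.max_tries):
        if eval_budget is not None and evals >= eval_budget:
            break
        tries += 1
        try:
            candidate, taken = draw_mutation(parent, spec, ctx, rng)
        except NoLegalAction:
            if tries == 1:
                # deterministic: if nothing is legal once, nothing ever is
                return MutationOutcome(MutationStatus.NO_LEGAL_ACTION,
                                       tries_spent=tries)
            continue
        key = candidate.to_smiles()
        if key == parent_key or key in existing_keys:
            continue
        if not objective.admits(candidate):
            continue
        cached = objective.is_cached(key)
        try:
            score = objective(candidate, key=key)
        except EvaluationFailure:
            continue  # evaluator failure: a failed try, not a low score
        if not cached:
            evals += 1
        if score >= floor_score:
            return MutationOutcome(MutationStatus.IMPROVER_FOUND,
                                   result_graph=candidate, result_key=key,
                                   result_score=score, actions_taken=taken,
                                   evaluations_spent=evals,
                                   tries_spent=tries)
    return MutationOutcome(MutationStatus.NO_IMPROVER,
                           evaluations_spent=evals, tries_spent=tries)
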