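"""Steady-state evolutionary loop: mutate the best, replace the worst.

The population is a fixed-capacity collection of unique molecules (identity
by canonical aromatic SMILES).  While below capacity, each step *adds* up to
``n_replaced_per_step`` freshly mutated molecules (bounded by the number of
individuals available to mutate).  At capacity, each step pairs the i-th
best individual with the i-th worst and runs a first-improver search whose
floor is the worst individual's score; on failure the next-best individual
takes over the slot, until the expected number of replacements is done or no
candidate is left.  With capacity 1 this degenerates to a hill climber with
a first-improver policy.

Every insertion is recorded in an :class:`~molevo.tree.ExplorationTree`.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .actions import ActionContext
from .graph import MolecularGraph
from .mutation import MutationSpec, MutationStatus, find_improver
from .objectives import ObjectiveFunction
from .tree import ExplorationTree

__all__ = ["Individual", "Population", "EvolutionConfig", "StepReport",
           "initialise", "step", "run"]


@dataclass
class Individual:
    graph: MolecularGraph
    key: str
    score: float
    birth_step: int
    sub_scores: dict[str, float] = field(default_factory=dict)


class Population:
    """Fixed-capacity, uniqueness-guaranteed collection of individuals."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._by_key: dict[str, Individual] = {}

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, key: str) -> bool:
        return key in self._by_key

    @property
    def keys(self) -> set[str]:
        return set(self._by_key)

    @property
    def members(self) -> list[Individual]:
        return list(self._by_key.values())

    def add(self, ind: Individual) -> None:
        if ind.key in self._by_key:
            raise ValueError(f"duplicate molecule {ind.key!r}")
        if len(self._by_key) >= self.capacity:
            raise ValueError("population is at capacity")
        self._by_key[ind.key] = ind

    def remove(self, key: str) -> Individual:
        return self._by_key.pop(key)

    def sorted_members(self) -> list[Individual]:
        """Best first; ties broken by age (older, i.e. smaller birth step,
        first) for reproducibility."""
        return sorted(self._by_key.values(),
                      key=lambda i: (-i.score, i.birth_step, i.key))

    def best(self) -> Individual:
        return self.sorted_members()[0]

    def mean_score(self) -> float:
        return sum(i.score for i in self._by_key.values()) / len(self._by_key)


@dataclass
class EvolutionConfig:
    """Run parameters for the evolutionary loop."""

    capacity: int = 1
    n_replaced_per_step: int = 1
    max_steps: int = 1500
    max_evaluations: Optional[int] = None
    mutation: MutationSpec = field(default_factory=MutationSpec)
    context: ActionContext = field(default_factory=ActionContext)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_replaced_per_step <= self.capacity):
            raise ValueError(
                "need 1 <= n_replaced_per_step <= capacity, got "
                f"{self.n_replaced_per_step} / {self.capacity}")
        if self.max_steps < 0:
            raise ValueError("max_steps must be >= 0")


@dataclass
class StepReport:
    step: int
    best_score: float
    mean_score: float
    pop_size: int
    evaluations: int
    inserted: int


def _score_graph(graph: MolecularGraph, objective: ObjectiveFunction,
                 birth_step: int) -> Individual:
    key = graph.to_smiles()
    score = objective(graph, key=key)
    return Individual(graph, key, score, birth_step,
                      sub_scores=objective.sub_scores(graph))


def initialise(seeds: Sequence[MolecularGraph], cfg: EvolutionConfig,
               objective: ObjectiveFunction,
               tree: Optional[ExplorationTree] = None) -> Population:
    """Score the seed molecules into a fresh population (and as tree roots).

    Seeds must be valid, mutually distinct by canonical key, and each must
    pass the objective's hard constraint if one is set.  At most
    ``cfg.capacity`` seeds are taken, in the given order.
    """
    if not seeds:
        raise ValueError("at least one seed molecule is required")
    pop = Population(cfg.capacity)
    seen: set[str] = set()
    for g in seeds:
        violations = g.validity_violations()
        if violations:
            raise ValueError(f"invalid seed {g.to_smiles()!r}: {violations}")
        key = g.to_smiles()
        if key in seen:
            raise ValueError(f"duplicate seed molecule {key!r}")
        seen.add(key)
        if len(pop) >= cfg.capacity:
            continue
        if not objective.admits(g):
            raise ValueError(
                f"seed {key!r} fails the hard constraint "
                f"{objective.constraint.name!r}")
        ind = _score_graph(g, objective, birth_step=0)
        pop.add(ind)
        if tree is not None:
            tree.add_root(ind.key, ind.score, 0, ind.sub_scores)
    return pop


def step(pop: Population, cfg: EvolutionConfig,
         objective: ObjectiveFunction, rng: random.Random,
         step_index: int = 0,
         tree: Optional[ExplorationTree] = None) -> StepReport:
    """One evolution step (growth or steady-state); mutates ``pop`` in place."""
    budget_left = (None if cfg.max_evaluations is None
                   else cfg.max_evaluations - objective.n_evaluations)
    inserted = 0
    ranked = pop.sorted_members()
    # uniqueness is global across the run: molecules ever inserted (tree
    # nodes) are tabu, not just current members, so one canonical key can
    # only ever denote one solution
    tabu = pop.keys
    if tree is not None:
        tabu |= set(tree.nodes)

    if len(pop) < pop.capacity:
        # growth phase: add up to n new individuals, each mutated from one
        # of the current members (bounded by how many members exist)
        n_add = min(cfg.n_replaced_per_step, len(ranked),
                    pop.capacity - len(pop))
        for parent in ranked[:n_add]:
            if budget_left is not None and budget_left <= 0:
                break
            outcome = find_improver(
                parent.graph, -math.inf, objective, cfg.mutation,
                cfg.context, rng, existing_keys=tabu,
                eval_budget=budget_left)
            if budget_left is not None:
                budget_left -= outcome.evaluations_spent
            if outcome.status is MutationStatus.IMPROVER_FOUND:
                child = Individual(outcome.result_graph, outcome.result_key,
                                   outcome.result_score, step_index,
                                   objective.sub_scores(outcome.result_graph))
                pop.add(child)
                tabu.add(child.key)
                inserted += 1
                if tree is not None:
                    tree.record(parent.key, child.key, child.score,
                                step_index, outcome.actions_taken,
                                child.sub_scores)
    else:
        # steady state: try to replace the n worst with improvers bred from
        # the best; each best individual fills at most one slot per step
        n = cfg.n_replaced_per_step
        worst = ranked[::-1][:n]          # worst first
        queue = list(ranked)              # best first
        q = 0
        for slot in worst:
            replaced = False
            while q < len(queue) and not replaced:
                if budget_left is not None and budget_left <= 0:
                    q = len(queue)
                    break
                parent = queue[q]
                q += 1
                outcome = find_improver(
                    parent.graph, slot.score, objective, cfg.mutation,
                    cfg.context, rng, existing_keys=tabu,
                    eval_budget=budget_left)
                if budget_left is not None:
                    budget_left -= outcome.evaluations_spent
                if outcome.status is MutationStatus.IMPROVER_FOUND:
                    pop.remove(slot.key)
                    child = Individual(
                        outcome.result_graph, outcome.result_key,
                        outcome.result_score, step_index,
                        objective.sub_scores(outcome.result_graph))
                    pop.add(child)
                    tabu.add(child.key)
                    inserted += 1
                    if tree is not None:
                        tree.record(parent.key, child.key, child.score,
                                    step_index, outcome.actions_taken,
                                    child.sub_scores)
                    replaced = True
            if q >= len(queue) and not replaced:
                break  # no individual left to be mutated this step

    return StepReport(step=step_index, best_score=pop.best().score,
                      mean_score=pop.mean_score(), pop_size=len(pop),
                      evaluations=objective.n_evaluations, inserted=inserted)


def run(cfg: EvolutionConfig, seeds: Sequence[MolecularGraph],
        objective: ObjectiveFunction,
        ) -> tuple[Population, list[StepReport], ExplorationTree]:
    """Full optimisation: initialise, then step until the step limit or the
    evaluation budget is reached.  Deterministic given ``cfg.seed``."""
    rng = random.Random(cfg.seed)
    tree = ExplorationTree()
    pop = initialise(seeds, cfg, objective, tree)
    reports: list[StepReport] = []
    for s in range(1, cfg.max_steps + 1):
        if (cfg.max_evaluations is not None
                and objective.n_evaluations >= cfg.max_evaluations):
            break
        reports.append(step(pop, cfg, objective, rng, step_index=s,
                            tree=tree))
    return pop, reports, tree
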