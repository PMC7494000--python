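"""Run configuration: named experiment presets and resolution to a runnable
setup.

Presets bundle the parameter profiles of the headline experiments (atom set,
size cap, mutation depth, tries, step/evaluation budgets); every field can
be overridden by explicit flags or config-file entries.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Optional

from .actions import ActionContext, ActionType, PRIMARY_ACTIONS
from .evolve import EvolutionConfig
from .mutation import MutationSpec

__all__ = ["RunConfig", "PRESETS", "resolve_preset"]

FULL_ATOM_SET = frozenset({"C", "N", "O", "F", "P", "S", "Cl", "Br"})
CNOF = frozenset({"C", "N", "O", "F"})


@dataclass
class RunConfig:
    """Fully explicit run description, serialisable alongside outputs."""

    objective: str = "qed"
    seed_smiles: tuple[str, ...] = ("C",)
    capacity: int = 1
    n_replaced_per_step: int = 1
    max_steps: int = 1500
    max_evaluations: Optional[int] = None
    max_heavy_atoms: int = 38
    atoms: frozenset[str] = FULL_ATOM_SET
    max_actions: int = 2
    max_tries: int = 50
    primary_only: bool = False
    seed: int = 0
    shingle_table: Optional[str] = None

    def evolution_config(self) -> EvolutionConfig:
        action_types = (PRIMARY_ACTIONS if self.primary_only
                        else tuple(ActionType))
        return EvolutionConfig(
            capacity=self.capacity,
            n_replaced_per_step=self.n_replaced_per_step,
            max_steps=self.max_steps,
            max_evaluations=self.max_evaluations,
            mutation=MutationSpec(max_actions=self.max_actions,
                                  max_tries=self.max_tries),
            context=ActionContext(allowed_elements=self.atoms,
                                  max_heavy_atoms=self.max_heavy_atoms,
                                  action_types=action_types),
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["atoms"] = sorted(self.atoms)
        d["seed_smiles"] = list(self.seed_smiles)
        return d


#: Experiment profiles.  "case1-*" are the single-objective baselines from
#: methane (capacity 1 = hill climber, capacity 1000 with 10 replacements);
#: "hillclimb-plogp-budget1000" is the evaluation-budget variant;
#: "guacamol-like" mirrors the goal-directed benchmark profile (50 heavy
#: atoms, 3 actions, 3000 steps) without shipping its task definitions.
PRESETS: dict[str, RunConfig] = {
    "case1-qed-pop1": RunConfig(objective="qed"),
    "case1-plogp-pop1": RunConfig(objective="plogp"),
    "case1-plogp-norm-pop1": RunConfig(objective="plogp_norm"),
    "case1-plogp-pop1-cnof": RunConfig(objective="plogp", atoms=CNOF),
    "case1-sascore-pop1": RunConfig(objective="sascore_norm"),
    "case1-qed-pop1000": RunConfig(objective="qed", capacity=1000,
                                   n_replaced_per_step=10),
    "case1-plogp-pop1000": RunConfig(objective="plogp", capacity=1000,
                                     n_replaced_per_step=10),
    "hillclimb-plogp-budget1000": RunConfig(
        objective="plogp_norm", max_steps=10_000, max_evaluations=1000),
    "guacamol-like": RunConfig(objective="qed", max_heavy_atoms=50,
                               max_actions=3, max_steps=3000),
}


def resolve_preset(name: Optional[str], **overrides) -> RunConfig:
    """A preset (or the default profile) with explicit overrides applied."""
    base = PRESETS[name] if name else RunConfig()
    overrides = {k: v for k, v in overrides.items() if v is not None}
    if "atoms" in overrides:
        overrides["atoms"] = frozenset(overrides["atoms"])
    if "seed_smiles" in overrides:
        overrides["seed_smiles"] = tuple(overrides["seed_smiles"])
    return replace(base, **overrides)
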