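"""Scoring functions and combinators guiding the evolutionary search.

Implemented here: drug-likeness (QED), synthetic accessibility (SAscore and
its [0,1] normalisation), penalised logP in raw and ZINC-normalised form,
the shingle-based ChEMBL-likeness CLscore, sigmoid transforms and their
product composite for multi-property objectives, a hard-constraint wrapper,
and a contract for expensive external property evaluators (e.g. DFT
frontier-orbital energies).

QED, Crippen logP and the raw SAscore delegate to their standard published
definitions as shipped with RDKit; everything else is assembled here.

Every :class:`ObjectiveFunction` caches by canonical SMILES and counts only
cache misses, so the evaluation counter equals the number of distinct
molecules scored.
"""

from __future__ import annotations

import gzip
import json
import math
import os
import sys
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, QED

from .graph import MolecularGraph

__all__ = [
    "ObjectiveFunction", "ConstraintPredicate", "EvaluationFailure",
    "PlogPConfig", "SigmoidSpec", "CompositeObjective",
    "ShingleWeightTable", "ExternalPropertyEvaluator",
    "qed", "sascore", "sascore_normalised", "plogp", "clscore",
    "sigmoid", "shingles",
    "qed_objective", "sascore_objective", "plogp_objective",
    "clscore_objective", "composite_objective", "constrain",
    "CLSCORE_SIGMOID", "LUMO_SIGMOID", "HOMO_SIGMOID",
]


# ---------------------------------------------------------------------------
# objective-function contract

class EvaluationFailure(RuntimeError):
    """An evaluator could not produce a value for this molecule.

    Distinct from a low score: the search treats the candidate as a failed
    try instead of inserting it with a bad value.
    """


@dataclass
class ConstraintPredicate:
    """A hard pass/fail rule applied before scoring (e.g. a compound-quality
    rule set).  Pure: same graph, same verdict."""

    name: str
    test: Callable[[MolecularGraph], bool]

    def __call__(self, graph: MolecularGraph) -> bool:
        return bool(self.test(graph))


class ObjectiveFunction:
    """Pure scoring contract with canonical-key caching.

    ``evaluate`` maps a :class:`MolecularGraph` to a float.  The counter
    increments only on cache misses, so it equals the number of distinct
    molecules evaluated.  An optional :class:`ConstraintPredicate` screens
    candidates *before* scoring; rejected candidates never touch the cache
    or the counter.
    """

    def __init__(self, evaluate: Callable[[MolecularGraph], float],
                 name: str = "objective",
                 constraint: Optional[ConstraintPredicate] = None):
        self._evaluate = evaluate
        self.name = name
        self.constraint = constraint
        self.cache: dict[str, float] = {}
        self.n_evaluations = 0
        self.n_calls = 0  # including cache hits

    def admits(self, graph: MolecularGraph) -> bool:
        return self.constraint is None or self.constraint(graph)

    def is_cached(self, key: str) -> bool:
        return key in self.cache

    def __call__(self, graph: MolecularGraph,
                 key: Optional[str] = None) -> float:
        if key is None:
            key = graph.to_smiles()
        self.n_calls += 1
        if key in self.cache:
            return self.cache[key]
        value = float(self._evaluate(graph))
        self.cache[key] = value
        self.n_evaluations += 1
        return value

    def with_constraint(self, predicate: ConstraintPredicate,
                        ) -> "ObjectiveFunction":
        return ObjectiveFunction(self._evaluate,
                                 name=f"{self.name}|{predicate.name}",
                                 constraint=predicate)

    def sub_scores(self, graph: MolecularGraph) -> dict[str, float]:
        """Per-component scores where meaningful; empty by default."""
        return {}


def constrain(objective: ObjectiveFunction,
              predicate: ConstraintPredicate) -> ObjectiveFunction:
    """Wrap an objective with a hard constraint: candidates failing
    ``predicate`` are discarded before scoring, so every molecule ever
    inserted in a run passes it."""
    return objective.with_constraint(predicate)


# ---------------------------------------------------------------------------
# QED and SAscore (standard definitions via RDKit)

def qed(graph: MolecularGraph) -> float:
    """Quantitative estimate of drug-likeness, in [0, 1] (1 best)."""
    return float(QED.qed(graph.to_rdkit()))


_sascorer = None


def _load_sascorer():
    global _sascorer
    if _sascorer is None:
        from rdkit.Chem import RDConfig
        sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
        if sa_dir not in sys.path:
            sys.path.append(sa_dir)
        import sascorer  # noqa: F401  (RDKit contrib module)
        _sascorer = sascorer
    return _sascorer


def sascore(graph: MolecularGraph) -> float:
    """Synthetic-accessibility score (fragment-contribution method),
    typically in [1, 10]; 1 is easiest to synthesise."""
    return float(_load_sascorer().calculateScore(graph.to_rdkit()))


def sascore_normalised(graph: MolecularGraph) -> float:
    """(10 - SAscore) / 9: maps [1, 10] onto [0, 1] with 1 best."""
    return (10.0 - sascore(graph)) / 9.0


# ---------------------------------------------------------------------------
# penalised logP

@dataclass
class PlogPConfig:
    """Penalised-logP assembly: logP - SAscore - large-ring penalty.

    With ``normalised=True`` each component is z-scored first; the default
    constants are the ZINC-250k statistics used by the reference
    goal-directed-generation implementations.
    """

    normalised: bool = False
    logp_mean: float = 2.4570953396190123
    logp_std: float = 1.434324401111988
    sa_mean: float = 3.0525811293166134
    sa_std: float = 0.8335207024513095
    cycle_mean: float = 0.0485696876403053
    cycle_std: float = 0.2860212110245455
    ring_size_threshold: int = 6

    def __post_init__(self) -> None:
        if self.normalised and min(self.logp_std, self.sa_std,
                                   self.cycle_std) <= 0:
            raise ValueError("z-score stds must be > 0")


def ring_penalty(graph: MolecularGraph, threshold: int = 6) -> int:
    """Number of atoms by which the largest SSSR ring exceeds ``threshold``."""
    mol = graph.to_rdkit()
    rings = mol.GetRingInfo().AtomRings()
    largest = max((len(r) for r in rings), default=0)
    return max(0, largest - threshold)


def plogp(graph: MolecularGraph,
          cfg: Optional[PlogPConfig] = None) -> float:
    """Penalised logP: octanol-water partition coefficient penalised by the
    SAscore and by any ring larger than the threshold."""
    cfg = cfg or PlogPConfig()
    mol = graph.to_rdkit()
    logp = Crippen.MolLogP(mol)
    sa = float(_load_sascorer().calculateScore(mol))
    rings = mol.GetRingInfo().AtomRings()
    largest = max((len(r) for r in rings), default=0)
    cycle = max(0, largest - cfg.ring_size_threshold)
    if cfg.normalised:
        return ((logp - cfg.logp_mean) / cfg.logp_std
                - (sa - cfg.sa_mean) / cfg.sa_std
                - (cycle - cfg.cycle_mean) / cfg.cycle_std)
    return logp - sa - cycle


# ---------------------------------------------------------------------------
# CLscore: shingle-based ChEMBL-likeness

def shingles(graph: MolecularGraph, radius_max: int = 3,
             rooted: bool = True) -> set[str]:
    """Distinct circular substructures of radius 1..radius_max around every
    heavy atom, serialised as (rooted) SMILES substructure strings."""
    mol = graph.to_rdkit()
    out: set[str] = set()
    for atom_idx in range(mol.GetNumAtoms()):
        for radius in range(1, radius_max + 1):
            bonds = AllChem.FindAtomEnvironmentOfRadiusN(mol, radius,
                                                         atom_idx)
            if not bonds:
                break
            atoms = set()
            for b in bonds:
                bond = mol.GetBondWithIdx(b)
                atoms.add(bond.GetBeginAtomIdx())
                atoms.add(bond.GetEndAtomIdx())
            out.add(Chem.MolFragmentToSmiles(
                mol, atomsToUse=sorted(atoms), bondsToUse=list(bonds),
                rootedAtAtom=atom_idx if rooted else -1))
    return out


class ShingleWeightTable:
    """Map shingle substructure string -> weight.

    Unknown shingles weigh 0.  Typically the weights are log10 occurrence
    counts of each shingle in a reference corpus of bioactive compounds;
    the table is consumed as a file, not derived here.
    """

    def __init__(self, weights: Mapping[str, float], radius_max: int = 3):
        self.weights = {k: float(v) for k, v in weights.items()}
        for k, w in self.weights.items():
            if not math.isfinite(w):
                raise ValueError(f"non-finite weight for shingle {k!r}")
        self.radius_max = radius_max

    def __len__(self) -> int:
        return len(self.weights)

    def weight(self, shingle: str) -> float:
        return self.weights.get(shingle, 0.0)

    @classmethod
    def from_json(cls, path: str, radius_max: int = 3,
                  ) -> "ShingleWeightTable":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            return cls(json.load(fh), radius_max)

    @classmethod
    def from_tsv(cls, path: str, radius_max: int = 3,
                 ) -> "ShingleWeightTable":
        weights = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                shingle, w = line.split("\t")
                weights[shingle] = float(w)
        return cls(weights, radius_max)

    @classmethod
    def from_molecules(cls, smiles_list: Iterable[str], radius_max: int = 3,
                       ) -> "ShingleWeightTable":
        """Build a table from a small corpus: weight = log10(count), with
        singletons weighing 0 (log10 1).  Useful for tests and toy runs."""
        counts: dict[str, int] = {}
        for smi in smiles_list:
            g = MolecularGraph.from_smiles(smi)
            for s in shingles(g, radius_max):
                counts[s] = counts.get(s, 0) + 1
        return cls({s: math.log10(c) for s, c in counts.items()}, radius_max)


def clscore(graph: MolecularGraph, table: ShingleWeightTable) -> float:
    """Mean table weight over the molecule's distinct shingles; 0 when the
    molecule yields no shingle (e.g. a single atom)."""
    sh = shingles(graph, table.radius_max)
    if not sh:
        return 0.0
    return sum(table.weight(s) for s in sh) / len(sh)


# ---------------------------------------------------------------------------
# sigmoids and composites

@dataclass(frozen=True)
class SigmoidSpec:
    """Logistic transform ``x -> 1 / (1 + exp(sign * steepness * (x - center)))``.

    ``sign=-1`` gives an increasing sigmoid, ``sign=+1`` a decreasing one;
    the output is strictly inside (0, 1) and equals 0.5 at the center.
    """

    steepness: float = 1.0
    center: float = 0.0
    sign: int = -1

    def __call__(self, x: float) -> float:
        z = self.sign * self.steepness * (x - self.center)
        # clamp so the result stays strictly inside (0, 1) in float64
        z = max(-30.0, min(30.0, z))
        return 1.0 / (1.0 + math.exp(z))


def sigmoid(x: float, spec: SigmoidSpec) -> float:
    return spec(x)


#: 1 / (1 + e^{10(-x + 1.5)}) — gates candidates below ChEMBL-likeness ~1.5
CLSCORE_SIGMOID = SigmoidSpec(steepness=10.0, center=1.5, sign=-1)
#: 1 / (1 + e^{x}) — rewards low LUMO energies (eV)
LUMO_SIGMOID = SigmoidSpec(steepness=1.0, center=0.0, sign=+1)
#: 1 / (1 + e^{-x - 7}) — rewards high HOMO energies (eV)
HOMO_SIGMOID = SigmoidSpec(steepness=1.0, center=-7.0, sign=-1)


@dataclass
class CompositeObjective:
    """Product of sigmoid-transformed property values.

    ``factors`` pairs a property extractor (graph -> float, may raise
    :class:`EvaluationFailure`) with the sigmoid applied to it.  The product
    lies strictly in (0, 1) and is monotone in each property.
    """

    factors: Sequence[tuple[Callable[[MolecularGraph], float], SigmoidSpec]]

    def __call__(self, graph: MolecularGraph) -> float:
        value = 1.0
        for extract, spec in self.factors:
            value *= spec(float(extract(graph)))
        return value


class ExternalPropertyEvaluator:
    """Contract for expensive external property calculations.

    Wraps a callable ``graph -> float | None`` (None signalling failure,
    e.g. an unconverged geometry).  Results — including failures — are
    cached by canonical key; a failure raises :class:`EvaluationFailure`
    so it can never be mistaken for a low score.
    """

    _FAILED = object()

    def __init__(self, compute: Callable[[MolecularGraph], Optional[float]],
                 name: str = "external"):
        self._compute = compute
        self.name = name
        self.cache: dict[str, object] = {}
        self.n_evaluations = 0
        self.n_failures = 0

    def __call__(self, graph: MolecularGraph) -> float:
        key = graph.to_smiles()
        if key not in self.cache:
            self.n_evaluations += 1
            value = self._compute(graph)
            if value is None:
                self.n_failures += 1
                self.cache[key] = self._FAILED
            else:
                self.cache[key] = float(value)
        cached = self.cache[key]
        if cached is self._FAILED:
            raise EvaluationFailure(
                f"{self.name} evaluator failed for {key!r}")
        return cached  # type: ignore[return-value]


def heteroatom_surrogate(graph: MolecularGraph) -> float:
    """Deterministic toy stand-in for a frontier-orbital evaluator.

    Synthetic: a cheap electron-count heuristic (more N/O/F lowers the
    value), *not* a quantum-chemistry result.  It exists so composite
    electronic-property objectives can be wired and tested without a DFT
    driver plugged into :class:`ExternalPropertyEvaluator`.
    """
    pull = {"N": 0.8, "O": 1.0, "F": 1.2, "Cl": 0.7, "Br": 0.6,
            "S": 0.4, "P": 0.3}
    value = 1.0
    for _idx, atom in graph.atoms():
        value -= pull.get(atom.element, 0.05)
    return value


# ---------------------------------------------------------------------------
# named-objective factories

def qed_objective() -> ObjectiveFunction:
    return ObjectiveFunction(qed, name="qed")


def sascore_objective(normalised: bool = True) -> ObjectiveFunction:
    if normalised:
        return ObjectiveFunction(sascore_normalised, name="sascore_norm")
    return ObjectiveFunction(sascore, name="sascore")


class _PlogP(ObjectiveFunction):
    def __init__(self, cfg: PlogPConfig):
        name = "plogp_norm" if cfg.normalised else "plogp"
        super().__init__(lambda g: plogp(g, cfg), name=name)
        self.cfg = cfg

    def sub_scores(self, graph: MolecularGraph) -> dict[str, float]:
        return {
            "logp": float(Crippen.MolLogP(graph.to_rdkit())),
            "sascore": sascore(graph),
            "ring_penalty": float(
                ring_penalty(graph, self.cfg.ring_size_threshold)),
        }


def plogp_objective(normalised: bool = False,
                    cfg: Optional[PlogPConfig] = None) -> ObjectiveFunction:
    if cfg is None:
        cfg = PlogPConfig(normalised=normalised)
    return _PlogP(cfg)


def clscore_objective(table: ShingleWeightTable) -> ObjectiveFunction:
    return ObjectiveFunction(lambda g: clscore(g, table), name="clscore")


def composite_objective(
        factors: Sequence[tuple[Callable[[MolecularGraph], float],
                                SigmoidSpec]],
        name: str = "composite") -> ObjectiveFunction:
    return ObjectiveFunction(CompositeObjective(factors), name=name)
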