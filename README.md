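# molevo

Evolutionary de novo molecular generation on valence-constrained molecular
graphs.

`molevo` is for researchers who need to *search* chemical space — drug-like
or far outside it — with an optimiser that is independent of training data,
guarantees the validity and uniqueness of every molecule it proposes, and
leaves behind an interpretable record of how it got there. Molecules are
heavy-atom graphs with implicit hydrogens, edited by seven chemically
meaningful atom-level mutations (append atom, remove atom, change bond;
substitute atom type, insert carbon, cut atom, move group). A steady-state
evolutionary loop mutates the best-scoring individuals to replace the
worst, accepting the *first improver* found (ties accepted, so plateaus can
be crossed); with a population of one it reduces to a hill climber. Illegal
edits — disconnecting the graph, exceeding an element's valence, touching
the bonds of a charged atom, editing frozen atoms — are filtered *before*
application, so every intermediate and final molecule is valid by
construction, and duplicate solutions are excluded by canonical-SMILES
identity. Every insertion becomes a node of an exploration tree whose edges
carry the applied actions (`Ad`/`Rm`/`Ch`/`Sub`/`In`/`Ct`/`Mv`).

Built-in objectives: QED, SAscore and its [0,1] normalisation
SAscore‡ = (10 − SA)/9, penalised logP

    plogP(m)  = logP(m) − SA(m) − max(0, maxRing(m) − 6)
    plogP‡(m) = z(logP) − z(SA) − z(ringPenalty)        (ZINC z-scores)

shingle-based ChEMBL-likeness (CLscore = mean table weight of the
molecule's circular substructures, radius 1–3), sigmoid transforms
1/(1+e^{sign·a·(x−c)}) and their products for multi-property targets, hard
constraint predicates (candidates failing a rule are rejected before
scoring), and a plug-in contract for expensive external evaluators such as
DFT frontier-orbital energies.

## Worked example

A hill climb from methane maximising normalised penalised logP under a
budget of 1000 objective evaluations:

```bash
molevo run --preset hillclimb-plogp-budget1000 --seed 1 --out out_plogp
```

prints (abridged):

```json
{
 "best_smiles": "CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC",
 "best_score": 11.193972511319698,
 "mean_score": 11.193972511319698,
 "pop_size": 1,
 "evaluations": 1000,
 "steps": 67,
 "tree_nodes": 41
}
```

The optimiser walks from CH4 to the 38-carbon unbranched alkane — the
optimum of this objective in this search space, because the z-scored
SAscore term outweighs the halogen/heteroatom logP gains that dominate the
*unnormalised* objective — and reaches its final score well inside the
budget. `out_plogp/` contains the per-step log (`steps.csv`), the final
population with sub-scores (`population.csv`), the exploration tree
(`tree.json`, `tree.dot` — render with Graphviz), and the fully resolved
configuration (`config.json`), which reproduces the run byte-for-byte:

```bash
molevo run --objective plogp_norm --seed-smiles C --pop-size 1 \
    --max-evals 1000 --max-steps 10000 --seed 1 --out again
```

Library use mirrors the CLI:

```python
from molevo import MolecularGraph, run, resolve_preset, plogp_objective

cfg = resolve_preset("case1-qed-pop1000", capacity=100, max_steps=300)
pop, reports, tree = run(cfg.evolution_config(),
                         [MolecularGraph.from_smiles("C")],
                         plogp_objective(normalised=True))
print(pop.best().key, pop.best().score)
```

Presets (`molevo presets`) cover the standard experiment profiles: single
hill climber and 1000-molecule populations for QED/plogP (full atom set
C,N,O,F,P,S,Cl,Br or restricted C,N,O,F; ≤38 heavy atoms; up to 2 actions
per mutation; 50 improver tries; 1500 steps) and a goal-directed profile
(≤50 atoms, 3 actions, 3000 steps).

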