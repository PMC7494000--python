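# Methods

## The model

`molevo` searches chemical space with a steady-state evolutionary algorithm
over *molecular graphs*: undirected graphs whose nodes are heavy atoms
(element, formal charge, mutability flag) and whose edges carry integer bond
orders 1–3. Hydrogens are implicit — every atom is assumed saturated with H
up to its maximum valence — so the only valence fault that can occur is
hypervalence (bond-order sum above the element's maximum). Graphs are kept
in Kekulé form; aromaticity appears only at the identity boundary, where a
molecule's canonical aromatic SMILES (RDKit canonicalisation) serves as its
key for deduplication, caching and tree bookkeeping.

Default maximum valences: C 4, N 3, O 2, F 1, P 3, S 2, Cl 1, Br 1
(configurable). Expanded valence states of S and P are excluded by default:
a single per-element maximum keeps the a-priori action filters unambiguous.
Charged atoms may only enter through the input (no action creates or
neutralises charges); their allowed valence is fixed at parse time from the
parsed connectivity (explicit bonds + implicit hydrogens), which is
well-defined because no action may alter the bonds of a charged atom.

## The seven actions

Three primary actions span the space: **append atom** (new atom, single
bond), **remove atom**, **change bond** (any pair of atoms, new order 0–3,
covering bond creation and therefore ring closure). Four secondary actions
are shortcuts composed of primary effects: **substitute atom type**,
**insert carbon** (replace a bond a–b by a–C–b with two single bonds),
**cut atom** (remove an atom with exactly two, mutually unbonded,
neighbours and relink them with a single bond), and **move group**
(relocate one side of a bridge bond to another atom of the kept side,
conserving the bond order).

Enumeration applies four filters *a priori*, so an enumerated action is
guaranteed to produce a valid (connected, hypervalence-free, within the
heavy-atom cap) graph without trial application:

1. dislocation — deletions that split the graph (bridge bonds, articulation
   atoms) are excluded;
2. hypervalence — bond-increasing edits require matching free valence;
3. charged atoms — no action may add/delete/re-order a bond incident to a
   charged atom or substitute it, except removal of the charged atom
   itself (ionic subgraphs are conserved or dropped whole);
4. frozen atoms — substitute/cut need a mutable atom, change-bond /
   insert-carbon / move-group a pair with a mutable member, remove a
   mutable atom; appending *onto* a frozen atom remains legal.

Choices made where the action definitions left room:

- The last atom can never be removed; the empty molecule is unrepresentable.
- Both sides of a bridge are candidate groups for move-group; the
  destination must lie on the kept side and differ from the current
  attachment atom.
- Insert-carbon requires carbon in the run's allowed element set.
- Substitution on charged atoms is excluded (no charge bookkeeping is
  defined for it).
- Atom indices are stable for a molecule's lifetime (removal leaves holes),
  so logged actions stay interpretable.

Secondary actions do not extend the reachable space: every one-secondary-
action product is reachable by primary actions alone. The test suite
verifies this by breadth-first search; most products need ≤3 primary steps,
but valence-saturated neighbourhoods can require up to 6 (e.g. substituting
the inner carbon of vinyl cyanide), so the BFS oracle searches to depth 6.

## Mutation and selection

A mutation applies k successive actions, k uniform on 1..`max_actions`
(default 2; 3 for primary-only or methane-start profiles). At each sub-step
the action *type* is drawn uniformly among the types that currently admit
at least one action — implemented by rejection sampling, which realises
exactly that distribution — then the concrete action uniformly within the
type. Both draws are uniform to avoid assumptions about the chemical space.

The loop is steady-state with a *first-improver* policy. At capacity, each
step pairs the i-th best individual with the i-th worst and searches, up to
`max_tries` (default 50) mutations, for a candidate scoring ≥ the worst's
score (equality accepted: plateau exploration). On failure the next-best
individual takes the slot; each best individual fills at most one slot per
step. Below capacity, steps *add* up to `n_replaced_per_step` new
molecules, bounded by the number of existing members, so a run can start
from a single methane. Capacity 1 degenerates to a hill climber.

Uniqueness is global: a canonical key ever inserted (a node of the
exploration tree) is tabu for the improver search, so the set of solutions
a run generates contains no duplicates even across replacements. Candidates
identical to their own parent count as failed tries.

Objective values are cached by canonical key; the evaluation counter
increments only on cache misses and therefore equals the number of distinct
molecules scored. The `max_evaluations` budget bounds that counter; the
run loop and each improver search stop when it is exhausted. The per-run
logs also expose `n_calls` (objective invocations including cache hits),
which is the appropriate figure when comparing against conventions that
count every scoring call.

## Objectives

- **QED** and raw **SAscore** delegate to the standard published
  definitions shipped with RDKit (QED module; `Contrib/SA_Score` fragment
  contributions). SAscore‡ = (10 − SA)/9 maps [1,10] to [0,1], 1 best.
- **Penalised logP**: Crippen logP − SAscore − max(0, largest SSSR ring − 6).
  The normalised variant z-scores each component with ZINC-250k constants
  (logP 2.457/1.434, SA 3.053/0.834, ring penalty 0.0486/0.286) before
  combination; both the constants and the ring threshold are configuration.
- **CLscore**: mean weight of the molecule's distinct circular
  substructures ("shingles", radius 1–3 around each atom, rooted canonical
  substructure SMILES) against a weight table; unknown shingles weigh 0, a
  shingle-free molecule scores 0. The table is consumed as a JSON/TSV file;
  `ShingleWeightTable.from_molecules` builds log10-count tables from small
  corpora for tests and toy runs.
- **Sigmoid composites**: logistic transforms
  1/(1+e^{sign·a·(x−c)}) with presets centred at CLscore 1.5 (steepness
  10), LUMO 0 eV and HOMO −7 eV, multiplied together for multi-property
  objectives. The exponent is clamped at ±30 so outputs stay strictly
  inside (0,1) in float64.
- **Hard constraints**: a predicate wrapper screens candidates before
  scoring; failing candidates count as failed mutation tries, so 100% of
  inserted molecules pass the rule by construction.
- **External evaluators**: expensive properties (e.g. DFT frontier-orbital
  energies) plug in through `ExternalPropertyEvaluator`, a one-molecule-in /
  one-number-out contract whose failures raise instead of scoring low and
  are cached. A deterministic heteroatom-count surrogate ships so the
  composite wiring is testable without a quantum-chemistry driver; it is a
  synthetic stand-in, not a physical model.

## Problem sizes in the shipped tests

The test-suite and acceptance-script runs use the preset profiles
(≤38 heavy atoms, 2 actions, 50 tries; population 1 or scaled populations
of ~100) with step counts chosen so the whole suite completes on a single
CPU in minutes: the budgeted hill climbs run to their 1000-evaluation
limit; long-protocol population claims are demonstrated on reduced
capacity/steps where the note in each test states what the scaled run is
expected to show (monotone approach, exceeding the single-individual
optimum). Exhaustive oracle comparisons run on deterministic samples of
small molecules (≤6–7 atoms) rather than the full combinatorial space.

## Known limitations

- No stereochemistry, isotopes, conformers or 3-D geometry; actions never
  touch them and objectives see only the graph.
- No crossover/recombination and no diversity mechanism; searches can
  intensify on one basin (visible in exploration trees).
- Expanded S/P valences are off by default; runs wanting hypervalent
  sulfur must supply a custom valence table.
- The CLscore of real ChEMBL-likeness requires an externally derived
  457k-compound shingle table; the package only consumes such files.
- GuacaMol task definitions and DFT drivers are integration seams
  (constraint predicates, external evaluators), not shipped features.
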