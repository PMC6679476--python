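# ancestate

Ancestral discrete-character state reconstruction and evolutionary-scenario
exploration on rooted phylogenies.

Phylogeographers and molecular epidemiologists routinely ask where a virus
lineage came from, when a resistance trait arose, or how a host shift
propagated — questions answered by combining a phylogeny of sampled
sequences with one discrete trait observed at its tips (country, host,
resistance status), inferring the trait at every internal node, and then
reading the **transitions** (state changes between parent and child, root
to tips) as the evolutionary scenario. `ancestate` is a headless library
plus CLI for that whole workflow: inference, scenario summarization,
querying, and cross-method comparison.

## What it computes

**Reconstruction** of one character over a rooted (possibly
multifurcating) tree:

* *Parsimony* with ACCTRAN (changes accelerated toward the root) and
  DELTRAN (changes delayed toward the tips) resolutions; polytomies are
  first-class and every resolution provably attains the minimum change
  count.
* *Maximum likelihood* under an F81-type model: transition probability
  `P(i→j|t) = π_j(1−e^{−μσt}) + [i=j]e^{−μσt}` with
  `μ = 1/(1−Σπ_s²)`, stationary frequencies `π` estimated from tip
  frequencies (add-one smoothed) or supplied, and a single global branch
  scaling factor `σ` fitted by ML to adapt sequence-scale branch lengths
  to the character's own rate. Outputs are marginal posteriors with
  per-node MAP states, and the jointly most probable full scenario via
  max-product dynamic programming.
* *Import* of already-annotated trees (BEAST-style NEXUS node comments).

**Scenario summaries**: transition events with root distances; transition
maps of types 1–3 (each event a node; identical sibling transitions
merged with counts; identical transitions under the same ancestral state
merged map-wide); count and relative-rate transition matrices; wildcard
path queries (`"Greece * Albania"`); an ambiguity filter (states within
a fraction of the MAP probability); the Sz criterion (descendant leaves
sharing a node's state); and per-node agreement/discrepancy across any
set of methods, including shared/unique marking of transition maps.
Outputs are CSV, Newick (maps included), and deterministic SVG.

See `docs/methods.md` for the models, numerical choices, and limitations.

## Worked example

The repository ships a six-leaf, three-state example
(`tests/data/fig3.nwk`, `tests/data/fig3_leaves.csv`) whose full curated
annotation contains exactly four transitions: gray→red twice (two
independent red clades), gray→gold once, and red→gold once.

```python
from ancestate import (fig3_fixture, extract_transitions, build_map_type1,
                       collapse_type2, map_to_newick, transition_count_matrix)

tree, states = fig3_fixture()
events = extract_transitions(tree, states)
print(map_to_newick(collapse_type2(build_map_type1(tree, states))))
print(transition_count_matrix(events, ("gold", "gray", "red")))
```

prints

```
((gold|1)red|2,gold|1)gray|1;
      gold  gray  red
gold     0     0    0
gray     1     0    2
red      1     0    0
```

— the type-2 transition map: a gray root, a merged gray→red node with
collapse count **2** (the two independent red clades), one gray→gold
event, and one red→gold event below the red node; the count matrix shows
the same four events by ordered state pair.

Reconstructing from the tips alone tells a subtly different story:

```sh
ancestate run --tree tests/data/fig3.nwk --annotations tests/data/fig3_leaves.csv \
  --methods map,deltran --out-dir out
```

reports (in `out/summary.json`)

```
"events": {"deltran": 3, "map": 3},
"log_likelihood": -6.129017861384946,
"sigma": 1.0279440061216811,
"n_discrepant_nodes": 3
```

Both MAP and DELTRAN prefer a three-change scenario (a red root instead
of the curated gray one) — with so few gray tips the data cannot anchor
gray ancestry, a small illustration of why comparing methods and
inspecting ambiguous nodes matters before believing a single scenario.
The run directory also contains per-method state CSVs, posteriors,
matrices, map Newicks/SVGs, and the annotated-tree SVG.

## Command-line interface

`ancestate` exposes `simulate`, `reconstruct`, `transitions`, `matrix`,
`query`, `compare`, `draw`, and `run` (the full pipeline). For example:

```sh
ancestate simulate --n 100 --states 4 --sigma 2.0 --seed 42 --out-prefix sim
ancestate reconstruct --tree sim.nwk --annotations sim_leaves.csv \
  --method map --method joint --out states.csv
ancestate query --tree sim.nwk --annotations sim_leaves.csv "gray * gold"
ancestate draw --tree sim.nwk --annotations sim_leaves.csv \
  --what map --map-type 2 --layout radial --svg map.svg
```

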