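"""Deterministic synthetic data: Yule trees, simulated characters, and the
worked three-state example used throughout the documentation and tests.

Trees are drawn from a pure-birth (Yule) process — the topology source is
irrelevant to the reconstruction algorithms, so the simplest standard model
is used — and characters evolve along them under the scaled F81 process
with known priors, so parameter-recovery experiments have a ground truth.
All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .f81 import F81Model, f81_transition_probability
from .treedata import CharacterData, Node, NodeAnnotationSet, PhyloTree

__all__ = [
    "SimulationConfig",
    "generate_tree",
    "simulate_character",
    "fig3_fixture",
    "random_annotated_fixture",
]

DEFAULT_ALPHABET = ("blue", "gold", "gray", "red")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-data generator.

    ``birth_rate`` is the Yule speciation rate (events per unit branch
    length); with rate 1 the expected tree height is roughly log(n).
    ``sigma`` is the branch scaling factor of the character process.
    """

    n_leaves: int = 100
    birth_rate: float = 1.0
    alphabet: Tuple[str, ...] = DEFAULT_ALPHABET
    pi: Optional[Sequence[float]] = None  # default: uniform
    sigma: float = 1.0
    seed: int = 0

    def model(self) -> F81Model:
        pi = (
            np.full(len(self.alphabet), 1.0 / len(self.alphabet))
            if self.pi is None
            else np.asarray(self.pi, dtype=float)
        )
        return F81Model(tuple(self.alphabet), pi, sigma=self.sigma)


def generate_tree(config: SimulationConfig) -> PhyloTree:
    """Ultrametric Yule tree with ``n_leaves`` tips.

    Forward simulation: starting from the root's two lineages, waiting
    times between birth events are exponential with rate (number of open
    lineages) x birth_rate, and a uniformly chosen lineage splits, until
    the target tip count is reached.  Leaf labels are ``L1..Ln`` in an
    arbitrary but seed-stable order.
    """
    n = config.n_leaves
    if n < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(config.seed)
    next_id = [0]

    def new_node() -> Node:
        node = Node(next_id[0])
        next_id[0] += 1
        return node

    root = new_node()
    first = [new_node(), new_node()]
    for c in first:
        c.parent = root
        root.children.append(c)
    open_lineages = list(first)
    birth_time = {c.id: 0.0 for c in first}
    t = 0.0
    while len(open_lineages) < n:
        k = len(open_lineages)
        t += rng.exponential(1.0 / (k * config.birth_rate))
        idx = rng.integers(k)
        parent = open_lineages.pop(int(idx))
        parent.length = t - birth_time[parent.id]
        kids = [new_node(), new_node()]
        for c in kids:
            c.parent = parent
            parent.children.append(c)
            birth_time[c.id] = t
        open_lineages.extend(kids)
    # run until just before the (n+1)-th birth, then close all lineages
    # (ultrametric; avoids zero-length terminal branches)
    t += rng.exponential(1.0 / (n * config.birth_rate))
    for leaf in open_lineages:
        leaf.length = t - birth_time[leaf.id]
    for i, leaf in enumerate(open_lineages):
        leaf.label = f"L{i + 1}"
    tree = PhyloTree(root)
    tree.renumber_preorder()
    return tree


def simulate_character(
    tree: PhyloTree, model: F81Model, seed: int = 0
) -> Tuple[CharacterData, NodeAnnotationSet]:
    """Evolve one discrete character down the tree under the F81 model.

    The root state is drawn from the stationary distribution; each edge
    applies the model's transition probability for its (scaled) length.
    Returns the observable leaf data and the full ground-truth annotation.
    """
    rng = np.random.default_rng(seed)
    k = len(model.states)
    truth = NodeAnnotationSet()
    index: Dict[int, int] = {}
    for node in tree.preorder():
        if node.parent is None:
            s = int(rng.choice(k, p=model.pi))
        else:
            p = f81_transition_probability(model, node.length or 0.0)
            s = int(rng.choice(k, p=p[index[node.parent.id]]))
        index[node.id] = s
        truth[node.id] = model.states[s]
    assignment = {leaf.label: truth[leaf.id] for leaf in tree.leaves()}
    data = CharacterData(
        name="trait", alphabet=tuple(model.states), assignment=assignment
    )
    return data, truth


def fig3_fixture() -> Tuple[PhyloTree, NodeAnnotationSet]:
    """Small fully annotated three-state tree used as the worked example.

    Its transition multiset is exactly {gray->red x2, gray->gold x1,
    red->gold x1}, with the two independent gray->red events both hanging
    directly off the gray root in the type-1 transition map — so the type-2
    collapse merges them into a single node with count 2.
    """
    tree = PhyloTree.from_nested(
        (
            "R",
            None,
            [
                (
                    "I1",
                    1.0,
                    [
                        ("t1", 1.0, [("L1", 1.0), ("L2", 1.0)]),
                        ("L3", 2.0),
                    ],
                ),
                ("t2", 2.0, [("L4", 1.0), ("L5", 1.0)]),
                ("L6", 3.0),
            ],
        )
    )
    by_label = {n.label: n.id for n in tree.preorder()}
    states = {
        "R": "gray",
        "I1": "gray",
        "t1": "red",
        "L1": "red",
        "L2": "gold",
        "L3": "gray",
        "t2": "red",
        "L4": "red",
        "L5": "red",
        "L6": "gold",
    }
    annotations = NodeAnnotationSet({by_label[l]: s for l, s in states.items()})
    return tree, annotations


def random_annotated_fixture(
    seed: int, n_leaves: int = 20, n_states: int = 3, sigma: float = 1.0
) -> Tuple[PhyloTree, NodeAnnotationSet, F81Model]:
    """One seeded tree with a fully annotated character (simulation truth)."""
    config = SimulationConfig(
        n_leaves=n_leaves,
        alphabet=DEFAULT_ALPHABET[:n_states],
        sigma=sigma,
        seed=seed,
    )
    tree = generate_tree(config)
    model = config.model()
    _, truth = simulate_character(tree, model, seed=seed + 1)
    return tree, truth, model
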