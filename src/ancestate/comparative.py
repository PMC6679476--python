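"""Comparison of ancestral reconstructions from multiple methods.

Probabilistic and deterministic methods are made comparable by reducing
every reconstruction to its per-node majority state (for distributions, the
highest-probability state).  Discrepant nodes are internal nodes where at
least two methods disagree on that majority state; leaves are excluded
because every method pins annotated leaves to their observed state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Set, Tuple, Union

import pandas as pd

from .f81 import MarginalPosteriors
from .transitions import TransitionMap
from .treedata import AnnotationError, NodeAnnotationSet, PhyloTree

__all__ = [
    "ComparisonResult",
    "majority_state",
    "as_states",
    "discrepant_nodes",
    "map_compatibility",
]

Reconstruction = Union[NodeAnnotationSet, Mapping[int, str], MarginalPosteriors]


def majority_state(distribution: Mapping[str, float]) -> Tuple[str, bool]:
    """Highest-probability state of a distribution, with a tie flag.

    Ties are broken by lexicographic state order (deterministic); the flag
    reports whether a tie occurred.
    """
    if not distribution:
        raise ValueError("empty distribution")
    top = max(distribution.values())
    winners = sorted(s for s, p in distribution.items() if p == top)
    return winners[0], len(winners) > 1


def as_states(recon: Reconstruction) -> NodeAnnotationSet:
    """Reduce any reconstruction to one state per node (majority rule)."""
    if isinstance(recon, MarginalPosteriors):
        out = NodeAnnotationSet()
        for node_id, p in recon.probs.items():
            out[node_id], _ = majority_state(dict(zip(recon.states, map(float, p))))
        return out
    out = NodeAnnotationSet()
    out.update(recon)
    return out


@dataclass
class ComparisonResult:
    methods: List[str]
    table: pd.DataFrame  # index: node id; one column per method + "agree"
    discrepant: Set[int]  # internal nodes with >= 2 disagreeing methods

    @property
    def n_discrepant(self) -> int:
        return len(self.discrepant)


def discrepant_nodes(
    reconstructions: Mapping[str, Reconstruction], tree: PhyloTree
) -> ComparisonResult:
    """Node-wise agreement across two or more reconstructions.

    Every reconstruction must cover every node of the tree.  The result
    table carries each method's majority state per node and an agreement
    flag; the discrepant set contains the internal nodes where methods
    disagree.
    """
    if len(reconstructions) < 2:
        raise ValueError("need at least two reconstructions to compare")
    reduced = {name: as_states(r) for name, r in reconstructions.items()}
    all_ids = [n.id for n in tree.preorder()]
    for name, states in reduced.items():
        missing = sorted(i for i in all_ids if i not in states)
        if missing:
            raise AnnotationError(f"method {name!r} does not cover nodes {missing}")
    methods = list(reduced)
    internal = {n.id for n in tree.preorder() if not n.is_leaf}
    rows = {}
    discrepant: Set[int] = set()
    for node_id in all_ids:
        states = [reduced[m][node_id] for m in methods]
        agree = len(set(states)) == 1
        rows[node_id] = [*states, agree]
        if not agree and node_id in internal:
            discrepant.add(node_id)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=[*methods, "agree"]
    )
    table.index.name = "node_id"
    return ComparisonResult(methods=methods, table=table, discrepant=discrepant)


def map_compatibility(
    map_a: TransitionMap, map_b: TransitionMap
) -> Tuple[Dict[int, bool], Dict[int, bool]]:
    """Shared/unique marking of two transition maps of the same type.

    A map node is *shared* when the other map contains a node with the
    identical root-to-node state sequence.  Returns one
    ``map-node id -> shared`` dict per map; the relation is symmetric and
    reflexive.
    """
    if map_a.map_type != map_b.map_type:
        raise ValueError(
            f"cannot compare maps of different types "
            f"({map_a.map_type} vs {map_b.map_type})"
        )
    paths_a = {n.id: map_a.state_path(n) for n in map_a.preorder()}
    paths_b = {n.id: map_b.state_path(n) for n in map_b.preorder()}
    set_a, set_b = set(paths_a.values()), set(paths_b.values())
    return (
        {i: p in set_b for i, p in paths_a.items()},
        {i: p in set_a for i, p in paths_b.items()},
    )
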