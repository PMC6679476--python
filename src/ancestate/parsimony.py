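"""Parsimony ancestral reconstruction with ACCTRAN and DELTRAN resolutions.

The downpass is a unit-cost dynamic program over subtree change counts
(Sankoff with the Fitch cost), whose per-node argmin sets coincide with the
Fitch downpass sets on binary trees and with Hartigan's majority sets on
polytomies, so multifurcating trees are first-class.

Ambiguity resolution works in preorder on the exact subtree-cost tables.
Given the parent's assigned state ``a`` and a node's table ``c``, the
optimal choices are forced except when ``c[a] == min(c) + 1``, where either
keeping the parent's state (one change somewhere below) or switching now
(one change on this edge) completes a minimum-change labeling:

* ACCTRAN switches immediately — the change is accelerated toward the root;
* DELTRAN keeps the parent's state — the change is delayed toward the tips.

Remaining ties (including the root's) are broken by lexicographic state
order, so results are deterministic.  Branch lengths are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Tuple

import numpy as np

from .treedata import AnnotationError, CharacterData, NodeAnnotationSet, PhyloTree

__all__ = ["ParsimonyResult", "fitch_downpass", "acctran", "deltran"]


@dataclass
class ParsimonyResult:
    """A single minimum-change labeling plus the downpass evidence."""

    method: str  # "acctran" | "deltran"
    states: NodeAnnotationSet  # node id -> final state
    state_sets: Dict[int, FrozenSet[str]]  # node id -> downpass (argmin) set
    score: int  # minimum number of changes

    def realized_changes(self, tree: PhyloTree) -> int:
        return sum(
            1
            for node in tree.preorder()
            if node.parent is not None
            and self.states[node.id] != self.states[node.parent.id]
        )


def _subtree_costs(
    tree: PhyloTree, data: CharacterData
) -> Tuple[np.ndarray, List[str]]:
    """Per-node, per-state minimum subtree change counts (unit cost).

    Missing leaves cost 0 in every state (fully ambiguous).
    """
    states = list(data.alphabet)
    k = len(states)
    index = {s: i for i, s in enumerate(states)}
    leaf_states = data.leaf_states(tree)
    if all(s is None for s in leaf_states.values()):
        raise AnnotationError("character uninformative: all leaves missing")
    n = len(tree)
    cost = np.zeros((n, k), dtype=np.int64)
    for node in tree.postorder():
        if node.is_leaf:
            s = leaf_states[node.id]
            if s is not None:
                cost[node.id, :] = 1 << 30  # big, not overflow-prone
                cost[node.id, index[s]] = 0
        else:
            acc = np.zeros(k, dtype=np.int64)
            for child in node.children:
                c = cost[child.id]
                acc += np.minimum(c, c.min() + 1)
            cost[node.id] = acc
    return cost, states


def fitch_downpass(
    tree: PhyloTree, data: CharacterData
) -> Tuple[Dict[int, FrozenSet[str]], int]:
    """Downpass state sets and the minimum change count.

    The set at each node contains the states achieving the minimum subtree
    change count (Fitch sets on binary trees, Hartigan sets on polytomies);
    the score is the overall minimum number of changes on the tree.
    """
    cost, states = _subtree_costs(tree, data)
    sets = {
        node.id: frozenset(
            states[i] for i in np.flatnonzero(cost[node.id] == cost[node.id].min())
        )
        for node in tree.preorder()
    }
    return sets, int(cost[tree.root.id].min())


def _resolve(tree: PhyloTree, data: CharacterData, accelerate: bool) -> ParsimonyResult:
    cost, states = _subtree_costs(tree, data)
    index = {s: i for i, s in enumerate(states)}
    sets = {
        node.id: frozenset(
            states[i] for i in np.flatnonzero(cost[node.id] == cost[node.id].min())
        )
        for node in tree.preorder()
    }
    final = NodeAnnotationSet()
    for node in tree.preorder():
        c = cost[node.id]
        m = int(c.min())
        best = sorted(sets[node.id])  # lexicographic tie-break
        if node.parent is None:
            final[node.id] = best[0]
            continue
        a = final[node.parent.id]
        ca = int(c[index[a]])
        if ca == m:
            # keeping the parent's state is strictly optimal (any switch
            # spends an extra change on this edge)
            final[node.id] = a
        elif ca == m + 1:
            # genuine ACCTRAN/DELTRAN choice point
            final[node.id] = best[0] if accelerate else a
        else:
            final[node.id] = best[0]
    result = ParsimonyResult(
        method="acctran" if accelerate else "deltran",
        states=final,
        state_sets=sets,
        score=int(cost[tree.root.id].min()),
    )
    return result


def acctran(tree: PhyloTree, data: CharacterData) -> ParsimonyResult:
    """Minimum-change labeling with changes accelerated toward the root."""
    return _resolve(tree, data, accelerate=True)


def deltran(tree: PhyloTree, data: CharacterData) -> ParsimonyResult:
    """Minimum-change labeling with changes delayed toward the tips."""
    return _resolve(tree, data, accelerate=False)
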