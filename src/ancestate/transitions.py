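"""Transition extraction and scenario summaries.

A transition is a change of reconstructed state between a node and its
parent, read top-down from the root.  This module turns a single-state
annotation of a tree into:

* a list of transition events (with root-to-node cumulative distances),
* transition maps of types 1-3 (multifurcating trees of state changes,
  progressively collapsed),
* transition matrices (raw counts, or count-based relative rates),
* wildcard path queries over compressed root-to-leaf state sequences,
* the ambiguity filter over marginal posteriors, and
* the Sz size criterion (number of descendant leaves sharing a node's
  annotation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .f81 import MarginalPosteriors
from .treedata import AnnotationError, NodeAnnotationSet, PhyloTree, _format_label, _format_length

__all__ = [
    "TransitionEvent",
    "TransitionMap",
    "MapNode",
    "PathPattern",
    "extract_transitions",
    "build_map_type1",
    "collapse_type2",
    "collapse_type3",
    "map_to_newick",
    "transition_count_matrix",
    "relative_rate_matrix",
    "query_paths",
    "ambiguous_nodes",
    "size_criterion",
]


@dataclass(frozen=True)
class TransitionEvent:
    """One state change, attributed to the child endpoint of its edge."""

    node_id: int  # tree node where the new state starts
    parent_state: str
    state: str
    distance: float  # root-to-node path length, input units

    def __post_init__(self) -> None:
        if self.parent_state == self.state:
            raise ValueError("a transition requires two distinct states")
        if self.distance < 0:
            raise ValueError("negative cumulative distance")


class MapNode:
    """Node of a transition map: a state-change class with a collapse count."""

    __slots__ = ("id", "state", "count", "members", "distance", "children", "parent")

    def __init__(
        self,
        node_id: int,
        state: str,
        count: int = 1,
        members: Optional[Set[int]] = None,
        distance: float = 0.0,
    ) -> None:
        self.id = node_id
        self.state = state
        self.count = count
        self.members: Set[int] = set(members or ())
        self.distance = distance
        self.children: List["MapNode"] = []
        self.parent: Optional["MapNode"] = None


@dataclass
class TransitionMap:
    """Rooted multifurcating tree of transition events.

    ``map_type`` 1 keeps one node per event; 2 merges identical sibling
    transitions; 3 additionally merges identical transitions across the
    map whenever their parents carry the same state.  Node distances are
    the event's root-to-node path length (type 1) or the minimum over the
    merged members (types 2-3); the full member sets are kept so other
    summaries stay recoverable.
    """

    root: MapNode
    map_type: int

    def preorder(self) -> List[MapNode]:
        out: List[MapNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def nonroot_nodes(self) -> List[MapNode]:
        return [n for n in self.preorder() if n is not self.root]

    def total_count(self) -> int:
        return sum(n.count for n in self.nonroot_nodes())

    def renumber(self) -> None:
        for i, node in enumerate(self.preorder()):
            node.id = i

    def state_path(self, node: MapNode) -> Tuple[str, ...]:
        """Root-to-node sequence of map states (compatibility key)."""
        path: List[str] = []
        cur: Optional[MapNode] = node
        while cur is not None:
            path.append(cur.state)
            cur = cur.parent
        return tuple(reversed(path))


def _require_full_states(tree: PhyloTree, states: NodeAnnotationSet) -> None:
    states.require_full(tree)


def extract_transitions(
    tree: PhyloTree, states: NodeAnnotationSet
) -> List[TransitionEvent]:
    """All state changes between parent and child, in preorder.

    Every node must carry a single state (reduce distributions with
    :func:`ancestate.comparative.majority_state` first).  Cumulative
    distances sum branch lengths from the root; absent lengths contribute 0
    and trigger a warning.
    """
    _require_full_states(tree, states)
    if not tree.has_branch_lengths() and any(
        n.length is None for n in tree.preorder() if n.parent is not None
    ):
        warnings.warn(
            "missing branch lengths contribute 0 to cumulative distances",
            stacklevel=2,
        )
    depths = tree.depths()
    events: List[TransitionEvent] = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        a, b = states[node.parent.id], states[node.id]
        if a != b:
            events.append(
                TransitionEvent(
                    node_id=node.id, parent_state=a, state=b, distance=depths[node.id]
                )
            )
    return events


def build_map_type1(tree: PhyloTree, states: NodeAnnotationSet) -> TransitionMap:
    """Type-1 transition map: the annotated tree contracted along
    state-constant edges.

    The map root carries the tree root's state; each transition event
    becomes one map node whose parent is the nearest ancestral event (or
    the root).
    """
    _require_full_states(tree, states)
    depths = tree.depths()
    root = MapNode(0, states[tree.root.id], count=1, members={tree.root.id}, distance=0.0)
    # walk the tree carrying the current map node; child order preserved
    stack: List[Tuple] = [(tree.root, root)]
    while stack:
        node, mnode = stack.pop()
        descend: List[Tuple] = []
        for child in node.children:
            if states[child.id] != states[node.id]:
                mchild = MapNode(
                    -1,
                    states[child.id],
                    count=1,
                    members={child.id},
                    distance=depths[child.id],
                )
                mchild.parent = mnode
                mnode.children.append(mchild)
                descend.append((child, mchild))
            else:
                descend.append((child, mnode))
        stack.extend(reversed(descend))
    out = TransitionMap(root=root, map_type=1)
    out.renumber()
    return out


def _merge_group(group: List[MapNode]) -> MapNode:
    head = group[0]
    for other in group[1:]:
        head.count += other.count
        head.members |= other.members
        head.distance = min(head.distance, other.distance)
        for c in other.children:
            c.parent = head
        head.children.extend(other.children)
    return head


def _copy_map(map_: TransitionMap) -> MapNode:
    def dup(node: MapNode) -> MapNode:
        new = MapNode(node.id, node.state, node.count, set(node.members), node.distance)
        for c in node.children:
            cc = dup(c)
            cc.parent = new
            new.children.append(cc)
        return new

    return dup(map_.root)


def collapse_type2(map1: TransitionMap) -> TransitionMap:
    """Type-2 map: merge identical sibling transitions, top-down.

    Children of one map node that carry the same state (hence represent the
    same parent-state -> state transition under the same father) merge into
    a single node whose count is the sum; merged nodes' children are then
    merged against each other recursively.
    """
    if map1.map_type != 1:
        raise ValueError(f"expected a type-1 map, got type {map1.map_type}")
    root = _copy_map(map1)

    def collapse(node: MapNode) -> None:
        groups: Dict[str, List[MapNode]] = {}
        for c in node.children:
            groups.setdefault(c.state, []).append(c)
        node.children = []
        for state in groups:
            merged = _merge_group(groups[state])
            merged.parent = node
            node.children.append(merged)
        for c in node.children:
            collapse(c)

    collapse(root)
    out = TransitionMap(root=root, map_type=2)
    out.renumber()
    return out


def collapse_type3(map2: TransitionMap) -> TransitionMap:
    """Type-3 map: merge identical transitions across the whole map.

    Nodes representing the same transition i -> j (parents share state i)
    collapse into the first such node encountered in preorder; their
    children are re-attached there and re-merged recursively, so the result
    stays a well-formed tree and counts are conserved.
    """
    if map2.map_type != 2:
        raise ValueError(f"expected a type-2 map, got type {map2.map_type}")
    root = _copy_map(map2)

    def preorder(node: MapNode):
        stack = [node]
        while stack:
            cur = stack.pop()
            yield cur
            stack.extend(reversed(cur.children))

    # one merge per scan until no two nodes share a (parent state, state)
    # key; the preorder-first node of each class is kept, so merging moves
    # subtrees toward the root and terminates (node count decreases)
    while True:
        canonical: Dict[Tuple[str, str], MapNode] = {}
        pair = None
        for node in preorder(root):
            for child in node.children:
                key = (node.state, child.state)
                if key not in canonical:
                    canonical[key] = child
                elif canonical[key] is not child:
                    pair = (canonical[key], child)
                    break
            if pair:
                break
        if pair is None:
            break
        canon, dup = pair
        dup.parent.children.remove(dup)
        canon.count += dup.count
        canon.members |= dup.members
        canon.distance = min(canon.distance, dup.distance)
        for gc in dup.children:
            gc.parent = canon
        canon.children.extend(dup.children)
    out = TransitionMap(root=root, map_type=3)
    out.renumber()
    return out


def map_to_newick(map_: TransitionMap) -> str:
    """Serialize a transition map to Newick; labels encode ``state|count``.

    Type-1 maps carry branch lengths equal to distance increments between
    consecutive events.
    """

    def render(node: MapNode) -> str:
        label = _format_label(f"{node.state}|{node.count}")
        if node.children:
            inner = ",".join(render(c) for c in node.children)
            core = f"({inner}){label}"
        else:
            core = label
        if map_.map_type == 1 and node.parent is not None:
            incr = max(node.distance - node.parent.distance, 0.0)
            core += ":" + _format_length(incr)
        return core

    return render(map_.root) + ";"


def transition_count_matrix(
    events: Sequence[TransitionEvent], alphabet: Sequence[str]
) -> pd.DataFrame:
    """State x state table of transition counts (rows = source, zero diagonal)."""
    states = sorted(set(alphabet))
    mat = pd.DataFrame(0, index=states, columns=states, dtype=int)
    for ev in events:
        mat.loc[ev.parent_state, ev.state] += 1
    return mat


def relative_rate_matrix(
    counts: pd.DataFrame, priors: Dict[str, float], normalize_by: str = "target"
) -> pd.DataFrame:
    """Count-based relative transition rates.

    Each count is normalized by the total number of events and divided by a
    state prior — the *target* state's by default; ``normalize_by`` in
    {"target", "source", "both"} selects the alternative conventions.
    """
    for s in counts.index:
        if priors.get(s, 0.0) <= 0:
            raise ValueError(f"state {s!r} has non-positive prior")
    total = int(counts.to_numpy().sum())
    if total == 0:
        warnings.warn("no transitions: relative rates are all zero", stacklevel=2)
        return counts.astype(float)
    rates = counts.astype(float) / total
    pi = pd.Series({s: priors[s] for s in counts.index})
    if normalize_by == "target":
        rates = rates.div(pi, axis=1)
    elif normalize_by == "source":
        rates = rates.div(pi, axis=0)
    elif normalize_by == "both":
        rates = rates.div(pi, axis=1).div(pi, axis=0)
    else:
        raise ValueError(f"unknown normalization {normalize_by!r}")
    return rates


# ---------------------------------------------------------------------------
# wildcard path queries


@dataclass(frozen=True)
class PathPattern:
    """A sequence of state tokens and ``*`` wildcards.

    Consecutive wildcards are redundant and normalized away.  ``*`` matches
    any run of zero or more states; matching is over contiguous
    subsequences of a compressed root-to-leaf state sequence (not
    anchored), unless ``anchor_start``/``anchor_end`` are set.
    """

    tokens: Tuple[str, ...]
    anchor_start: bool = False
    anchor_end: bool = False

    @classmethod
    def parse(cls, text: str) -> "PathPattern":
        raw = text.split()
        anchor_start = anchor_end = False
        if raw and raw[0] == "^":
            anchor_start = True
            raw = raw[1:]
        if raw and raw[-1] == "$":
            anchor_end = True
            raw = raw[:-1]
        tokens: List[str] = []
        for tok in raw:
            if tok == "*" and tokens and tokens[-1] == "*":
                continue
            tokens.append(tok)
        if not tokens:
            raise ValueError("empty path pattern")
        return cls(tuple(tokens), anchor_start, anchor_end)

    def validate(self, alphabet: Sequence[str]) -> None:
        known = set(alphabet)
        bad = [t for t in self.tokens if t != "*" and t not in known]
        if bad:
            raise ValueError(f"pattern states not in alphabet: {bad}")


def _compress(seq: Sequence[str]) -> List[str]:
    out: List[str] = []
    for s in seq:
        if not out or out[-1] != s:
            out.append(s)
    return out


def _match_from(tokens: Sequence[str], seq: Sequence[str], ti: int, si: int) -> bool:
    if ti == len(tokens):
        return True
    tok = tokens[ti]
    if tok == "*":
        # '*' absorbs any run, including an empty one
        return any(_match_from(tokens, seq, ti + 1, j) for j in range(si, len(seq) + 1))
    return si < len(seq) and seq[si] == tok and _match_from(tokens, seq, ti + 1, si + 1)


def _matches(pattern: PathPattern, compressed: Sequence[str]) -> bool:
    tokens = pattern.tokens
    n = len(compressed)
    starts = [0] if pattern.anchor_start else range(n + 1)
    for start in starts:
        if pattern.anchor_end:
            # consume exactly to the end: append a virtual end check
            if _match_to_end(tokens, compressed, 0, start):
                return True
        elif _match_from(tokens, compressed, 0, start):
            return True
    return False


def _match_to_end(tokens: Sequence[str], seq: Sequence[str], ti: int, si: int) -> bool:
    if ti == len(tokens):
        return si == len(seq)
    tok = tokens[ti]
    if tok == "*":
        return any(
            _match_to_end(tokens, seq, ti + 1, j) for j in range(si, len(seq) + 1)
        )
    return si < len(seq) and seq[si] == tok and _match_to_end(tokens, seq, ti + 1, si + 1)


def query_paths(
    tree: PhyloTree,
    states: NodeAnnotationSet,
    pattern: PathPattern | str,
    alphabet: Optional[Sequence[str]] = None,
) -> Tuple[List[Tuple[int, ...]], Set[Tuple[int, int]]]:
    """Root-to-leaf paths whose compressed state sequence matches a pattern.

    A path's compressed sequence drops consecutive duplicate states; the
    pattern matches against any contiguous subsequence of it.  Pattern
    tokens are validated against ``alphabet`` (default: the states realized
    in the annotation).  Returns the matching paths (as node-id tuples,
    root first) and the union of their edges as (parent id, child id)
    pairs.
    """
    if isinstance(pattern, str):
        pattern = PathPattern.parse(pattern)
    _require_full_states(tree, states)
    pattern.validate(sorted(set(states.values())) if alphabet is None else alphabet)
    matched: List[Tuple[int, ...]] = []
    edges: Set[Tuple[int, int]] = set()
    for leaf in tree.leaves():
        path: List[int] = []
        node = leaf
        while node is not None:
            path.append(node.id)
            node = node.parent
        path.reverse()
        compressed = _compress([states[i] for i in path])
        if _matches(pattern, compressed):
            matched.append(tuple(path))
            edges.update(zip(path[:-1], path[1:]))
    return matched, edges


# ---------------------------------------------------------------------------
# display filters


def ambiguous_nodes(
    post: MarginalPosteriors, fraction: float = 0.4
) -> Dict[int, List[str]]:
    """Nodes with several states of high, close posterior probability.

    A node is ambiguous when at least two states have posterior at or above
    the MAP probability minus ``fraction`` of its value, i.e.
    ``(1 - fraction) * p_max``.  Returns, for each ambiguous node, the
    retained states in descending posterior (ties lexicographic).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    out: Dict[int, List[str]] = {}
    for node_id, p in post.probs.items():
        cutoff = (1.0 - fraction) * float(p.max())
        keep = [
            (float(-p[i]), s)
            for i, s in enumerate(post.states)
            if p[i] >= cutoff - 1e-12
        ]
        if len(keep) >= 2:
            out[node_id] = [s for _, s in sorted(keep)]
    return out


def size_criterion(tree: PhyloTree, states: NodeAnnotationSet) -> Dict[int, int]:
    """Sz criterion: descendant leaves sharing each node's annotation.

    For a node v, Sz(v) counts leaves in v's subtree (v itself included when
    it is a leaf) whose state equals state(v).
    """
    _require_full_states(tree, states)
    # per-node leaf-state counters, merged bottom-up
    counts: Dict[int, Dict[str, int]] = {}
    sz: Dict[int, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            counts[node.id] = {states[node.id]: 1}
        else:
            acc: Dict[str, int] = {}
            for child in node.children:
                for s, c in counts[child.id].items():
                    acc[s] = acc.get(s, 0) + c
            counts[node.id] = acc
        sz[node.id] = counts[node.id].get(states[node.id], 0)
    return sz
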