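"""Tree and annotation data model, readers and writers.

The in-memory tree is a thin rooted-tree structure with stable integer node
ids assigned in preorder at construction time.  All other modules refer to
nodes through these ids, because internal node labels may be absent or
duplicated.  Parsing of Newick and NEXUS text is delegated to dendropy; the
writer is local so that round trips are lossless after canonicalization.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import dendropy
import pandas as pd
from dendropy.utility.error import DataParseError as _DendropyParseError

__all__ = [
    "TreeError",
    "NewickParseError",
    "AnnotationError",
    "Node",
    "PhyloTree",
    "CharacterData",
    "NodeAnnotationSet",
    "parse_newick",
    "write_newick",
    "read_annotations_csv",
    "write_annotations_csv",
    "import_nexus_annotated",
    "reroot",
    "ladderize",
    "swap",
]


class TreeError(ValueError):
    """Structural problem with a tree or a tree edit request."""


class NewickParseError(TreeError):
    """Malformed Newick/NEXUS input (position or label named in message)."""


class AnnotationError(ValueError):
    """Annotation data inconsistent with itself or with the bound tree."""


# ---------------------------------------------------------------------------
# core structures


class Node:
    """A single tree node: id, optional label, optional branch length, children.

    ``length`` is the length of the branch leading *into* this node (``None``
    for the root and for topology-only trees).
    """

    __slots__ = ("id", "label", "length", "children", "parent")

    def __init__(
        self,
        node_id: int,
        label: Optional[str] = None,
        length: Optional[float] = None,
    ) -> None:
        if length is not None and length < 0:
            raise TreeError(f"negative branch length {length!r} on node {node_id}")
        self.id = node_id
        self.label = label
        self.length = length
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Node(id={self.id}, label={self.label!r}, length={self.length})"


class PhyloTree:
    """Rooted, possibly multifurcating tree with named leaves.

    Node ids are consecutive integers in preorder (root is 0).  Child order
    is significant and preserved from input.
    """

    def __init__(self, root: Node, allow_duplicate_leaves: bool = False) -> None:
        self.root = root
        self.allow_duplicate_leaves = allow_duplicate_leaves
        self._index: Dict[int, Node] = {}
        self._reindex()
        self._validate()

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_nested(cls, spec) -> "PhyloTree":
        """Build a tree from a nested ``(label, length, [children])`` spec.

        Leaves may be given as a bare label string or ``(label, length)``.
        Ids are assigned in preorder.
        """

        counter = [0]

        def build(item) -> Node:
            if isinstance(item, str):
                label, length, kids = item, None, []
            elif len(item) == 2:
                label, length = item
                kids = []
            else:
                label, length, kids = item
            node = Node(counter[0], label=label, length=length)
            counter[0] += 1
            for k in kids:
                child = build(k)
                child.parent = node
                node.children.append(child)
            return node

        return cls(build(spec))

    def _reindex(self) -> None:
        self._index = {}
        for node in self.preorder():
            self._index[node.id] = node

    def renumber_preorder(self) -> None:
        """Reassign ids 0..n-1 in preorder (used after structural edits)."""
        for i, node in enumerate(self.preorder()):
            node.id = i
        self._reindex()

    def _validate(self) -> None:
        seen = set()
        labels = set()
        for node in self.preorder():
            if node.id in seen:
                raise TreeError(f"duplicate node id {node.id}")
            seen.add(node.id)
            for child in node.children:
                if child.parent is not node:
                    raise TreeError(f"broken parent link at node {child.id}")
            if node.is_leaf:
                if not node.label:
                    raise TreeError(f"leaf node {node.id} has empty label")
                if node.label in labels and not self.allow_duplicate_leaves:
                    raise TreeError(f"duplicate leaf label {node.label!r}")
                labels.add(node.label)

    # -- traversal -----------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> List[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def node(self, node_id: int) -> Node:
        try:
            return self._index[node_id]
        except KeyError:
            raise TreeError(f"no node with id {node_id}") from None

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._index

    def __len__(self) -> int:
        return len(self._index)

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.preorder() if n.is_leaf)

    def leaf_labels(self) -> List[str]:
        return [n.label for n in self.leaves()]

    def depths(self) -> Dict[int, float]:
        """Root-to-node path length per node (missing lengths count 0)."""
        out: Dict[int, float] = {self.root.id: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[node.id] = out[node.parent.id] + (node.length or 0.0)
        return out

    def has_branch_lengths(self) -> bool:
        return all(n.length is not None for n in self.preorder() if n is not self.root)

    def copy(self) -> "PhyloTree":
        def dup(node: Node) -> Node:
            new = Node(node.id, node.label, node.length)
            for child in node.children:
                c = dup(child)
                c.parent = new
                new.children.append(c)
            return new

        return PhyloTree(dup(self.root))

    def leaf_distance_matrix(self) -> pd.DataFrame:
        """Pairwise path lengths between leaves (lower-level oracle for edits)."""
        depths = self.depths()
        leaves = self.leaves()
        # ancestor chains per leaf
        chains: Dict[int, List[int]] = {}
        for lf in leaves:
            chain = []
            node: Optional[Node] = lf
            while node is not None:
                chain.append(node.id)
                node = node.parent
            chains[lf.id] = chain
        labels = [lf.label for lf in leaves]
        mat = pd.DataFrame(0.0, index=labels, columns=labels)
        for i, a in enumerate(leaves):
            seen = set(chains[a.id])
            for b in leaves[i + 1 :]:
                mrca = next(x for x in chains[b.id] if x in seen)
                d = depths[a.id] + depths[b.id] - 2 * depths[mrca]
                mat.loc[a.label, b.label] = d
                mat.loc[b.label, a.label] = d
        return mat

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_nodes={len(self)}, n_leaves={self.n_leaves})"


@dataclass
class CharacterData:
    """One discrete character: taxon label -> state label.

    Taxa absent from ``assignment`` (or mapped to ``None``) are treated as
    missing, i.e. fully ambiguous for downstream inference.
    """

    name: str
    alphabet: Tuple[str, ...]
    assignment: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alphabet = tuple(sorted(set(self.alphabet)))
        if not self.alphabet:
            raise AnnotationError("state alphabet is empty")
        for taxon, state in self.assignment.items():
            if state is not None and state not in self.alphabet:
                raise AnnotationError(
                    f"state {state!r} of taxon {taxon!r} not in alphabet"
                )

    def state_of(self, taxon: str) -> Optional[str]:
        return self.assignment.get(taxon)

    def bind(self, tree: PhyloTree) -> Tuple[List[str], List[str]]:
        """Split the tree's leaves into (annotated, missing) label lists.

        Raises if an assigned taxon does not match any leaf.
        """
        leaf_set = set(tree.leaf_labels())
        unknown = sorted(set(self.assignment) - leaf_set)
        if unknown:
            raise AnnotationError(
                f"annotated taxa not found in tree: {', '.join(unknown)}"
            )
        annotated = [l for l in tree.leaf_labels() if self.assignment.get(l) is not None]
        missing = [l for l in tree.leaf_labels() if self.assignment.get(l) is None]
        return annotated, missing

    def leaf_states(self, tree: PhyloTree) -> Dict[int, Optional[str]]:
        """Map leaf node id -> state (``None`` when missing)."""
        self.bind(tree)
        return {lf.id: self.assignment.get(lf.label) for lf in tree.leaves()}


class NodeAnnotationSet(Dict[int, str]):
    """node id -> state label for every annotated node (internal and leaf).

    A plain dict subclass so transition analysis can consume either imported
    (NEXUS) or inferred annotations uniformly.
    """

    def validate(self, tree: PhyloTree) -> None:
        bad = sorted(i for i in self if i not in tree)
        if bad:
            raise AnnotationError(f"annotation refers to unknown node ids: {bad}")

    def require_full(self, tree: PhyloTree) -> None:
        self.validate(tree)
        missing = sorted(n.id for n in tree.preorder() if n.id not in self)
        if missing:
            raise AnnotationError(f"nodes without annotation: {missing}")


# ---------------------------------------------------------------------------
# Newick I/O


def _from_dendropy(dtree: dendropy.Tree, allow_duplicate_leaves: bool = False) -> PhyloTree:
    counter = [0]

    def build(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        length = dnode.edge.length
        node = Node(counter[0], label=label, length=length)
        counter[0] += 1
        for dchild in dnode.child_nodes():
            child = build(dchild)
            child.parent = node
            node.children.append(child)
        return node

    return PhyloTree(build(dtree.seed_node), allow_duplicate_leaves=allow_duplicate_leaves)


def parse_newick(text: str, allow_duplicate_leaves: bool = False) -> PhyloTree:
    """Parse a single rooted Newick statement into a :class:`PhyloTree`.

    Child order, internal labels and branch lengths are preserved exactly as
    written.  Quoted labels are unquoted; underscores are NOT converted to
    spaces.  A basal polytomy (unrooted convention) is accepted as-is and
    treated as rooted at the outermost node, with a warning.

    ``allow_duplicate_leaves`` relaxes the unique-leaf-label invariant,
    which transition-map Newicks (tips labeled ``state|count``) need.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=allow_duplicate_leaves,
            rooting="force-rooted",
        )
    except _DendropyParseError as exc:
        raise NewickParseError(str(exc)) from exc
    tree = _from_dendropy(dtree, allow_duplicate_leaves=allow_duplicate_leaves)
    if len(tree.root.children) > 2:
        warnings.warn(
            "basal polytomy: input looks unrooted; treating the outermost "
            "node as the root",
            stacklevel=2,
        )
    return tree


_NEEDS_QUOTE = set("()[]{}:;,'\" \t\n")


def _format_label(label: str) -> str:
    if label and not (_NEEDS_QUOTE & set(label)):
        return label
    return "'" + label.replace("'", "''") + "'"


def _format_length(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return format(x, ".12g")


def write_newick(tree: PhyloTree) -> str:
    """Serialize to a single Newick statement (lossless counterpart of parse)."""

    def render(node: Node) -> str:
        if node.is_leaf:
            core = _format_label(node.label or "")
        else:
            inner = ",".join(render(c) for c in node.children)
            core = f"({inner})" + (_format_label(node.label) if node.label else "")
        if node.length is not None:
            core += ":" + _format_length(node.length)
        return core

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# annotation CSV I/O


def read_annotations_csv(
    text: str,
    character: Optional[str] = None,
    taxon_column: Optional[str] = None,
    sep: str = ",",
) -> CharacterData:
    """Read a leaf-annotation table (one row per taxon, header required).

    The taxon identifier column is the first column unless ``taxon_column``
    names another; the character column is ``character`` or, by default, the
    first non-taxon column.  Empty cells mark missing annotations.
    """
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise AnnotationError("need a taxon column plus at least one character column")
    tcol = taxon_column if taxon_column is not None else df.columns[0]
    if tcol not in df.columns:
        raise AnnotationError(f"taxon column {tcol!r} not in CSV header")
    ccols = [c for c in df.columns if c != tcol]
    ccol = character if character is not None else ccols[0]
    if ccol not in ccols:
        raise AnnotationError(f"character column {ccol!r} not in CSV header")
    dup = df[tcol][df[tcol].duplicated()]
    if not dup.empty:
        raise AnnotationError(f"duplicate taxon rows: {sorted(set(dup))}")
    assignment: Dict[str, str] = {}
    for taxon, state in zip(df[tcol], df[ccol]):
        state = state.strip()
        if state:
            assignment[taxon.strip()] = state
    if not assignment:
        raise AnnotationError(f"character {ccol!r} has no annotated taxa")
    return CharacterData(
        name=ccol, alphabet=tuple(sorted(set(assignment.values()))), assignment=assignment
    )


def write_annotations_csv(data: CharacterData, taxon_column: str = "taxon") -> str:
    rows = [{taxon_column: t, data.name: s} for t, s in sorted(data.assignment.items())]
    return pd.DataFrame(rows).to_csv(index=False)


# ---------------------------------------------------------------------------
# NEXUS with BEAST-style node comments


def import_nexus_annotated(
    text: str, trait: str
) -> Tuple[PhyloTree, NodeAnnotationSet]:
    """Read a NEXUS tree whose node comments carry ancestral trait values.

    Supports the BEAST bracket-comment dialect ``[&trait=value]`` and
    ``[&trait="value"]``.  When only ``trait.set``/``trait.set.prob`` paired
    vectors are present on a node, the majority (highest-probability) state
    is used.  Every internal node must end up annotated.
    """
    if not text or not text.strip():
        raise NewickParseError("empty NEXUS input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="nexus",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            extract_comment_metadata=True,
            rooting="force-rooted",
        )
    except _DendropyParseError as exc:
        raise NewickParseError(str(exc)) from exc

    # rebuild with our ids while walking both trees in lockstep
    counter = [0]
    annotations = NodeAnnotationSet()
    unannotated_internal: List[int] = []

    def build(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(counter[0], label=label, length=dnode.edge.length)
        counter[0] += 1
        meta = {a.name: a.value for a in dnode.annotations}
        state = _trait_from_metadata(meta, trait, node.id)
        if state is not None:
            annotations[node.id] = state
        elif dnode.child_nodes():
            unannotated_internal.append(node.id)
        for dchild in dnode.child_nodes():
            child = build(dchild)
            child.parent = node
            node.children.append(child)
        return node

    root = build(dtree.seed_node)
    if unannotated_internal:
        raise AnnotationError(
            f"trait {trait!r} missing on internal nodes: {unannotated_internal}"
        )
    tree = PhyloTree(root)
    annotations.validate(tree)
    return tree, annotations


def _trait_from_metadata(meta: dict, trait: str, node_id: int) -> Optional[str]:
    if trait in meta:
        value = meta[trait]
        if isinstance(value, list):
            raise AnnotationError(
                f"node {node_id}: trait {trait!r} is a vector; expected a scalar"
            )
        return str(value)
    sset, sprob = meta.get(f"{trait}.set"), meta.get(f"{trait}.set.prob")
    if sset is not None:
        if sprob is None or len(sprob) != len(sset):
            raise AnnotationError(
                f"node {node_id}: {trait}.set and {trait}.set.prob do not pair up"
            )
        probs = [float(p) for p in sprob]
        best = max(zip(sset, probs), key=lambda sp: (sp[1], sp[0]))
        # deterministic: on probability ties take the lexicographically
        # *smallest* state
        top = max(probs)
        tied = sorted(s for s, p in zip(sset, probs) if p == top)
        return str(tied[0]) if len(tied) > 1 else str(best[0])
    return None


# ---------------------------------------------------------------------------
# tree edits


def swap(tree: PhyloTree, node_id: int) -> PhyloTree:
    """Return a copy with one node's child order reversed (an involution)."""
    out = tree.copy()
    out.node(node_id).children.reverse()
    out.renumber_preorder()
    return out


def ladderize(tree: PhyloTree, ascending: bool = True) -> PhyloTree:
    """Return a copy with children everywhere sorted by subtree leaf count.

    Stable sort, so equal-sized siblings keep their relative order; the
    operation is idempotent.
    """
    out = tree.copy()
    sizes: Dict[int, int] = {}
    for node in out.postorder():
        sizes[node.id] = 1 if node.is_leaf else sum(sizes[c.id] for c in node.children)
    for node in out.preorder():
        node.children.sort(key=lambda c: sizes[c.id], reverse=not ascending)
    out.renumber_preorder()
    return out


def reroot(tree: PhyloTree, node_id: int) -> Tuple[PhyloTree, bool]:
    """Reroot on the branch above ``node_id``, splitting it at the midpoint.

    Returns ``(new_tree, changed)``.  Rerooting at the current root is a
    no-op flagged with ``changed=False``.  Leaf set and pairwise leaf path
    lengths are preserved; a unary old root left over by the reversal is
    suppressed (its two incident branch lengths merge).
    """
    if node_id == tree.root.id:
        return tree.copy(), False
    work = tree.copy()
    target = work.node(node_id)

    half = None if target.length is None else target.length / 2.0

    # detach target from its parent, then reverse the parent chain
    old_parent = target.parent
    old_parent.children.remove(target)
    target.parent = None

    new_root = Node(-1, label=None, length=None)
    new_root.children.append(target)
    target.parent = new_root
    target.length = half

    # walk up from old_parent to the old root, reversing edges
    prev = new_root
    prev_len = half
    node: Optional[Node] = old_parent
    while node is not None:
        up = node.parent
        up_len = node.length
        if up is not None:
            up.children.remove(node)
        node.parent = prev
        node.length = prev_len
        prev.children.append(node)
        prev, prev_len = node, up_len
        node = up

    # suppress a now-unary old root
    _suppress_unary(new_root)
    out = PhyloTree(new_root)
    out.renumber_preorder()
    return out, True


def _suppress_unary(root: Node) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        i = 0
        while i < len(node.children):
            child = node.children[i]
            if len(child.children) == 1 and child.label is None:
                grand = child.children[0]
                if child.length is not None or grand.length is not None:
                    grand.length = (child.length or 0.0) + (grand.length or 0.0)
                grand.parent = node
                node.children[i] = grand
            else:
                i += 1
        stack.extend(node.children)
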