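"""F81-like maximum-likelihood ancestral reconstruction.

The substitution model is the multi-state Felsenstein 1981 process: from
any state, the chain jumps at rate mu to a state drawn from the stationary
distribution pi, giving the closed-form transition probability

    P(i -> j | t) = pi_j * (1 - exp(-mu * sigma * t)) + [i == j] * exp(-mu * sigma * t)

with mu = 1 / (1 - sum_s pi_s^2) so that one unit of scaled branch length
corresponds to one expected substitution at stationarity.  A single global
scaling factor sigma, fitted by maximum likelihood, adapts branch lengths
(typically estimated from sequences) to the evolutionary rate of the
analyzed character.

Likelihoods use Felsenstein pruning with per-node renormalization to avoid
underflow; marginal posteriors combine an up-pass (inside likelihoods) with
a down-pass (outside likelihoods); the joint reconstruction is the
max-product dynamic program of Pupko et al. with back-pointers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .treedata import AnnotationError, CharacterData, NodeAnnotationSet, PhyloTree

__all__ = [
    "F81Model",
    "MarginalPosteriors",
    "JointReconstruction",
    "estimate_priors",
    "f81_transition_probability",
    "tree_log_likelihood",
    "fit_scaling_factor",
    "marginal_posteriors",
    "map_states",
    "joint_reconstruction",
]

# bounds of the 1-D ML search for the branch scaling factor, in log sigma
_LOG_SIGMA_BOUNDS = (math.log(1e-3), math.log(1e3))
_NEG_INF = float("-inf")


@dataclass
class F81Model:
    states: Tuple[str, ...]
    pi: np.ndarray  # stationary distribution, aligned with `states`
    sigma: float = 1.0
    log_likelihood: Optional[float] = None

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        self.pi = np.asarray(self.pi, dtype=float)
        if len(self.states) != self.pi.size:
            raise ValueError("priors and alphabet sizes differ")
        if np.any(self.pi <= 0):
            raise ValueError("all priors must be strictly positive")
        if not math.isclose(float(self.pi.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("priors must sum to 1")
        if self.sigma <= 0:
            raise ValueError("scaling factor must be positive")

    @property
    def mu(self) -> float:
        """Rate normalization 1 / (1 - sum pi^2)."""
        return 1.0 / (1.0 - float(np.dot(self.pi, self.pi)))

    def state_index(self) -> Dict[str, int]:
        return {s: i for i, s in enumerate(self.states)}


def estimate_priors(
    data: CharacterData, smoothing: float = 1.0
) -> Tuple[Tuple[str, ...], np.ndarray]:
    """Observed leaf state frequencies with add-one smoothing.

    Smoothing keeps every prior strictly positive, as the model requires
    even for states present in the alphabet but unobserved at the leaves.
    """
    states = tuple(data.alphabet)
    observed = [s for s in data.assignment.values() if s is not None]
    if not observed:
        raise AnnotationError("cannot estimate priors: no annotated leaves")
    counts = np.array([observed.count(s) for s in states], dtype=float)
    counts += smoothing
    return states, counts / counts.sum()


def uniform_priors(alphabet: Iterable[str]) -> Tuple[Tuple[str, ...], np.ndarray]:
    states = tuple(sorted(set(alphabet)))
    return states, np.full(len(states), 1.0 / len(states))


def f81_transition_probability(model: F81Model, length: float) -> np.ndarray:
    """Stochastic matrix P(i -> j | length) under the scaled F81 process."""
    if length < 0:
        raise ValueError(f"negative branch length {length!r}")
    e = math.exp(-model.mu * model.sigma * length)
    k = len(model.states)
    return (1.0 - e) * np.tile(model.pi, (k, 1)) + e * np.eye(k)


def _leaf_partials(
    tree: PhyloTree, data: CharacterData, model: F81Model
) -> Dict[int, np.ndarray]:
    if set(data.alphabet) - set(model.states):
        raise AnnotationError("model priors do not cover the data alphabet")
    index = model.state_index()
    k = len(model.states)
    out: Dict[int, np.ndarray] = {}
    for leaf_id, s in data.leaf_states(tree).items():
        v = np.ones(k) if s is None else np.zeros(k)
        if s is not None:
            v[index[s]] = 1.0
        out[leaf_id] = v
    return out


def _edge_lengths(tree: PhyloTree) -> Dict[int, float]:
    """Branch length above each non-root node; absent lengths become 1."""
    if not tree.has_branch_lengths():
        warnings.warn(
            "tree has missing branch lengths; treating them as 1 "
            "(the scaling factor absorbs the unit)",
            stacklevel=3,
        )
    return {
        n.id: (n.length if n.length is not None else 1.0)
        for n in tree.preorder()
        if n.parent is not None
    }


def _pruning(
    tree: PhyloTree, data: CharacterData, model: F81Model
) -> Tuple[Dict[int, np.ndarray], Dict[int, float], Dict[int, np.ndarray], float]:
    """Up-pass.  Returns (partials, per-node log-scalers, edge P-matrices, logL).

    Partials are renormalized per node; the discarded magnitude accumulates
    in log-space scalers so the total likelihood is exact.
    """
    leaf_partials = _leaf_partials(tree, data, model)
    lengths = _edge_lengths(tree)
    pmats = {nid: f81_transition_probability(model, t) for nid, t in lengths.items()}
    partials: Dict[int, np.ndarray] = {}
    logscale: Dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            v = leaf_partials[node.id].copy()
            ls = 0.0
        else:
            v = np.ones(len(model.states))
            ls = 0.0
            for child in node.children:
                v = v * (pmats[child.id] @ partials[child.id])
                ls += logscale[child.id]
        mx = v.max()
        if mx > 0:
            v = v / mx
            ls += math.log(mx)
        else:
            ls = _NEG_INF
        partials[node.id] = v
        logscale[node.id] = ls
    root = tree.root.id
    total = float(np.dot(model.pi, partials[root]))
    logl = _NEG_INF if (total <= 0 or logscale[root] == _NEG_INF) else (
        math.log(total) + logscale[root]
    )
    return partials, logscale, pmats, logl


def tree_log_likelihood(tree: PhyloTree, data: CharacterData, model: F81Model) -> float:
    """Felsenstein-pruning log-likelihood of the leaf data, root weighted by pi.

    Returns ``-inf`` (not an exception) when the data have probability zero,
    e.g. conflicting states across zero-length branches.
    """
    return _pruning(tree, data, model)[3]


def fit_scaling_factor(
    tree: PhyloTree,
    data: CharacterData,
    priors: Optional[Tuple[Tuple[str, ...], np.ndarray]] = None,
) -> F81Model:
    """Fit the global branch scaling factor by 1-D ML on log sigma.

    Bounded Brent search on log sigma in [log 1e-3, log 1e3] (tolerance 1e-6
    in log sigma).  With fewer than two distinct observed states the factor
    is unidentifiable: a warning is issued and sigma = 1 is returned.
    """
    states, pi = priors if priors is not None else estimate_priors(data)
    observed = {s for s in data.assignment.values() if s is not None}
    if len(observed) < 2:
        warnings.warn(
            "scaling factor unidentifiable (fewer than 2 observed states); "
            "using sigma = 1",
            stacklevel=2,
        )
        model = F81Model(states, pi, sigma=1.0)
        model.log_likelihood = tree_log_likelihood(tree, data, model)
        return model

    def neg_logl(log_sigma: float) -> float:
        model = F81Model(states, pi, sigma=math.exp(log_sigma))
        ll = tree_log_likelihood(tree, data, model)
        return 1e300 if ll == _NEG_INF else -ll

    res = minimize_scalar(
        neg_logl,
        bounds=_LOG_SIGMA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    if res.fun >= 1e300:
        raise ValueError("likelihood is non-finite across the whole sigma range")
    lo, hi = _LOG_SIGMA_BOUNDS
    if res.x <= lo + 1e-3 or res.x >= hi - 1e-3:
        warnings.warn(
            f"fitted scaling factor {math.exp(res.x):.4g} sits at the search "
            "bound; the character may carry too little signal",
            stacklevel=2,
        )
    model = F81Model(states, pi, sigma=math.exp(float(res.x)))
    model.log_likelihood = -float(res.fun)
    return model


@dataclass
class MarginalPosteriors:
    """Per-node marginal posterior distributions, P(node = s | leaf data)."""

    states: Tuple[str, ...]
    probs: Dict[int, np.ndarray]
    log_likelihood: float

    def distribution(self, node_id: int) -> Dict[str, float]:
        return dict(zip(self.states, map(float, self.probs[node_id])))


def marginal_posteriors(
    tree: PhyloTree, data: CharacterData, model: F81Model
) -> MarginalPosteriors:
    """Marginal posterior state probabilities at every node.

    One up-pass (inside likelihoods) and one down-pass (outside
    likelihoods); the per-node posterior is their normalized product, so
    each vector sums to 1 and an annotated leaf is a point mass.
    """
    partials, _, pmats, logl = _pruning(tree, data, model)
    if logl == _NEG_INF:
        raise ValueError("data have zero likelihood under the model")
    k = len(model.states)
    outside: Dict[int, np.ndarray] = {tree.root.id: model.pi.copy()}
    for node in tree.preorder():
        out_u = outside[node.id]
        if node.is_leaf:
            continue
        # downward messages: for each child v, combine the parent's outside
        # vector with the inside messages of v's siblings, then push through
        # v's edge matrix
        msgs = [pmats[c.id] @ partials[c.id] for c in node.children]
        for i, child in enumerate(node.children):
            sib = out_u.copy()
            for j, m in enumerate(msgs):
                if j != i:
                    sib = sib * m
            v = pmats[child.id].T @ sib
            mx = v.max()
            outside[child.id] = v / mx if mx > 0 else v
    probs: Dict[int, np.ndarray] = {}
    for node in tree.preorder():
        p = outside[node.id] * partials[node.id]
        total = p.sum()
        if total <= 0:
            raise ValueError(f"zero posterior mass at node {node.id}")
        probs[node.id] = p / total
    return MarginalPosteriors(states=tuple(model.states), probs=probs, log_likelihood=logl)


def map_states(
    post: MarginalPosteriors,
) -> Tuple[NodeAnnotationSet, Set[int]]:
    """Per-node argmax of the marginal posterior (MAP states).

    Ties are broken by lexicographic state order; tied node ids are
    returned in the second element.
    """
    out = NodeAnnotationSet()
    ties: Set[int] = set()
    for node_id, p in post.probs.items():
        mx = p.max()
        winners = sorted(post.states[i] for i in np.flatnonzero(p == mx))
        out[node_id] = winners[0]
        if len(winners) > 1:
            ties.add(node_id)
    return out, ties


@dataclass
class JointReconstruction:
    """Single most probable full assignment of states to all nodes."""

    states: NodeAnnotationSet
    log_probability: float
    ties: Set[int] = field(default_factory=set)


def joint_reconstruction(
    tree: PhyloTree, data: CharacterData, model: F81Model
) -> JointReconstruction:
    """Globally most probable joint assignment (max-product DP, Pupko-style).

    Bottom-up tables C_v(i) = max over s of P(i -> s) * L(subtree of v | s)
    with back-pointers, then a top-down traceback.  Tie-breaks are
    lexicographic and flagged.  Works in log space.
    """
    leaf_partials = _leaf_partials(tree, data, model)
    lengths = _edge_lengths(tree)
    k = len(model.states)
    with np.errstate(divide="ignore"):
        logp = {
            nid: np.log(f81_transition_probability(model, t))
            for nid, t in lengths.items()
        }
    # C[v] : given parent state i, best log-prob of v's subtree incl. v's edge
    C: Dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        if node.is_leaf:
            with np.errstate(divide="ignore"):
                inner = np.log(leaf_partials[node.id])
        else:
            inner = np.zeros(k)
            for child in node.children:
                inner = inner + C[child.id]
        scores = logp[node.id] + inner[None, :]  # [parent i, own s]
        C[node.id] = scores.max(axis=1)

    with np.errstate(divide="ignore"):
        root_scores = np.log(model.pi)
    for child in tree.root.children:
        root_scores = root_scores + C[child.id]
    if np.all(np.isneginf(root_scores)):
        raise ValueError("data have zero likelihood under the model")

    assignment = NodeAnnotationSet()
    ties: Set[int] = set()
    best = float(root_scores.max())
    winners = sorted(model.states[i] for i in np.flatnonzero(root_scores == best))
    assignment[tree.root.id] = winners[0]
    if len(winners) > 1:
        ties.add(tree.root.id)
    index = model.state_index()
    for node in tree.preorder():
        if node.parent is None:
            continue
        i = index[assignment[node.parent.id]]
        scores = logp[node.id][i]
        if not node.is_leaf:
            inner = np.zeros(k)
            for child in node.children:
                inner = inner + C[child.id]
            scores = scores + inner
        else:
            with np.errstate(divide="ignore"):
                scores = scores + np.log(leaf_partials[node.id])
        mx = scores.max()
        winners = sorted(model.states[i] for i in np.flatnonzero(scores == mx))
        assignment[node.id] = winners[0]
        if len(winners) > 1:
            ties.add(node.id)
    return JointReconstruction(
        states=assignment, log_probability=best, ties=ties
    )
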