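"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own algorithms: parsimony
scores come from exhaustive enumeration of labelings, likelihoods and
posteriors from exhaustive summation over internal assignments, and path
queries from a regular-expression matcher.  They are only feasible on tiny
instances, which is the point.
"""

from __future__ import annotations

import itertools
import math
import re
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pytest

from ancestate import (
    CharacterData,
    F81Model,
    PhyloTree,
    SimulationConfig,
    generate_tree,
)


# ---------------------------------------------------------------------------
# tree corpus helpers


def random_tree(seed: int, n_leaves: int, polytomy_prob: float = 0.0) -> PhyloTree:
    """Seeded random tree; optionally contract internal edges into polytomies."""
    tree = generate_tree(SimulationConfig(n_leaves=n_leaves, seed=seed))
    if polytomy_prob > 0:
        rng = np.random.default_rng(seed + 777)
        for node in list(tree.preorder()):
            if node.parent is not None and not node.is_leaf and rng.random() < polytomy_prob:
                parent = node.parent
                i = parent.children.index(node)
                for c in node.children:
                    c.parent = parent
                    if c.length is not None and node.length is not None:
                        c.length += node.length
                parent.children[i : i + 1] = node.children
        tree.renumber_preorder()
    return tree


def random_character(
    tree: PhyloTree,
    alphabet: Sequence[str],
    seed: int,
    missing_prob: float = 0.0,
) -> CharacterData:
    rng = np.random.default_rng(seed)
    assignment = {}
    for leaf in tree.leaves():
        if rng.random() >= missing_prob:
            assignment[leaf.label] = str(rng.choice(list(alphabet)))
    if not assignment:  # keep at least one annotated leaf
        assignment[tree.leaves()[0].label] = str(alphabet[0])
    return CharacterData("trait", tuple(alphabet), assignment)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_parsimony_min(tree: PhyloTree, data: CharacterData) -> int:
    """Minimum change count by exhaustive enumeration of all labelings."""
    leaf_states = {l.id: data.assignment.get(l.label) for l in tree.leaves()}
    free = [n.id for n in tree.preorder() if not n.is_leaf]
    free += [i for i, s in leaf_states.items() if s is None]
    fixed = {i: s for i, s in leaf_states.items() if s is not None}
    edges = [
        (n.parent.id, n.id) for n in tree.preorder() if n.parent is not None
    ]
    best = math.inf
    for combo in itertools.product(data.alphabet, repeat=len(free)):
        lab = dict(zip(free, combo))
        lab.update(fixed)
        best = min(best, sum(1 for u, v in edges if lab[u] != lab[v]))
    return int(best)


def brute_optimal_states(
    tree: PhyloTree, data: CharacterData
) -> Dict[int, set]:
    """Per node, the states realized by at least one minimum-change labeling."""
    leaf_states = {l.id: data.assignment.get(l.label) for l in tree.leaves()}
    free = [n.id for n in tree.preorder() if not n.is_leaf]
    free += [i for i, s in leaf_states.items() if s is None]
    fixed = {i: s for i, s in leaf_states.items() if s is not None}
    edges = [(n.parent.id, n.id) for n in tree.preorder() if n.parent is not None]
    labelings = []
    best = math.inf
    for combo in itertools.product(data.alphabet, repeat=len(free)):
        lab = dict(zip(free, combo))
        lab.update(fixed)
        score = sum(1 for u, v in edges if lab[u] != lab[v])
        if score < best:
            best, labelings = score, [lab]
        elif score == best:
            labelings.append(lab)
    out: Dict[int, set] = {}
    for lab in labelings:
        for i, s in lab.items():
            out.setdefault(i, set()).add(s)
    return out


def _assignment_log_prob(
    tree: PhyloTree, model: F81Model, labeling: Dict[int, str]
) -> float:
    index = model.state_index()
    logp = math.log(model.pi[index[labeling[tree.root.id]]])
    from ancestate import f81_transition_probability

    for node in tree.preorder():
        if node.parent is None:
            continue
        t = node.length if node.length is not None else 1.0
        P = f81_transition_probability(model, t)
        p = P[index[labeling[node.parent.id]], index[labeling[node.id]]]
        if p <= 0:
            return -math.inf
        logp += math.log(p)
    return logp


def brute_likelihood_table(
    tree: PhyloTree, data: CharacterData, model: F81Model
) -> Tuple[float, Dict[int, Dict[str, float]], Dict[int, str], float]:
    """Exhaustive-summation reference quantities.

    Returns (log-likelihood, per-node marginal posteriors, best joint
    assignment, best joint log-probability).
    """
    leaf_states = {l.id: data.assignment.get(l.label) for l in tree.leaves()}
    free = [n.id for n in tree.preorder() if not n.is_leaf]
    free += [i for i, s in leaf_states.items() if s is None]
    fixed = {i: s for i, s in leaf_states.items() if s is not None}
    total = 0.0
    marg: Dict[int, Dict[str, float]] = {
        n.id: {s: 0.0 for s in model.states} for n in tree.preorder()
    }
    best_lab, best_lp = None, -math.inf
    for combo in itertools.product(model.states, repeat=len(free)):
        lab = dict(zip(free, combo))
        lab.update(fixed)
        lp = _assignment_log_prob(tree, model, lab)
        if lp == -math.inf:
            continue
        p = math.exp(lp)
        total += p
        for i, s in lab.items():
            marg[i][s] += p
        if lp > best_lp or (
            lp == best_lp
            and best_lab is not None
            and [lab[i] for i in sorted(lab)] < [best_lab[i] for i in sorted(best_lab)]
        ):
            best_lab, best_lp = dict(lab), lp
    for i in marg:
        for s in marg[i]:
            marg[i][s] /= total
    return math.log(total), marg, best_lab, best_lp


def regex_path_match(pattern_tokens: Sequence[str], compressed: Sequence[str]) -> bool:
    """Regex oracle for wildcard path queries.

    States are mapped to single private-use characters so a pattern becomes
    an ordinary regex over a string.
    """
    alphabet = sorted(set(compressed) | {t for t in pattern_tokens if t != "*"})
    char = {s: chr(0xE000 + i) for i, s in enumerate(alphabet)}
    hay = "".join(char[s] for s in compressed)
    rx = "".join(".*" if t == "*" else re.escape(char[t]) for t in pattern_tokens)
    return re.search(rx, hay) is not None


# ---------------------------------------------------------------------------
# pytest fixtures


@pytest.fixture(scope="session")
def small_instance_grid():
    """Seeded grid of tiny annotated instances for exhaustive checks.

    Trees up to 10 nodes (binary and multifurcating), alphabets of 2-4
    states, with and without missing leaves.
    """
    cases = []
    specs = [
        (0, 3, 2, 0.0, 0.0),
        (1, 3, 3, 0.0, 0.0),
        (2, 4, 2, 0.0, 0.0),
        (3, 4, 3, 0.5, 0.0),
        (4, 4, 4, 0.0, 0.0),
        (5, 5, 2, 0.0, 0.0),
        (6, 5, 3, 0.5, 0.0),
        (7, 3, 2, 0.0, 0.4),
        (8, 4, 3, 0.0, 0.3),
        (9, 5, 4, 0.5, 0.0),
        (10, 4, 2, 0.5, 0.3),
        (11, 5, 3, 0.0, 0.0),
    ]
    alphabet_full = ("a", "b", "c", "d")
    for seed, n_leaves, k, poly, miss in specs:
        tree = random_tree(seed, n_leaves, polytomy_prob=poly)
        data = random_character(tree, alphabet_full[:k], seed + 100, missing_prob=miss)
        cases.append((tree, data))
    return cases
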