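"""Transition events, maps, matrices, queries, filters, Sz criterion."""

import numpy as np
import pytest

from ancestate import (
    AnnotationError,
    CharacterData,
    F81Model,
    MarginalPosteriors,
    NodeAnnotationSet,
    PathPattern,
    ambiguous_nodes,
    build_map_type1,
    collapse_type2,
    collapse_type3,
    extract_transitions,
    fig3_fixture,
    map_to_newick,
    parse_newick,
    query_paths,
    random_annotated_fixture,
    relative_rate_matrix,
    size_criterion,
    swap,
    transition_count_matrix,
)

from conftest import regex_path_match


@pytest.fixture(scope="module")
def fig3():
    return fig3_fixture()


@pytest.fixture(scope="module")
def fixture_corpus():
    """Random annotated trees reused by the conservation/oracle tests."""
    return [random_annotated_fixture(seed, n_leaves=6 + seed % 20) for seed in range(60)]


class TestExtractTransitions:
    def test_uniform_annotation_yields_no_events(self):
        tree = parse_newick("((A:1,B:1):1,C:1);")
        states = NodeAnnotationSet({n.id: "x" for n in tree.preorder()})
        assert extract_transitions(tree, states) == []

    def test_worked_example_multiset(self, fig3):
        tree, states = fig3
        events = extract_transitions(tree, states)
        multiset = sorted((e.parent_state, e.state) for e in events)
        assert multiset == [
            ("gray", "gold"),
            ("gray", "red"),
            ("gray", "red"),
            ("red", "gold"),
        ]

    def test_distances_are_root_path_lengths(self, fig3):
        tree, states = fig3
        depths = tree.depths()
        for ev in extract_transitions(tree, states):
            assert ev.distance == pytest.approx(depths[ev.node_id])

    def test_unannotated_node_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        states = NodeAnnotationSet({tree.root.id: "x"})
        with pytest.raises(AnnotationError, match="without annotation"):
            extract_transitions(tree, states)

    def test_missing_lengths_warn_and_count_zero(self):
        tree = parse_newick("((A,B),C);")
        states = NodeAnnotationSet({n.id: "x" for n in tree.preorder()})
        states[tree.leaves()[0].id] = "y"
        with pytest.warns(UserWarning, match="branch lengths"):
            events = extract_transitions(tree, states)
        assert events[0].distance == 0.0


class TestTransitionMaps:
    def test_uniform_annotation_gives_single_node_map(self):
        tree = parse_newick("((A:1,B:1):1,C:1);")
        states = NodeAnnotationSet({n.id: "x" for n in tree.preorder()})
        m = build_map_type1(tree, states)
        assert len(m.preorder()) == 1
        assert m.root.state == "x" and m.total_count() == 0

    def test_worked_example_type1_structure(self, fig3):
        tree, states = fig3
        m = build_map_type1(tree, states)
        assert m.root.state == "gray"
        # 5 map nodes: gray root, two red events, one gold under root,
        # one gold under a red
        assert len(m.preorder()) == 5
        root_child_states = sorted(c.state for c in m.root.children)
        assert root_child_states == ["gold", "red", "red"]
        red_with_child = [c for c in m.root.children if c.children]
        assert len(red_with_child) == 1
        assert red_with_child[0].children[0].state == "gold"

    def test_type1_counts_are_all_one(self, fixture_corpus):
        for tree, states, _ in fixture_corpus:
            m = build_map_type1(tree, states)
            assert all(n.count == 1 for n in m.nonroot_nodes())

    def test_worked_example_type2_collapse(self, fig3):
        tree, states = fig3
        m2 = collapse_type2(build_map_type1(tree, states))
        by_state = {}
        for c in m2.root.children:
            by_state[c.state] = c.count
        assert by_state == {"red": 2, "gold": 1}

    def test_collapse_type2_distinct_siblings_unchanged(self):
        tree = parse_newick("((A:1,B:1)n:1,C:1)r;")
        ids = {n.label: n.id for n in tree.preorder()}
        states = NodeAnnotationSet(
            {ids["r"]: "x", ids["n"]: "y", ids["A"]: "y", ids["B"]: "z", ids["C"]: "w"}
        )
        m1 = build_map_type1(tree, states)
        m2 = collapse_type2(m1)
        assert len(m2.preorder()) == len(m1.preorder())
        assert all(n.count == 1 for n in m2.nonroot_nodes())

    def test_type3_merges_same_transition_across_parents(self):
        # two gray->gold events under *different* gray map parents
        tree = parse_newick("(((A:1)g1:1)r1:1,B:1)top;")
        ids = {n.label: n.id for n in tree.preorder() if n.label}
        states = NodeAnnotationSet(
            {
                ids["top"]: "gray",
                ids["r1"]: "red",
                ids["g1"]: "gray",
                ids["A"]: "gold",
                ids["B"]: "gold",
            }
        )
        m2 = collapse_type2(build_map_type1(tree, states))
        golds = [n for n in m2.preorder() if n.state == "gold"]
        assert len(golds) == 2  # still separate in type 2
        m3 = collapse_type3(m2)
        golds3 = [n for n in m3.preorder() if n.state == "gold"]
        assert len(golds3) == 1 and golds3[0].count == 2

    def test_type3_of_minimal_type2_unchanged(self, fig3):
        tree, states = fig3
        m2 = collapse_type2(build_map_type1(tree, states))
        m3 = collapse_type3(m2)
        assert sorted((n.state, n.count) for n in m3.nonroot_nodes()) == sorted(
            (n.state, n.count) for n in m2.nonroot_nodes()
        )

    def test_collapse_rejects_wrong_input_type(self, fig3):
        tree, states = fig3
        m1 = build_map_type1(tree, states)
        m2 = collapse_type2(m1)
        with pytest.raises(ValueError):
            collapse_type2(m2)
        with pytest.raises(ValueError):
            collapse_type3(m1)

    def test_conservation_across_map_types(self, fixture_corpus):
        """|events| = type-1 non-root size = sum of type-2 = sum of type-3
        counts = count-matrix total, on the whole corpus."""
        for tree, states, model in fixture_corpus:
            events = extract_transitions(tree, states)
            m1 = build_map_type1(tree, states)
            m2 = collapse_type2(m1)
            m3 = collapse_type3(m2)
            counts = transition_count_matrix(events, model.states)
            n = len(events)
            assert len(m1.nonroot_nodes()) == n
            assert m2.total_count() == n
            assert m3.total_count() == n
            assert int(counts.to_numpy().sum()) == n

    def test_map_edges_always_change_state(self, fixture_corpus):
        for tree, states, _ in fixture_corpus[:20]:
            m1 = build_map_type1(tree, states)
            for m in (m1, collapse_type2(m1), collapse_type3(collapse_type2(m1))):
                for node in m.preorder():
                    for child in node.children:
                        assert child.state != node.state

    def test_map_matches_contraction_oracle(self, fixture_corpus):
        """Type-1 map is isomorphic to the annotated tree contracted along
        state-constant edges (independent recursive implementation)."""

        def contract(node, states):
            # returns the labeled shape of the contracted subtree rooted here
            kids = []
            for c in node.children:
                sub = contract(c, states)
                if states[c.id] == states[node.id]:
                    kids.extend(sub[1])  # splice grandchildren up
                else:
                    kids.append(sub)
            return (states[node.id], sorted(kids))

        def shape(mnode):
            return (mnode.state, sorted(shape(c) for c in mnode.children))

        for tree, states, _ in fixture_corpus[:25]:
            oracle = contract(tree.root, states)
            got = shape(build_map_type1(tree, states).root)
            assert got == oracle

    def test_invariant_under_child_order_swap(self, fixture_corpus):
        """Swapping child order changes node ids but not the multiset of
        transitions (annotations carried across via each node's leaf set)."""

        def leafset(node):
            stack, out = [node], set()
            while stack:
                n = stack.pop()
                if n.is_leaf:
                    out.add(n.label)
                stack.extend(n.children)
            return frozenset(out)

        for tree, states, _ in fixture_corpus[:10]:
            swapped = swap(tree, tree.root.id)
            by_leafset = {leafset(n): states[n.id] for n in tree.preorder()}
            after_states = NodeAnnotationSet(
                {n.id: by_leafset[leafset(n)] for n in swapped.preorder()}
            )
            before = sorted(
                (e.parent_state, e.state) for e in extract_transitions(tree, states)
            )
            after = sorted(
                (e.parent_state, e.state)
                for e in extract_transitions(swapped, after_states)
            )
            assert after == before


class TestMapNewick:
    def test_single_node_map(self):
        tree = parse_newick("(A:1,B:1);")
        states = NodeAnnotationSet({n.id: "gray" for n in tree.preorder()})
        m = build_map_type1(tree, states)
        assert map_to_newick(m) == "gray|1;"

    def test_worked_example_type2_label(self, fig3):
        tree, states = fig3
        m2 = collapse_type2(build_map_type1(tree, states))
        assert "red|2" in map_to_newick(m2)

    def test_round_trip_preserves_topology(self, fig3):
        tree, states = fig3
        for build in (
            lambda: build_map_type1(tree, states),
            lambda: collapse_type2(build_map_type1(tree, states)),
        ):
            m = build()
            parsed = parse_newick(map_to_newick(m), allow_duplicate_leaves=True)
            assert len(parsed) == len(m.preorder())
            got = sorted(l.label for l in parsed.leaves())
            want = sorted(
                f"{n.state}|{n.count}" for n in m.preorder() if not n.children
            )
            assert got == want


class TestMatrices:
    def test_no_events_zero_matrix(self):
        mat = transition_count_matrix([], ("a", "b"))
        assert mat.to_numpy().sum() == 0

    def test_worked_example_counts(self, fig3):
        tree, states = fig3
        events = extract_transitions(tree, states)
        mat = transition_count_matrix(events, ("gold", "gray", "red"))
        assert mat.loc["gray", "red"] == 2
        assert mat.loc["gray", "gold"] == 1
        assert mat.loc["red", "gold"] == 1
        assert int(mat.to_numpy().sum()) == 4
        assert all(mat.loc[s, s] == 0 for s in mat.index)

    def test_relative_rates_hand_computed(self):
        import pandas as pd

        counts = pd.DataFrame(
            [[0, 2], [1, 0]], index=["A", "B"], columns=["A", "B"]
        )
        rates = relative_rate_matrix(counts, {"A": 0.75, "B": 0.25})
        # rate(A->B) = (2/3)/0.25 = 8/3 ; rate(B->A) = (1/3)/0.75 = 4/9
        assert rates.loc["A", "B"] == pytest.approx(8 / 3)
        assert rates.loc["B", "A"] == pytest.approx(4 / 9)

    def test_uniform_priors_keep_proportionality(self, fig3):
        tree, states = fig3
        events = extract_transitions(tree, states)
        counts = transition_count_matrix(events, ("gold", "gray", "red"))
        rates = relative_rate_matrix(counts, {s: 1 / 3 for s in counts.index})
        ratio = rates.to_numpy()[counts.to_numpy() > 0] / counts.to_numpy()[counts.to_numpy() > 0]
        assert np.allclose(ratio, ratio[0])

    def test_doubling_counts_preserves_rate_ratios(self):
        import pandas as pd

        counts = pd.DataFrame([[0, 4], [2, 0]], index=["A", "B"], columns=["A", "B"])
        pri = {"A": 0.6, "B": 0.4}
        r1 = relative_rate_matrix(counts, pri)
        r2 = relative_rate_matrix(counts * 2, pri)
        assert r2.loc["A", "B"] / r2.loc["B", "A"] == pytest.approx(
            r1.loc["A", "B"] / r1.loc["B", "A"]
        )

    def test_zero_prior_rejected(self):
        import pandas as pd

        counts = pd.DataFrame([[0, 1], [0, 0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError, match="prior"):
            relative_rate_matrix(counts, {"A": 0.0, "B": 1.0})


class TestQueries:
    def test_single_state_pattern_matches_everywhere(self):
        tree = parse_newick("((A:1,B:1):1,C:1);")
        states = NodeAnnotationSet({n.id: "A" for n in tree.preorder()})
        paths, edges = query_paths(tree, states, "A")
        assert len(paths) == tree.n_leaves
        assert len(edges) == len(tree) - 1

    def test_wildcard_semantics(self):
        # compressed path (A, C, B) matches "A * B"; (B, A) does not
        tree = parse_newick("((x:1)m:1)r;")
        ids = {n.label: n.id for n in tree.preorder() if n.label}
        states = NodeAnnotationSet({ids["r"]: "A", ids["m"]: "C", ids["x"]: "B"})
        paths, _ = query_paths(tree, states, "A * B")
        assert len(paths) == 1
        states2 = NodeAnnotationSet({ids["r"]: "B", ids["m"]: "B", ids["x"]: "A"})
        paths2, _ = query_paths(tree, states2, "A * B")
        assert paths2 == []

    def test_unknown_pattern_state_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        states = NodeAnnotationSet({n.id: "x" for n in tree.preorder()})
        with pytest.raises(ValueError, match="alphabet"):
            query_paths(tree, states, "zz")

    def test_consecutive_wildcards_normalized(self):
        p = PathPattern.parse("A * * B")
        assert p.tokens == ("A", "*", "B")

    @pytest.mark.parametrize(
        "pattern",
        ["blue * gold", "* gray", "gold", "blue gold", "gray * blue", "* blue *"],
    )
    def test_matches_regex_oracle_on_corpus(self, pattern, fixture_corpus):
        tokens = PathPattern.parse(pattern).tokens
        for tree, states, model in fixture_corpus[:40]:
            paths, _ = query_paths(tree, states, pattern, alphabet=model.states)
            matched_leaves = {p[-1] for p in paths}
            for leaf in tree.leaves():
                chain = []
                n = leaf
                while n is not None:
                    chain.append(states[n.id])
                    n = n.parent
                chain.reverse()
                compressed = [s for i, s in enumerate(chain) if i == 0 or s != chain[i - 1]]
                expected = regex_path_match(tokens, compressed)
                assert (leaf.id in matched_leaves) == expected


class TestAmbiguityFilter:
    def _post(self, probs):
        return MarginalPosteriors(
            states=tuple(f"s{i}" for i in range(len(probs[0]))),
            probs={i: np.array(p) for i, p in enumerate(probs)},
            log_likelihood=0.0,
        )

    def test_point_mass_never_ambiguous(self):
        post = self._post([[1.0, 0.0, 0.0]])
        assert ambiguous_nodes(post, 0.99) == {}

    def test_forced_arithmetic_example(self):
        # (0.5, 0.45, 0.05) with f=0.4: cutoff 0.30 keeps the top two
        post = self._post([[0.5, 0.45, 0.05]])
        out = ambiguous_nodes(post, 0.4)
        assert out == {0: ["s0", "s1"]}

    def test_zero_fraction_only_exact_ties(self):
        post = self._post([[0.5, 0.5, 0.0], [0.6, 0.4, 0.0]])
        out = ambiguous_nodes(post, 0.0)
        assert 0 in out and 1 not in out

    def test_fraction_out_of_range_rejected(self):
        post = self._post([[1.0, 0.0]])
        with pytest.raises(ValueError):
            ambiguous_nodes(post, 1.5)


class TestSizeCriterion:
    def test_uniform_tree_root_counts_all_leaves(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        states = NodeAnnotationSet({n.id: "x" for n in tree.preorder()})
        sz = size_criterion(tree, states)
        assert sz[tree.root.id] == 4
        assert all(sz[l.id] == 1 for l in tree.leaves())

    def test_worked_example_red_cherry(self, fig3):
        tree, states = fig3
        t1 = next(n for n in tree.preorder() if n.label == "t1")
        sz = size_criterion(tree, states)
        assert sz[t1.id] == 1  # one red leaf, one gold leaf below

    def test_recursion_property(self, fixture_corpus):
        """When a parent and child share a state, the child's same-state
        leaves all count toward the parent's Sz."""
        for tree, states, _ in fixture_corpus[:20]:
            sz = size_criterion(tree, states)
            for node in tree.preorder():
                if node.is_leaf:
                    continue
                same_children = [
                    c for c in node.children if states[c.id] == states[node.id]
                ]
                assert sz[node.id] >= sum(sz[c.id] for c in same_children)
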