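"""cSupB discovery, verification, tree building and simple decomposition."""

import itertools

import pytest

from conftest import build_random_graph
from csupb.decompose import (
    all_simple_csupbs,
    build_csupb_tree,
    csupb_node_set,
    decompose_simple,
    find_csupbs,
    is_simple,
    relate_csupbs,
    verify_csupb,
)
from csupb.graph import ColorSet, Genome, build_graph, generate_anchors


def brute_force_superbubbles(graph, color):
    """Independent enumeration of all ⟨s,t⟩ passing the Definition-1 criteria
    (with supernode endpoints) in the color-induced subgraph."""
    hits = []
    for s, t in itertools.permutations(graph.nodes, 2):
        if graph.outdegree(s) < 2 or graph.indegree(t) < 2:
            continue
        if verify_csupb(graph, s, t, color):
            hits.append((s, t))
    return hits


class TestVerify:
    def test_toy_full_color_bubble(self, toy_graph):
        assert verify_csupb(toy_graph, "TAT", "ACC", ColorSet.from_string("111"))

    def test_color_restricted_bubble(self, toy_graph):
        assert verify_csupb(toy_graph, "CAC", "GTA", ColorSet.from_string("011"))

    def test_minimality_rejects_enclosing_pair(self, toy_graph):
        # ⟨TCA, GTA⟩ at color 110 contains the interior sink GGG that matches
        # TCA, so the pair fails minimality at that color
        assert not verify_csupb(toy_graph, "TCA", "GTA", ColorSet.from_string("110"))

    def test_non_bubble_pairs_rejected(self, toy_graph):
        assert not verify_csupb(toy_graph, "GGG", "ACC", ColorSet.from_string("111"))
        assert not verify_csupb(toy_graph, "TAT", "GTA", ColorSet.from_string("111"))

    def test_empty_color_rejected(self, toy_graph):
        with pytest.raises(ValueError):
            verify_csupb(toy_graph, "TAT", "ACC", 0)

    def test_monochrome_reduction_to_plain_superbubbles(self):
        # on a two-sample graph the full-color cSupBs are exactly the plain
        # superbubbles found by exhaustive enumeration
        g, _, _ = build_random_graph(3, length=250, n_samples=2, snp=3)
        full = ColorSet.from_string("11")
        emitted = {
            (b.source, b.sink) for b in find_csupbs(g) if str(b.colorset) == "11"
        }
        assert emitted == set(brute_force_superbubbles(g, full))


class TestFind:
    def test_toy_discovery_order_and_colors(self, toy_csupbs):
        got = [(b.source, b.sink, str(b.colorset)) for b in toy_csupbs]
        assert got == [
            ("TAT", "ACC", "111"),
            ("GGG", "GTA", "110"),
            ("CAC", "GTA", "011"),
            ("TCA", "GGG", "110"),
            ("TCA", "GTA", "111"),
        ]
        assert [b.order for b in toy_csupbs] == [1, 2, 3, 4, 5]

    def test_identical_sequences_have_no_bubbles(self):
        gen = [Genome("a", "ACGTGCATT"), Genome("b", "ACGTGCATT")]
        g = build_graph(gen, 3, generate_anchors(3, gen, seed=0))
        assert find_csupbs(g) == []

    def test_every_join_node_closes_a_bubble(self, toy_graph, toy_csupbs):
        joins = {n for n in toy_graph.nodes if toy_graph.indegree(n) > 1}
        assert joins == {b.sink for b in toy_csupbs}

    @pytest.mark.parametrize("seed", range(10))
    def test_emitted_bubbles_pass_brute_force_checker(self, seed):
        g, _, _ = build_random_graph(
            seed, length=400, n_samples=4, snp=4, dele=1, ins=1
        )
        for b in find_csupbs(g):
            assert verify_csupb(g, b.source, b.sink, b.color), repr(b)


class TestTree:
    def test_toy_parentage_matches_worked_example(self, toy_tree):
        assert toy_tree[5].children == [2, 3, 4]
        assert all(toy_tree[o].parent == 5 for o in (2, 3, 4))
        assert toy_tree[1].parent is None
        assert sorted(toy_tree.roots) == [1, 5]

    def test_levels_root_one_child_two(self, toy_tree):
        assert toy_tree[1].level == 1 and toy_tree[5].level == 1
        assert all(toy_tree[o].level == 2 for o in (2, 3, 4))
        assert toy_tree.max_level() == 2

    def test_single_bubble_is_root_level_one(self, toy_csupbs):
        tree = build_csupb_tree(toy_csupbs[:1])
        assert tree.roots == [1] and tree[1].level == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_forest_and_ordering_invariants(self, seed):
        g, _, _ = build_random_graph(seed + 20, length=400, n_samples=4, snp=5, dele=1)
        tree = build_csupb_tree(find_csupbs(g))
        for b in tree:
            if b.parent is not None:
                assert b.order < b.parent           # child found before parent
                assert b.nodes <= tree[b.parent].nodes
                assert b.colorset.issubset(tree[b.parent].colorset)
        for r in tree.roots:
            b = tree[r]
            assert b.level == 1
            # roots either carry every sample or have no containing bubble
            if str(b.colorset) != "1" * g.n_samples:
                others = [o for o in tree.bubbles if o > r]
                assert not any(b.nodes <= tree[o].nodes and
                               b.colorset.issubset(tree[o].colorset)
                               for o in others)

    def test_nested_parenthood_matches_node_set_containment(self):
        # a 2-sample insertion carrying an internal SNP between the alternates
        ref = "ACGTTGCAGGTACCTAGCATCCGGATCTAACGGT"
        ins1 = ref[:16] + "TTCAGTGA" + ref[16:]
        ins2 = ref[:16] + "TTCCGTGA" + ref[16:]
        gen = [Genome("r", ref), Genome("x", ins1), Genome("y", ins2)]
        g = build_graph(gen, 5, generate_anchors(5, gen, seed=4))
        tree = build_csupb_tree(find_csupbs(g))
        for b in tree:
            if b.parent is not None:
                assert b.nodes < tree[b.parent].nodes


class TestRelations:
    def test_toy_inclusion(self, toy_csupbs, toy_graph):
        by_order = {b.order: b for b in toy_csupbs}
        assert relate_csupbs(by_order[2], by_order[5], toy_graph) == "inclusion"

    def test_toy_separation(self, toy_csupbs, toy_graph):
        by_order = {b.order: b for b in toy_csupbs}
        assert relate_csupbs(by_order[1], by_order[4], toy_graph) == "separation"

    def test_shared_sink_intersection(self, toy_csupbs, toy_graph):
        # bub2 ⟨GGG,GTA,110⟩ and bub3 ⟨CAC,GTA,011⟩ share the sink GTA with
        # incomparable colors
        by_order = {b.order: b for b in toy_csupbs}
        assert relate_csupbs(by_order[2], by_order[3], toy_graph) == "intersection"


class TestSimple:
    def test_already_simple_bubble_returns_itself(self, toy_graph, toy_csupbs):
        bub1 = toy_csupbs[0]
        assert is_simple(toy_graph, bub1)
        simple = decompose_simple(toy_graph, bub1)
        assert len(simple) == 1
        s = simple[0]
        assert (s.source, s.sink, str(s.colorset)) == ("TAT", "ACC", "111")

    def test_multiallelic_site_decomposes_pairwise(self):
        # three samples with three different bases at one site: the pairwise
        # two-path bubbles are exactly the 3 enumerated by brute force
        ref = "ACGTTGCAGGTACCTAGCAT"
        a, b, c = ref, ref[:10] + "A" + ref[11:], ref[:10] + "C" + ref[11:]
        gen = [Genome("r", a), Genome("x", b), Genome("y", c)]
        g = build_graph(gen, 5, generate_anchors(5, gen, seed=6))
        tree = build_csupb_tree(find_csupbs(g))
        root = tree[tree.roots[0]]
        simple = decompose_simple(g, root)
        assert len(simple) == 3
        for s in simple:
            assert is_simple(g, s)
            assert s.colorset.count() == 2

    def test_toy_root_decomposition_is_verified_simple(self, toy_graph, toy_tree):
        simple = all_simple_csupbs(toy_graph, toy_tree)
        assert simple
        for s in simple:
            assert is_simple(toy_graph, s)

    def test_node_set_helper_matches_stored_sets(self, toy_graph, toy_csupbs):
        for b in toy_csupbs:
            assert b.nodes == csupb_node_set(toy_graph, b.source, b.sink, b.color)
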