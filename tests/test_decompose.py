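"""Backbone decomposition, path weights, extra subtrees and the
potential function w*."""

import pytest

from conftest import medium_pair, small_pair
from rfs2.decompose import (
    build_context,
    bp_side,
    compute_backbone,
    p_scores,
    split_pi,
    tr_star,
    trs_side,
    w_star,
    w_star_set,
)
from rfs2.fixtures import random_binary_tree
from rfs2.merge import build_initial_tree
from rfs2.oracle import enumerate_binary_trees
from rfs2.treecore import (
    Bipartition,
    PhyloError,
    are_compatible,
    bipartitions,
    parse_newick,
    restrict,
    sf_support,
)


class TestComputeBackbone:
    def test_full_leaf_set_has_no_extras(self):
        t = parse_newick("((a,b),((c,d),(e,f)));")
        d = compute_backbone(t, t.leaves)
        assert d.extras == []
        assert all(w == 1 for w in d.weight.values())

    def test_planted_extras(self):
        d = compute_backbone(parse_newick("(a,(p,(b,(q,c))));"), {"a", "b", "c"})
        assert d.backbone.leaves == {"a", "b", "c"}
        assert sorted(sorted(e.labels) for e in d.extras) == [["p"], ["q"]]
        # each extra sits on a pendant path, stretching its weight
        assert sorted(d.weight.values()) == [1, 2, 2]

    def test_small_x_rejected(self):
        t = parse_newick("((a,b),(c,d));")
        with pytest.raises(PhyloError):
            compute_backbone(t, {"a", "b"})

    @pytest.mark.parametrize("seed", range(8))
    def test_edge_conservation(self, seed):
        """Sum of w(e) equals the number of source edges whose splits meet
        x on both sides (the edges of the minimal x-spanning subtree)."""
        import random

        rng = random.Random(seed)
        t = random_binary_tree([f"x{i}" for i in range(10)], seed)
        x = frozenset(rng.sample(sorted(t.leaves), rng.randint(3, 8)))
        d = compute_backbone(t, x)
        steiner_edges = sum(
            1 for p in bipartitions(t) if (p.side_a & x) and (p.side_b & x)
        )
        assert sum(d.weight.values()) == steiner_edges

    @pytest.mark.parametrize("seed", range(8))
    def test_path_edges_induce_the_backbone_split(self, seed):
        """Every source edge on P(e) restricts to the split of e."""
        import random

        rng = random.Random(seed + 50)
        t = random_binary_tree([f"x{i}" for i in range(10)], seed)
        x = frozenset(rng.sample(sorted(t.leaves), rng.randint(3, 8)))
        d = compute_backbone(t, x)
        from rfs2.treecore import edge_bipartitions

        eb = edge_bipartitions(t)
        for ek, path in d.path_map.items():
            for u, v in zip(path, path[1:]):
                assert eb[frozenset((u, v))].restrict(x) == d.bip_of[ek]

    @pytest.mark.parametrize("seed", range(6))
    def test_extras_partition_non_shared_leaves(self, seed):
        t1, t2 = medium_pair(seed)
        ctx = build_context(t1, t2)
        for i in (1, 2):
            d = ctx.decomp(i)
            labels = [l for ex in d.extras for l in ex.labels]
            assert len(labels) == len(set(labels))
            assert set(labels) == set(d.source.leaves - ctx.x)


class TestTrStar:
    def test_absent_split_is_empty(self):
        from itertools import combinations

        t1, t2 = medium_pair(0)
        ctx = build_context(t1, t2)
        xs = sorted(ctx.x)
        absent = [
            p
            for pair in combinations(xs, 2)
            for p in [Bipartition.of(pair, set(xs) - set(pair))]
            if p not in ctx.all_splits
        ]
        assert absent, "fixture unexpectedly realises every 2-vs-rest split"
        for p in absent:
            assert tr_star(ctx, p) == frozenset()
            assert w_star(ctx, p) == 0

    def test_weight_one_edges_have_no_extras(self):
        t = parse_newick("((a,b),((c,d),(e,f)));")
        ctx = build_context(t, t.copy())
        for p in ctx.all_splits:
            assert tr_star(ctx, p) == frozenset()

    def test_union_over_both_sources(self):
        # plant two extras on one source's central path and one on the other's
        t1 = parse_newick("((a,b),(p1,(p2,(c,d))));")
        t2 = parse_newick("((a,b),(q1,(c,d)));")
        ctx = build_context(t1, t2)
        pi = Bipartition.of("ab", "cd")
        assert sorted(sorted(ex.labels) for ex in tr_star(ctx, pi)) == [
            ["p1"],
            ["p2"],
            ["q1"],
        ]
        assert w_star(ctx, pi) == 3 + 2


class TestBpTrs:
    def test_singleton_q_empty(self):
        t1, t2 = medium_pair(1)
        ctx = build_context(t1, t2)
        q = {min(ctx.x)}
        assert bp_side(ctx, q) == frozenset()
        assert trs_side(ctx, q) == frozenset()

    def test_q_equals_x_selects_everything(self):
        t1, t2 = medium_pair(1)
        ctx = build_context(t1, t2)
        assert bp_side(ctx, ctx.x) == ctx.all_splits

    @pytest.mark.parametrize("seed", range(6))
    def test_bp_sides_are_the_compatible_splits(self, seed):
        """BP_i(A) ∪ BP_i(B) = the splits of C(T_i|_X) compatible with [A|B]."""
        t1, t2 = medium_pair(seed)
        ctx = build_context(t1, t2)
        for i in (1, 2):
            for p in ctx.decomp(i).splits:
                got = bp_side(ctx, p.side_a, i) | bp_side(ctx, p.side_b, i)
                expected = frozenset(
                    q
                    for q in ctx.decomp(i).splits
                    if q != p and are_compatible(p, q)
                )
                assert got == expected

    @pytest.mark.parametrize("seed", range(6))
    def test_trs_partition_of_extras(self, seed):
        """TRS_i(A), TRS_i(B) and TR(e_i) partition Extra(T_i) when e_i exists."""
        t1, t2 = medium_pair(seed)
        ctx = build_context(t1, t2)
        for i in (1, 2):
            d = ctx.decomp(i)
            for p in d.splits:
                a = trs_side(ctx, p.side_a, i)
                b = trs_side(ctx, p.side_b, i)
                on_path = frozenset(d.tr[d.edge_of[p]])
                assert not (a & b)
                assert not (a & on_path) and not (b & on_path)
                assert a | b | on_path == frozenset(d.extras)


class TestSplitPi:
    def test_full_overlap_empties_pi2(self):
        t = parse_newick("((a,b),((c,d),(e,f)));")
        ctx = build_context(t, t.copy())
        _, pi2 = split_pi(ctx)
        assert pi2 == frozenset()

    def test_extra_subtree_splits_fall_in_pi2(self):
        t1 = parse_newick("((a,(p1,p2)),((b,c),d));")
        t2 = parse_newick("((a,q),((b,c),d));")
        ctx = build_context(t1, t2)
        _, pi2 = split_pi(ctx)
        assert Bipartition.of(["p1", "p2"], ["a", "b", "c", "d"]) in pi2

    @pytest.mark.parametrize("seed", range(6))
    def test_partition_sizes(self, seed):
        t1, t2 = medium_pair(seed)  # leaf sets differ, so C(T1), C(T2) disjoint
        ctx = build_context(t1, t2)
        pi1, pi2 = split_pi(ctx)
        assert not (pi1 & pi2)
        assert len(pi1) + len(pi2) == len(bipartitions(t1)) + len(bipartitions(t2))


class TestWStarAndPScores:
    def test_w_star_cases(self):
        t1 = parse_newick("((a,b),(p1,(p2,(c,d))));")  # w(e) = 3 for [ab|cd]
        t2 = parse_newick("((a,c),(b,d));")  # [ac|bd], w = 1
        ctx = build_context(t1, t2)
        assert w_star(ctx, Bipartition.of("ab", "cd")) == 3  # in T1 only
        assert w_star(ctx, Bipartition.of("ac", "bd")) == 1  # in T2 only
        assert w_star(ctx, Bipartition.of("ad", "bc")) == 0  # in neither
        triv = Bipartition.of("a", "bcd")
        assert w_star(ctx, triv) == 2  # shared, both weight 1

    @pytest.mark.parametrize("seed", range(8))
    def test_p1_plus_p2_is_split_support(self, seed):
        t1, t2 = small_pair(seed)
        ctx = build_context(t1, t2)
        s = t1.leaves | t2.leaves
        supertree = random_binary_tree(s, seed + 77)
        p1, p2 = p_scores(ctx, supertree)
        assert p1 + p2 == sf_support(supertree, t1) + sf_support(supertree, t2)

    def test_p_scores_leaf_mismatch(self):
        t1, t2 = small_pair(2)  # this seed carries non-shared leaves
        ctx = build_context(t1, t2)
        with pytest.raises(PhyloError):
            p_scores(ctx, t1)

    @pytest.mark.parametrize("seed", range(4))
    def test_p2_of_initial_tree_is_maximal(self, seed):
        t1, t2 = medium_pair(seed)
        ctx = build_context(t1, t2)
        _, p2 = p_scores(ctx, build_initial_tree(ctx))
        assert p2 == len(ctx.pi2[1]) + len(ctx.pi2[2])

    def test_p1_bounded_by_w_star_exhaustively(self):
        """Over every binary supertree on a 6-leaf union, p1(T) <= w*(C(T|_X))."""
        t1 = parse_newick("((a,(p,b)),(c,d));")
        t2 = parse_newick("((a,c),(b,(q,d)));")
        ctx = build_context(t1, t2)
        s = t1.leaves | t2.leaves
        for cand in enumerate_binary_trees(s):
            p1, _ = p_scores(ctx, cand)
            f = bipartitions(restrict(cand, ctx.x))
            assert p1 <= w_star_set(ctx, f)
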