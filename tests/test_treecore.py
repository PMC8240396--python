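"""Tree representation, Newick I/O, restriction, bipartitions and scores."""

import pytest
from hypothesis import given, settings, strategies as st

from rfs2.fixtures import random_binary_tree, star_tree
from rfs2.oracle import enumerate_binary_trees
from rfs2.treecore import (
    Bipartition,
    DuplicateLabelError,
    NewickParseError,
    PhyloError,
    Profile,
    are_compatible,
    bipartitions,
    parse_newick,
    profile_scores,
    restrict,
    rf_distance,
    sf_support,
    write_newick,
)


class TestNewick:
    @pytest.mark.parametrize(
        "text,n_leaves,n_internal_edges",
        [
            ("(A,((B,x),((C,y),(D,E))));", 7, 4),
            ("(a,b,c);", 3, 0),
            ("((a,b),(c,d));", 4, 1),
        ],
    )
    def test_parse_shapes(self, text, n_leaves, n_internal_edges):
        t = parse_newick(text)
        assert len(t.leaves) == n_leaves
        assert len(bipartitions(t, nontrivial_only=True)) == n_internal_edges
        # a rooted string yields an unrooted tree: no degree-2 vertices
        t.validate()

    def test_quartet_split(self):
        t = parse_newick("((a,b),(c,d));")
        assert bipartitions(t, nontrivial_only=True) == {
            Bipartition.of("ab", "cd")
        }

    def test_duplicate_labels_rejected(self):
        with pytest.raises(DuplicateLabelError):
            parse_newick("(A,(B,A));")

    def test_malformed_reports_position(self):
        with pytest.raises(NewickParseError, match="column"):
            parse_newick("(A,(B,C);")

    def test_canonical_star_output(self):
        assert write_newick(parse_newick("(c,(a,b));")) == "(a,b,c);"

    @pytest.mark.parametrize("seed", range(8))
    def test_roundtrip_random_trees(self, seed):
        t = random_binary_tree([f"x{i}" for i in range(seed + 4)], seed)
        s = write_newick(t)
        back = parse_newick(s)
        assert back.topologically_equal(t)
        assert write_newick(back) == s  # canonical form is a fixed point


class TestBipartitions:
    def test_binary_four_leaf_counts(self):
        t = parse_newick("((a,b),(c,d));")
        assert len(bipartitions(t)) == 5
        assert len(bipartitions(t, nontrivial_only=True)) == 1

    def test_star_has_only_trivial(self):
        t = star_tree([f"s{i}" for i in range(6)])
        assert len(bipartitions(t)) == 6
        assert bipartitions(t, nontrivial_only=True) == frozenset()

    def test_canonical_form_idempotent(self):
        p = Bipartition.of("cd", "ab")
        assert p.side_a == frozenset("ab")
        assert Bipartition.of(p.side_a, p.side_b) == p

    def test_invalid_bipartitions(self):
        with pytest.raises(PhyloError):
            Bipartition.of("ab", "")
        with pytest.raises(PhyloError):
            Bipartition.of("ab", "bc")


class TestRestrict:
    def test_identity(self):
        t = parse_newick("((a,b),((c,d),(e,f)));")
        assert restrict(t, t.leaves).topologically_equal(t)

    def test_three_labels_star(self):
        t = parse_newick("((a,b),((c,d),(e,f)));")
        r = restrict(t, {"a", "c", "e"})
        assert r.leaves == {"a", "c", "e"}
        assert bipartitions(r, nontrivial_only=True) == frozenset()

    def test_derived_example(self):
        t = parse_newick("((a,b),((c,d),(e,f)));")
        r = restrict(t, {"a", "c", "e", "f"})
        assert bipartitions(r, nontrivial_only=True) == {
            Bipartition.of("ef", "ac")
        }

    def test_errors(self):
        t = parse_newick("(a,b,c);")
        with pytest.raises(PhyloError):
            restrict(t, {"a", "z"})
        with pytest.raises(PhyloError):
            restrict(t, set())

    @pytest.mark.parametrize("seed", range(6))
    def test_commutes_with_itself(self, seed):
        import random

        rng = random.Random(seed)
        t = random_binary_tree([f"x{i}" for i in range(8)], seed)
        r1 = set(rng.sample(sorted(t.leaves), 6))
        r2 = set(rng.sample(sorted(r1), 4))
        assert restrict(restrict(t, r1), r2).topologically_equal(restrict(t, r2))

    @pytest.mark.parametrize("seed", range(6))
    def test_split_set_characterisation(self, seed):
        """Restriction agrees with the independent split-restriction oracle:
        C(t|_r) = {pi|_r : pi in C(t), both sides meet r}."""
        import random

        rng = random.Random(seed + 100)
        t = random_binary_tree([f"x{i}" for i in range(9)], seed)
        r = set(rng.sample(sorted(t.leaves), rng.randint(3, 7)))
        expected = {
            p.restrict(r) for p in bipartitions(t) if p.restrict(r) is not None
        }
        assert bipartitions(restrict(t, r)) == expected


class TestPairScores:
    def test_rf_examples(self):
        t = parse_newick("((a,b),(c,d));")
        assert rf_distance(t, t) == 0
        assert rf_distance(t, parse_newick("((a,c),(b,d));")) == 2

    def test_sf_examples(self):
        t = parse_newick("((a,b),(c,d));")
        assert sf_support(t, t) == 5
        assert sf_support(t, parse_newick("((a,c),(b,d));")) == 4

    def test_lemma4_supertree_distance(self, lemma4):
        t1, t2, ts = lemma4
        assert rf_distance(ts, t1) + rf_distance(ts, t2) == 2

    def test_no_shared_leaves_is_an_error(self):
        with pytest.raises(PhyloError):
            rf_distance(parse_newick("(a,b,c);"), parse_newick("(d,e,f);"))

    def test_small_overlap_convention(self):
        # |X| < 3: both restrictions carry no conflicting structure
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,e),(f,g));")
        assert rf_distance(t1, t2) == 0

    def test_metric_on_five_leaf_trees(self):
        trees = list(enumerate_binary_trees("abcde"))
        d = [[rf_distance(a, b) for b in trees] for a in trees]
        n = len(trees)
        for i in range(n):
            assert d[i][i] == 0
            for j in range(n):
                assert d[i][j] == d[j][i]
                if i != j:
                    assert d[i][j] > 0  # identity of indiscernibles
        # triangle inequality, spot-checked exhaustively at this size
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i][k] <= d[i][j] + d[j][k]


class TestCompatibility:
    def test_examples(self):
        u = "abcde"
        p = Bipartition.of("ab", "cde")
        assert are_compatible(p, p)
        assert are_compatible(p, Bipartition.of("abc", "de"))
        q1 = Bipartition.of("ab", "cd")
        q2 = Bipartition.of("ac", "bd")
        assert not are_compatible(q1, q2)
        with pytest.raises(PhyloError):
            are_compatible(p, q1)

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_two_splits_of_one_tree_always_compatible(self, seed):
        t = random_binary_tree([f"x{i}" for i in range(7)], seed)
        bips = sorted(bipartitions(t), key=Bipartition.sort_key)
        for i, p in enumerate(bips):
            for q in bips[i:]:
                assert are_compatible(p, q)


class TestProfileScores:
    def test_self_profile_is_zero(self):
        t = parse_newick("((a,b),((c,d),(e,f)));")
        rep = profile_scores(t, Profile((t, t.copy())))
        assert rep.rf_total == 0
        assert rep.fn_total == 0

    def test_lemma4_total(self, lemma4):
        t1, t2, ts = lemma4
        assert profile_scores(ts, Profile((t1, t2))).rf_total == 2

    def test_missing_leaf_named(self, lemma4):
        t1, t2, _ = lemma4
        with pytest.raises(PhyloError, match="'z'"):
            profile_scores(t1, Profile((t2,)))

    @pytest.mark.parametrize("seed", range(10))
    def test_score_identities(self, seed):
        """For a binary supertree, rf_i + 2*sf_i = 2|S_i| - 3 + |C(T_i)|;
        for any supertree, sf_total + fn_total = sum_i |C(T_i)|."""
        from conftest import small_pair

        t1, t2 = small_pair(seed)
        supertree = random_binary_tree(t1.leaves | t2.leaves, seed + 999)
        rep = profile_scores(supertree, Profile((t1, t2)))
        for (rf, sf, _), ti in zip(rep.per_tree, (t1, t2)):
            assert rf + 2 * sf == 2 * len(ti.leaves) - 3 + len(bipartitions(ti))
        assert rep.sf_total + rep.fn_total == len(bipartitions(t1)) + len(
            bipartitions(t2)
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_fn_identity_for_multifurcating_supertree(self, seed):
        from conftest import small_pair
        from rfs2.merge import exact_rfs_2

        t1, t2 = small_pair(seed)
        t_star, _ = exact_rfs_2(t1, t2, relax=True)  # generally multifurcating
        rep = profile_scores(t_star, Profile((t1, t2)))
        assert rep.sf_total + rep.fn_total == len(bipartitions(t1)) + len(
            bipartitions(t2)
        )
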