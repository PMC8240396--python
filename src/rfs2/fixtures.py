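"""Seeded synthetic tree generation and the small in-literature fixtures.

All generators are deterministic per seed.  The overlapping-pair
generator emulates the supertree setting this package targets: two
binary source trees derived from a common model tree, sharing a
controlled leaf set X, with controlled topological disagreement
introduced by subtree-prune-regraft (SPR) moves that are required to
alter the shared backbone (disagreement confined to non-shared leaves
would not affect the supertree optimum).
"""

from __future__ import annotations

import random
from typing import Iterable, Sequence

from .treecore import (
    PhyloError,
    PhyloTree,
    Profile,
    bipartitions,
    parse_newick,
    restrict,
)

__all__ = [
    "random_binary_tree",
    "random_spr",
    "overlapping_pair",
    "star_tree",
    "caterpillar_tree",
    "lemma2_labels",
    "lemma2_profile",
    "lemma4_trees",
]


def star_tree(labels: Iterable[str]) -> PhyloTree:
    """The tree with a single internal hub adjacent to every leaf."""
    lab = sorted(set(labels))
    if len(lab) < 3:
        raise PhyloError("a star needs at least 3 leaves")
    t = PhyloTree()
    c = t.new_node()
    for l in lab:
        t.add_edge(c, t.new_node(l))
    return t


def caterpillar_tree(labels: Sequence[str]) -> PhyloTree:
    """The caterpillar on ``labels`` in the given order: an internal path
    with the first two labels cherried at one end and the last two at the
    other."""
    lab = list(labels)
    if len(lab) < 4:
        raise PhyloError("a caterpillar needs at least 4 leaves")
    t = PhyloTree()
    spine = [t.new_node() for _ in range(len(lab) - 2)]
    for a, b in zip(spine, spine[1:]):
        t.add_edge(a, b)
    t.add_edge(spine[0], t.new_node(lab[0]))
    for i, l in enumerate(lab[1:-1]):
        t.add_edge(spine[i], t.new_node(l))
    t.add_edge(spine[-1], t.new_node(lab[-1]))
    return t


def random_binary_tree(labels: Iterable[str], seed: int) -> PhyloTree:
    """Uniformly random unrooted binary topology on ``labels``.

    Sequential leaf insertion (in sorted label order) on a uniformly
    random edge at each step is uniform over topologies.
    """
    lab = sorted(set(labels))
    if len(lab) < 3:
        raise PhyloError("need at least 3 labels")
    rng = random.Random(seed)
    t = PhyloTree()
    c = t.new_node()
    for l in lab[:3]:
        t.add_edge(c, t.new_node(l))
    for l in lab[3:]:
        u, v = rng.choice(t.edges)
        w = t.subdivide(u, v)
        t.add_edge(w, t.new_node(l))
    return t


def random_spr(t: PhyloTree, rng: random.Random) -> PhyloTree:
    """One random subtree-prune-regraft move on an unrooted binary tree.

    Returns a new tree; the input is untouched.  Retries internally
    until a structurally valid move is found.
    """
    for _ in range(200):
        nt = t.copy()
        edges = nt.edges
        u, v = rng.choice(edges)
        if rng.random() < 0.5:
            u, v = v, u
        if nt.is_leaf(u):
            continue  # nothing left to regraft into on u's side
        nt.remove_edge(u, v)
        rest = nt.component(u)
        a, b = sorted(nt.neighbors(u))
        nt.remove_node(u)  # u had degree 2 after the cut
        nt.add_edge(a, b)
        regraft_edges = [
            e for e in nt.edges if e[0] in rest and e[1] in rest
        ]
        if not regraft_edges:
            continue
        p, q = rng.choice(regraft_edges)
        w = nt.subdivide(p, q)
        nt.add_edge(w, v)
        nt.validate()
        return nt
    raise PhyloError("could not find a valid SPR move")


def overlapping_pair(
    model: PhyloTree,
    overlap: Iterable[str],
    extra_per_side: int = 2,
    disagreement_spr: int = 0,
    seed: int = 0,
) -> tuple[PhyloTree, PhyloTree]:
    """Two binary source trees sharing exactly the ``overlap`` leaf set.

    Both trees are restrictions of ``model``: the first to
    overlap ∪ E1, the second to overlap ∪ E2, where E1, E2 are disjoint
    samples of ``extra_per_side`` non-shared model leaves.  Each of the
    ``disagreement_spr`` SPR moves applied to the second tree is
    accepted only if it changes the tree's restriction to the overlap,
    so requested disagreement always reaches the shared backbone.  With
    zero moves the pair is compatible and the optimal supertree score
    is 0.
    """
    ov = frozenset(overlap)
    if not ov <= model.leaves:
        raise PhyloError("overlap must be a subset of the model's leaves")
    if len(ov) < 4:
        raise PhyloError("overlap must contain at least 4 leaves")
    rest = sorted(model.leaves - ov)
    if len(rest) < 2 * extra_per_side:
        raise PhyloError(
            f"model has {len(rest)} non-overlap leaves, need {2 * extra_per_side}"
        )
    rng = random.Random(seed)
    picked = rng.sample(rest, 2 * extra_per_side)
    e1, e2 = frozenset(picked[:extra_per_side]), frozenset(picked[extra_per_side:])
    t1 = restrict(model, ov | e1)
    t2 = restrict(model, ov | e2)
    for _ in range(disagreement_spr):
        backbone_before = bipartitions(restrict(t2, ov))
        for _attempt in range(100):
            cand = random_spr(t2, rng)
            if bipartitions(restrict(cand, ov)) != backbone_before:
                t2 = cand
                break
        else:
            raise PhyloError("no backbone-changing SPR move found")
    return t1, t2


# ---------------------------------------------------------------------------
# In-literature fixtures
# ---------------------------------------------------------------------------


def lemma2_labels(n: int) -> list[str]:
    """Zero-padded numeric labels so lexicographic order equals numeric."""
    return [f"{k:03d}" for k in range(1, n + 1)]


def lemma2_profile(n: int) -> Profile:
    """The profile of n−3 single-internal-edge trees on n leaves.

    Tree i carries exactly one non-trivial split, [1..i+1 | i+2..n];
    together with :func:`star_tree` and :func:`caterpillar_tree` on the
    same labels it exhibits that the relaxed RF-optimal and relaxed
    split-support-optimal supertrees can differ.
    """
    if n < 5:
        raise PhyloError("the construction needs n >= 5")
    lab = lemma2_labels(n)
    trees = []
    for i in range(1, n - 2):
        t = PhyloTree()
        ha = t.new_node()
        hb = t.new_node()
        t.add_edge(ha, hb)
        for l in lab[: i + 1]:
            t.add_edge(ha, t.new_node(l))
        for l in lab[i + 1 :]:
            t.add_edge(hb, t.new_node(l))
        trees.append(t)
    return Profile(tuple(trees))


def lemma4_trees() -> tuple[PhyloTree, PhyloTree, PhyloTree]:
    """The published worked example: two source trees on overlapping leaf
    sets and an optimal supertree with total RF distance 2 to them."""
    t1 = parse_newick("(A,((B,x),((C,y),(D,E))));")
    t2 = parse_newick("(A,(C,(z,(B,(D,E)))));")
    t_rfs = parse_newick("(A,((C,y),(z,((B,x),(D,E)))));")
    return t1, t2, t_rfs
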