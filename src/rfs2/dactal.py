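"""Divide-and-conquer merging: edge-based dataset decomposition around a
guide tree, short-quartet utilities, and the two-subset merge pipeline.

A guide tree's internal edge e = [A|B] splits the taxa into two
overlapping subsets A ∪ P and B ∪ P, where P collects, from each of the
four subtrees around e, the p topologically nearest leaves (all ties
included).  Trees are re-estimated on the two subsets by a pluggable
estimator and combined with Exact-RFS-2.  When the estimator returns
the true tree restricted to each subset and every short quartet of the
true tree lies inside one subset, the merge provably recovers the true
tree (it is then the unique compatibility supertree).

Only one decomposition level is implemented; recursive decomposition is
possible in principle but a single level suffices for the consistency
argument and keeps the surface small.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Callable, Iterable

from .merge import exact_rfs_2
from .treecore import Bipartition, PhyloError, PhyloTree, bipartitions

__all__ = [
    "Decomposition",
    "decompose_by_edge",
    "short_quartets",
    "covers_all_short_quartets",
    "most_balanced_edge",
    "dactal_merge",
]


@dataclass(frozen=True)
class Decomposition:
    """Two overlapping taxon subsets induced by one guide-tree edge."""

    edge: tuple[int, int]
    p: int
    set_a: frozenset[str]  # A ∪ P
    set_b: frozenset[str]  # B ∪ P
    shared: frozenset[str]  # P


def _subtree_leaf_distances(
    guide: PhyloTree, root: int, blocked: frozenset[int]
) -> dict[str, int]:
    """Edge-count distance from the deleted edge to each leaf of the
    subtree hanging at ``root`` (root itself is at distance 1)."""
    dist = {root: 1}
    out: dict[str, int] = {}
    q = deque([root])
    while q:
        v = q.popleft()
        lbl = guide.label_of(v)
        if lbl is not None:
            out[lbl] = dist[v]
        for u in guide.neighbors(v):
            if u not in dist and u not in blocked:
                dist[u] = dist[v] + 1
                q.append(u)
    return out


def _nearest(dists: dict[str, int], p: int) -> frozenset[str]:
    if len(dists) <= p:
        return frozenset(dists)
    cutoff = sorted(dists.values())[p - 1]
    return frozenset(l for l, d in dists.items() if d <= cutoff)


def _four_subtrees(guide: PhyloTree, u: int, v: int) -> list[tuple[int, frozenset[int]]]:
    blocked = frozenset((u, v))
    roots = [(w, blocked) for w in sorted(guide.neighbors(u) - {v})]
    roots += [(w, blocked) for w in sorted(guide.neighbors(v) - {u})]
    return roots


def decompose_by_edge(guide: PhyloTree, edge, p: int) -> Decomposition:
    """The DACTAL-style decomposition around one internal guide edge.

    ``P`` holds, per each of the four subtrees created by deleting the
    edge and its endpoints, the ``p`` leaves nearest to the edge
    (topological edge count; all ties for the p-th place included).
    """
    u, v = tuple(edge)
    if v not in guide.neighbors(u):
        raise PhyloError(f"({u}, {v}) is not an edge of the guide tree")
    if guide.is_leaf(u) or guide.is_leaf(v):
        raise PhyloError("decomposition requires an internal edge")
    if p < 1:
        raise PhyloError("p must be >= 1")
    shared: frozenset[str] = frozenset()
    for root, blocked in _four_subtrees(guide, u, v):
        shared |= _nearest(_subtree_leaf_distances(guide, root, blocked), p)
    side_u = guide.labels_in(guide.component(u, blocked=frozenset((v,))))
    side_v = guide.leaves - side_u
    return Decomposition(
        edge=(u, v),
        p=p,
        set_a=side_u | shared,
        set_b=side_v | shared,
        shared=shared,
    )


def short_quartets(t: PhyloTree) -> frozenset[Bipartition]:
    """All short-quartet trees of a binary tree.

    For every internal edge, every combination of one nearest leaf
    (tie-inclusive) per surrounding subtree, with the 2|2 topology the
    tree induces on it: leaves from the two same-end subtrees pair up.
    """
    if not t.is_binary():
        raise PhyloError("short quartets are defined for binary trees")
    out: set[Bipartition] = set()
    for (u, v) in t.internal_edges():
        closest: list[frozenset[str]] = []
        for root, blocked in _four_subtrees(t, u, v):
            closest.append(_nearest(_subtree_leaf_distances(t, root, blocked), 1))
        for a1 in closest[0]:
            for a2 in closest[1]:
                for b1 in closest[2]:
                    for b2 in closest[3]:
                        out.add(Bipartition.of((a1, a2), (b1, b2)))
    return frozenset(out)


def covers_all_short_quartets(model: PhyloTree, dec: Decomposition) -> bool:
    """True iff every short quartet of ``model`` lies inside one subset.

    This is the premise under which the two-subset merge of the exact
    restrictions provably returns ``model``.
    """
    for q in short_quartets(model):
        labels = q.universe
        if not (labels <= dec.set_a or labels <= dec.set_b):
            return False
    return True


def most_balanced_edge(guide: PhyloTree) -> tuple[int, int]:
    """The internal edge whose split is closest to halving the leaf set,
    ties broken by the canonical order of the induced bipartitions."""
    internal = guide.internal_edges()
    if not internal:
        raise PhyloError("guide tree has no internal edge")

    def key(e: tuple[int, int]):
        u, v = e
        side = guide.labels_in(guide.component(u, blocked=frozenset((v,))))
        pi = Bipartition.of(side, guide.leaves - side)
        return (abs(len(pi.side_a) - len(pi.side_b)), pi.sort_key())

    return min(internal, key=key)


def dactal_merge(
    guide: PhyloTree,
    estimator: Callable[[frozenset[str]], PhyloTree],
    p: int,
    edge_strategy="balanced",
    seed: int = 0,
) -> PhyloTree:
    """One decomposition + merge round of the divide-and-conquer pipeline.

    ``estimator`` maps a label set to a binary tree on exactly those
    labels (e.g. restriction of a known tree, or any tree-estimation
    method).  ``edge_strategy`` is ``"balanced"`` (default), a callable
    ``guide -> edge``, or an explicit edge (node-id pair).
    """
    if edge_strategy == "balanced":
        edge = most_balanced_edge(guide)
    elif callable(edge_strategy):
        edge = edge_strategy(guide)
    else:
        edge = tuple(edge_strategy)
    dec = decompose_by_edge(guide, edge, p)
    trees = []
    for subset in (dec.set_a, dec.set_b):
        t = estimator(subset)
        if t.leaves != subset:
            raise PhyloError(
                "estimator returned a tree on the wrong leaf set: "
                f"missing {sorted(subset - t.leaves)[:3]}, "
                f"extra {sorted(t.leaves - subset)[:3]}"
            )
        trees.append(t)
    merged, _ = exact_rfs_2(trees[0], trees[1], seed=seed)
    return merged
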