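"""Backbone decomposition of a source tree relative to the shared leaf set.

Given two binary source trees T1, T2 with shared leaf set X, restricting
T_i to X (the *backbone* tree) contracts each source path into a single
backbone edge e; P(e) is that path and w(e) = |P(e)| its edge count.
Deleting the minimal X-spanning (Steiner) subtree from T_i leaves a
forest of *extra subtrees*, each rooted at the vertex that was adjacent
to the Steiner subtree.  Extra subtrees rooted next to an internal
vertex of P(e) belong to TR(e); for binary sources every extra subtree
is of this kind (a Steiner branch vertex of a binary tree has no free
slot), but attachment directly at a backbone vertex is recorded for
completeness on multifurcating input.

On top of the per-tree decomposition, this module carries the shared
bookkeeping the supertree algorithm needs: the trivial / non-trivial
split classes of C(T1|X) ∪ C(T2|X); the partition of all source splits
into Π1 (both sides meet X: splits carried by Steiner-tree edges) and
Π2 (one side disjoint from X: splits inside or pendant to extra
subtrees); the potential function w*; and the p1/p2 decomposition of a
supertree's split support score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .treecore import (
    Bipartition,
    PhyloError,
    PhyloTree,
    bipartitions,
    edge_bipartitions,
    restrict,
)

__all__ = [
    "ExtraSubtree",
    "BackboneDecomposition",
    "SharedContext",
    "compute_backbone",
    "build_context",
    "tr_star",
    "bp_side",
    "trs_side",
    "split_pi",
    "w_star",
    "w_star_set",
    "p_scores",
]

EdgeKey = frozenset  # frozenset({u, v}) of backbone vertex ids


@dataclass(eq=False)
class ExtraSubtree:
    """A rooted component of a source tree left after deleting the backbone.

    Identity (hash/eq) is by object, so extra subtrees can be carried in
    sets and moved between supertree vertices without ambiguity.
    """

    source_index: int  # 1 or 2
    source_tree: PhyloTree
    root: int  # node id in the source tree, adjacent to the Steiner subtree
    node_ids: frozenset[int]
    labels: frozenset[str]
    attach_node: int  # Steiner-subtree node the root was adjacent to
    on_edge: EdgeKey | None  # backbone edge whose path holds attach_node, if any
    path_pos: int = 0  # index of attach_node along the oriented path

    def sort_key(self) -> tuple:
        return (self.source_index, tuple(sorted(self.labels)))


@dataclass
class BackboneDecomposition:
    """T_i restricted to X plus the edge-to-path machinery around it."""

    source: PhyloTree
    x: frozenset[str]
    backbone: PhyloTree  # T_i|_X, vertex ids shared with `source`
    path_map: dict[EdgeKey, list[int]]  # oriented from the side_a endpoint
    weight: dict[EdgeKey, int]  # w(e) = number of source edges on P(e)
    edge_of: dict[Bipartition, EdgeKey]  # e_i(pi)
    bip_of: dict[EdgeKey, Bipartition]
    tr: dict[EdgeKey, list[ExtraSubtree]]  # in path order from side_a
    vertex_extras: dict[int, list[ExtraSubtree]]  # attached at backbone vertices
    extras: list[ExtraSubtree]

    @property
    def splits(self) -> frozenset[Bipartition]:
        return frozenset(self.edge_of)


def _steiner_nodes(source: PhyloTree, x: frozenset[str]) -> set[int]:
    """Vertices of the minimal subtree of `source` spanning the leaves in x."""
    keep = {v: set(source.neighbors(v)) for v in source.nodes}
    pending = [
        v for v in source.nodes if len(keep[v]) <= 1 and source.label_of(v) not in x
    ]
    while pending:
        v = pending.pop()
        if v not in keep:
            continue
        nbs = keep.pop(v)
        for u in nbs:
            keep[u].discard(v)
            if len(keep[u]) <= 1 and source.label_of(u) not in x:
                pending.append(u)
    return set(keep)


def _decompose(source: PhyloTree, x: frozenset[str], index: int) -> BackboneDecomposition:
    """Backbone decomposition for |x| >= 1 (degenerate sizes included)."""
    if not x:
        raise PhyloError("shared leaf set is empty")
    missing = x - source.leaves
    if missing:
        raise PhyloError(f"labels not in source tree: {sorted(missing)}")

    steiner = _steiner_nodes(source, x)
    sdeg = {v: len(source.neighbors(v) & steiner) for v in steiner}
    kept = {v for v in steiner if sdeg[v] >= 3 or source.label_of(v) in x}

    # contract Steiner paths between kept vertices into backbone edges
    backbone = PhyloTree()
    backbone._adj = {v: set() for v in kept}
    backbone._label = {v: source.label_of(v) for v in kept if source.label_of(v) in x}
    backbone._node_of = {l: v for v, l in backbone._label.items()}
    backbone._next_id = max(kept, default=0) + 1

    path_map: dict[EdgeKey, list[int]] = {}
    for start in sorted(kept):
        for nb in sorted(source.neighbors(start) & steiner):
            path = [start, nb]
            while path[-1] not in kept:
                nxt = [
                    u
                    for u in source.neighbors(path[-1]) & steiner
                    if u != path[-2]
                ]
                assert len(nxt) == 1
                path.append(nxt[0])
            key = frozenset((start, path[-1]))
            if key not in path_map:
                path_map[key] = path
                backbone.add_edge(start, path[-1])
    weight = {k: len(p) - 1 for k, p in path_map.items()}

    # splits induced by backbone edges, and path orientation from side_a
    edge_of: dict[Bipartition, EdgeKey] = {}
    bip_of: dict[EdgeKey, Bipartition] = {}
    if len(x) >= 2:
        for ek, pi in edge_bipartitions(backbone).items():
            u, v = tuple(ek)
            edge_of[pi] = ek
            bip_of[ek] = pi
            path = path_map[ek]
            comp_first = backbone.labels_in(
                backbone.component(path[0], blocked=frozenset((path[-1],)))
            )
            if not (pi.side_a <= comp_first):
                path_map[ek] = path[::-1]

    # extra subtrees: components of source - steiner
    node_on_path: dict[int, EdgeKey] = {}
    for ek, path in path_map.items():
        for v in path[1:-1]:
            node_on_path[v] = ek
    extras: list[ExtraSubtree] = []
    tr: dict[EdgeKey, list[ExtraSubtree]] = {k: [] for k in path_map}
    vertex_extras: dict[int, list[ExtraSubtree]] = {v: [] for v in kept}
    fsteiner = frozenset(steiner)
    for s in sorted(steiner):
        for nb in sorted(source.neighbors(s) - fsteiner):
            comp = source.component(nb, blocked=fsteiner)
            on_edge = node_on_path.get(s)
            ex = ExtraSubtree(
                source_index=index,
                source_tree=source,
                root=nb,
                node_ids=frozenset(comp),
                labels=source.labels_in(comp),
                attach_node=s,
                on_edge=on_edge,
                path_pos=(path_map[on_edge].index(s) if on_edge is not None else 0),
            )
            extras.append(ex)
            if on_edge is not None:
                tr[on_edge].append(ex)
            else:
                vertex_extras[s].append(ex)
    for k in tr:
        tr[k].sort(key=lambda e: e.path_pos)

    return BackboneDecomposition(
        source=source,
        x=x,
        backbone=backbone,
        path_map=path_map,
        weight=weight,
        edge_of=edge_of,
        bip_of=bip_of,
        tr=tr,
        vertex_extras=vertex_extras,
        extras=extras,
    )


def compute_backbone(source: PhyloTree, x) -> BackboneDecomposition:
    """Public decomposition entry point; requires |x| >= 3.

    Smaller shared sets have no backbone edge structure worth exposing;
    the supertree algorithm handles them internally as degenerate cases.
    """
    fx = frozenset(x)
    if len(fx) < 3:
        raise PhyloError(f"backbone decomposition needs |x| >= 3, got {len(fx)}")
    return _decompose(source, fx, index=1)


@dataclass
class SharedContext:
    """Everything Exact-RFS-2 pre-computes about a pair of source trees."""

    t1: PhyloTree
    t2: PhyloTree
    x: frozenset[str]
    decomp1: BackboneDecomposition
    decomp2: BackboneDecomposition
    c1x: frozenset[Bipartition]  # C(T1|_X)
    c2x: frozenset[Bipartition]  # C(T2|_X)
    triv: frozenset[Bipartition]
    nontriv: frozenset[Bipartition]
    c_full: dict[int, frozenset[Bipartition]]  # C(T_i) on full leaf sets
    pi1: dict[int, frozenset[Bipartition]]  # per-source Π1
    pi2: dict[int, frozenset[Bipartition]]  # per-source Π2

    @property
    def shared_splits(self) -> frozenset[Bipartition]:
        return self.c1x & self.c2x

    @property
    def all_splits(self) -> frozenset[Bipartition]:
        """C(T1, T2, X) = C(T1|_X) ∪ C(T2|_X)."""
        return self.c1x | self.c2x

    def decomp(self, i: int) -> BackboneDecomposition:
        return self.decomp1 if i == 1 else self.decomp2


def build_context(t1: PhyloTree, t2: PhyloTree) -> SharedContext:
    """Pre-processing shared by all later phases; supports any |X| >= 1."""
    x = t1.leaves & t2.leaves
    if not x:
        raise PhyloError("source trees share no leaves")
    d1 = _decompose(t1, x, 1)
    d2 = _decompose(t2, x, 2)
    c1x, c2x = d1.splits, d2.splits
    allx = c1x | c2x
    triv = frozenset(p for p in allx if p.is_trivial)
    c_full: dict[int, frozenset[Bipartition]] = {}
    pi1: dict[int, frozenset[Bipartition]] = {}
    pi2: dict[int, frozenset[Bipartition]] = {}
    for i, t in ((1, t1), (2, t2)):
        ci = bipartitions(t) if len(t.leaves) >= 2 else frozenset()
        c_full[i] = ci
        pi1[i] = frozenset(p for p in ci if (p.side_a & x) and (p.side_b & x))
        pi2[i] = ci - pi1[i]
    return SharedContext(
        t1=t1,
        t2=t2,
        x=x,
        decomp1=d1,
        decomp2=d2,
        c1x=c1x,
        c2x=c2x,
        triv=triv,
        nontriv=allx - triv,
        c_full=c_full,
        pi1=pi1,
        pi2=pi2,
    )


# ---------------------------------------------------------------------------
# Derived mappings
# ---------------------------------------------------------------------------


def tr_star(ctx: SharedContext, p: Bipartition) -> frozenset[ExtraSubtree]:
    """TR*(pi): extra subtrees attached along the paths of e_1(pi), e_2(pi).

    Empty (by convention, mirroring w* = 0) if pi is in neither backbone.
    """
    out: list[ExtraSubtree] = []
    for i in (1, 2):
        d = ctx.decomp(i)
        ek = d.edge_of.get(p)
        if ek is not None:
            out.extend(d.tr[ek])
    return frozenset(out)


Which = Literal[1, 2, "both"]


def bp_side(ctx: SharedContext, q, which: Which = "both") -> frozenset[Bipartition]:
    """BP_i(Q): backbone splits with one side a strict subset of Q."""
    fq = frozenset(q)
    if not fq <= ctx.x:
        raise PhyloError("Q must be a subset of the shared leaf set X")
    idxs = (1, 2) if which == "both" else (which,)
    out = set()
    for i in idxs:
        for p in ctx.decomp(i).splits:
            if (p.side_a < fq) or (p.side_b < fq):
                out.add(p)
    return frozenset(out)


def trs_side(ctx: SharedContext, q, which: Which = "both") -> frozenset[ExtraSubtree]:
    """TRS_i(Q): extra subtrees hanging off the BP_i(Q) paths ("on Q's side")."""
    fq = frozenset(q)
    idxs = (1, 2) if which == "both" else (which,)
    out: set[ExtraSubtree] = set()
    for i in idxs:
        d = ctx.decomp(i)
        for p in bp_side(ctx, fq, i):
            if p in d.edge_of:
                out.update(d.tr[d.edge_of[p]])
    return frozenset(out)


def split_pi(ctx: SharedContext) -> tuple[frozenset[Bipartition], frozenset[Bipartition]]:
    """(Π1, Π2): source splits meeting X on both sides vs. on at most one.

    Tracked per source tree internally; the returned sets are the unions
    (disjoint whenever the two leaf sets differ, since then no split can
    occur in both source trees).
    """
    return (ctx.pi1[1] | ctx.pi1[2], ctx.pi2[1] | ctx.pi2[2])


def w_star(ctx: SharedContext, p: Bipartition) -> int:
    """w*(pi): maximum possible p1 gain from adding pi to the supertree's
    X-restriction — the number of source edges whose splits restrict to pi."""
    w = 0
    found = False
    for i in (1, 2):
        d = ctx.decomp(i)
        ek = d.edge_of.get(p)
        if ek is not None:
            w += d.weight[ek]
            found = True
    return w if found else 0


def w_star_set(ctx: SharedContext, f) -> int:
    """Additive extension of w* to a set of bipartitions."""
    return sum(w_star(ctx, p) for p in set(f))


def p_scores(ctx: SharedContext, t: PhyloTree) -> tuple[int, int]:
    """(p1, p2): split support decomposed over Π1 / Π2.

    p1 + p2 equals the total split support of ``t`` against {T1, T2}.
    """
    s = ctx.t1.leaves | ctx.t2.leaves
    if t.leaves != s:
        raise PhyloError("supertree leaf set must equal S1 ∪ S2")
    p1 = p2 = 0
    for i in (1, 2):
        si = ctx.decomp(i).source.leaves
        if len(si) < 2:
            continue
        ct = bipartitions(restrict(t, si))
        hit = ct & ctx.c_full[i]
        p1 += len(hit & ctx.pi1[i])
        p2 += len(hit & ctx.pi2[i])
    return p1, p2
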