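"""Exact-RFS-2: the exact Robinson-Foulds / Split-Fit supertree of two
binary trees with overlapping leaf sets.

The algorithm runs in four phases:

1. *Pre-processing*: backbone decompositions of both source trees
   relative to the shared leaf set X (:mod:`rfs2.decompose`).
2. *Initial construction*: a star tree T_init whose centre is adjacent
   to every shared leaf and to the root of every extra subtree.  T_init
   already maximises the p2 component of the split support score.
3. *Refinement*: the trivial splits of X are realised by threading their
   extra subtrees onto the pendant edges; then a maximum-weight
   independent set of the weighted incompatibility graph selects the
   compatible split set I of largest total potential w*, and each
   non-trivial split in I is inserted by a single vertex split
   (Algorithm "refine one bipartition" below), raising p1 by exactly
   w*(pi) per insertion.  The application order does not affect the
   final (p1, p2).
4. *Resolution*: the optimal (possibly multifurcating) tree T* is
   arbitrarily but deterministically refined to a binary tree, which
   cannot decrease the split support score.

The refinement phase maintains two auxiliary maps: ``sv(pi)`` is the
unique supertree vertex whose splitting inserts pi into C(T|_X), and
``h(v)`` is the set of still-addable splits assigned to vertex v.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import mwis as _mwis
from .decompose import (
    ExtraSubtree,
    SharedContext,
    build_context,
    tr_star,
    trs_side,
    w_star,
    w_star_set,
)
from .treecore import (
    Bipartition,
    PhyloError,
    PhyloTree,
    Profile,
    ScoreReport,
    are_compatible,
    bipartitions,
    edge_bipartitions,
    profile_scores,
    restrict,
)

__all__ = [
    "RefinementState",
    "initial_state",
    "build_initial_tree",
    "add_trivial_bipartitions",
    "refine_with_bipartition",
    "resolve_to_binary",
    "exact_rfs_2",
]


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------


@dataclass
class RefinementState:
    """The growing supertree plus the H / sv bookkeeping."""

    tree: PhyloTree
    ctx: SharedContext
    center: int
    h: dict[int, set[Bipartition]]
    sv: dict[Bipartition, int]
    extra_root: dict[ExtraSubtree, int]  # extra subtree -> its root node in `tree`
    root_extra: dict[int, ExtraSubtree]

    def p_scores(self) -> tuple[int, int]:
        from .decompose import p_scores

        return p_scores(self.ctx, self.tree)


def _graft(tree: PhyloTree, ex: ExtraSubtree) -> int:
    """Copy an extra subtree into ``tree``; return the new root node id."""
    src = ex.source_tree
    node_map: dict[int, int] = {}
    for nid in sorted(ex.node_ids):
        node_map[nid] = tree.new_node(src.label_of(nid))
    for u in ex.node_ids:
        for v in src.neighbors(u):
            if v in ex.node_ids and u < v:
                tree.add_edge(node_map[u], node_map[v])
    return node_map[ex.root]


def initial_state(ctx: SharedContext) -> RefinementState:
    """Build T_init and fresh H / sv maps.

    The centre vertex is adjacent to every shared leaf and to the root
    of every extra subtree of either source; every non-trivial split of
    the two backbones is initially addable at the centre.
    """
    tree = PhyloTree()
    center = tree.new_node()
    for lbl in sorted(ctx.x):
        tree.add_edge(center, tree.new_node(lbl))
    extra_root: dict[ExtraSubtree, int] = {}
    root_extra: dict[int, ExtraSubtree] = {}
    for d in (ctx.decomp1, ctx.decomp2):
        for ex in sorted(d.extras, key=ExtraSubtree.sort_key):
            rid = _graft(tree, ex)
            tree.add_edge(center, rid)
            extra_root[ex] = rid
            root_extra[rid] = ex
    return RefinementState(
        tree=tree,
        ctx=ctx,
        center=center,
        h={center: set(ctx.nontriv)},
        sv={p: center for p in ctx.nontriv},
        extra_root=extra_root,
        root_extra=root_extra,
    )


def build_initial_tree(ctx: SharedContext) -> PhyloTree:
    """T_init alone (the centre star over X and all extra-subtree roots)."""
    return initial_state(ctx).tree


# ---------------------------------------------------------------------------
# Refinement mechanics
# ---------------------------------------------------------------------------


def _attach_chain(tree: PhyloTree, u: int, v: int, roots: list[int]) -> None:
    """Subdivide edge (u, v), attaching each root in order starting from u."""
    prev = u
    for r in roots:
        w = tree.subdivide(prev, v)
        tree.add_edge(w, r)
        prev = w


def _ordered_star_extras(ctx: SharedContext, p: Bipartition, from_side: frozenset[str]):
    """TR*(p) as a list: source-1 extras then source-2 extras, each in the
    source path order starting from the given side of p."""
    out: list[ExtraSubtree] = []
    for i in (1, 2):
        d = ctx.decomp(i)
        ek = d.edge_of.get(p)
        if ek is None:
            continue
        lst = d.tr[ek]  # stored oriented from p.side_a
        out.extend(lst if from_side == p.side_a else list(reversed(lst)))
    return out


def add_trivial_bipartitions(state: RefinementState) -> RefinementState:
    """Realise every trivial split of X at full potential.

    The extra subtrees of TR*([{x}|X-x]) are threaded onto x's pendant
    edge in source path order (closest-to-x first), after which
    p1 = w*(Triv) while p2 is untouched.
    """
    tree, ctx = state.tree, state.ctx
    for p in sorted(ctx.triv, key=Bipartition.sort_key):
        single = p.side_a if len(p.side_a) == 1 else p.side_b
        ordered = _ordered_star_extras(ctx, p, single)
        if not ordered:
            continue
        (x_label,) = single
        leaf = tree.node_of(x_label)
        roots = []
        for ex in ordered:
            r = state.extra_root[ex]
            if state.center not in tree.neighbors(r):
                raise PhyloError("extra subtree moved before trivial-split phase")
            tree.remove_edge(state.center, r)
            roots.append(r)
        _attach_chain(tree, leaf, state.center, roots)
    return state


def refine_with_bipartition(
    state: RefinementState, p: Bipartition, check: bool = False
) -> RefinementState:
    """Insert one non-trivial split of X into the supertree (Algorithm 2).

    Splits sv(p) into an edge (v_a, v_b) inducing p in T|_X, re-homes the
    extra subtrees (TR*(p) onto the new edge in path order, TRS(A) to
    v_a, TRS(B) to v_b, unconstrained ones to v_a), and reassigns the
    pending splits of H(sv(p)) to v_a / v_b by side containment,
    discarding those now incompatible.  Raises p1 by exactly w*(p).
    """
    tree, ctx = state.tree, state.ctx
    if p not in state.sv:
        cur = bipartitions(restrict(tree, ctx.x)) if len(ctx.x) >= 2 else frozenset()
        if p in cur:
            raise PhyloError(f"bipartition {p} already present in the restriction")
        raise PhyloError(f"bipartition {p} is not addable to the current supertree")
    if check:
        p1_before, p2_before = state.p_scores()

    v = state.sv[p]
    a_side, b_side = p.side_a, p.side_b
    n_a: list[int] = []
    n_b: list[int] = []
    n_other: list[int] = []
    for u in sorted(tree.neighbors(v)):
        reach = tree.labels_in(tree.component(u, blocked=frozenset((v,)))) & ctx.x
        in_a, in_b = bool(reach & a_side), bool(reach & b_side)
        if in_a and in_b:
            raise PhyloError(f"bipartition {p} is incompatible with the supertree")
        (n_a if in_a else n_b if in_b else n_other).append(u)

    star_extras = _ordered_star_extras(ctx, p, a_side)
    star_set = set(star_extras)
    trs_a = trs_side(ctx, a_side)
    trs_b = trs_side(ctx, b_side)

    va = tree.new_node()
    vb = tree.new_node()
    tree.remove_node(v)
    tree.add_edge(va, vb)
    for u in n_a:
        tree.add_edge(va, u)
    for u in n_b:
        tree.add_edge(vb, u)
    for u in n_other:
        ex = state.root_extra.get(u)
        if ex is None:
            raise PhyloError(f"unlabelled dangling neighbor {u} is not an extra root")
        if ex in star_set:
            continue  # threaded onto (v_a, v_b) below
        if ex in trs_a:
            tree.add_edge(va, u)
        elif ex in trs_b:
            tree.add_edge(vb, u)
        else:
            tree.add_edge(va, u)  # unconstrained: deterministic choice
    for ex in star_extras:
        if state.extra_root[ex] not in set(n_other):
            raise PhyloError("TR*(p) extra subtree was not adjacent to sv(p)")
    _attach_chain(tree, va, vb, [state.extra_root[ex] for ex in star_extras])

    # update H / sv
    pending = state.h.pop(v, set())
    pending.discard(p)
    del state.sv[p]
    ha: set[Bipartition] = set()
    hb: set[Bipartition] = set()
    for q in pending:
        if not are_compatible(p, q):
            state.sv.pop(q, None)
            continue
        if q.side_a < a_side or q.side_b < a_side:
            ha.add(q)
            state.sv[q] = va
        else:
            hb.add(q)
            state.sv[q] = vb
    state.h[va] = ha
    state.h[vb] = hb
    if v == state.center:
        state.center = va

    if check:
        p1_after, p2_after = state.p_scores()
        if p1_after - p1_before != w_star(ctx, p):
            raise AssertionError(
                f"p1 gain {p1_after - p1_before} != w*({p}) = {w_star(ctx, p)}"
            )
        if p2_after != p2_before:
            raise AssertionError("p2 changed during a refinement step")
        check_state_invariants(state)
    return state


# ---------------------------------------------------------------------------
# Invariant checking (debug mode)
# ---------------------------------------------------------------------------


def check_state_invariants(state: RefinementState) -> None:
    """Assert the three structural invariants of the refinement phase.

    1. sv(pi) is a vertex whose splitting can insert pi into C(T|_X) and
       h/sv are mutually consistent;
    2. every extra subtree of TR*(pi) for a pending pi is rooted at a
       neighbor of sv(pi);
    3. for each split [A|B] already realised in T|_X, the TRS(A) extras
       sit on the A-side of the realising path, and symmetrically for B.
    """
    tree, ctx = state.tree, state.ctx
    cur = bipartitions(restrict(tree, ctx.x)) if len(ctx.x) >= 2 else frozenset()
    # h / sv consistency
    for v, hs in state.h.items():
        for q in hs:
            if state.sv.get(q) != v:
                raise AssertionError(f"h/sv inconsistent for {q}")
    for q, v in state.sv.items():
        if q not in state.h.get(v, set()):
            raise AssertionError(f"sv({q}) vertex lacks {q} in h")
        if q in cur:
            raise AssertionError(f"{q} already realised but still pending")
        # invariant 1: no neighbor of v reaches both sides of q
        for u in tree.neighbors(v):
            reach = tree.labels_in(tree.component(u, blocked=frozenset((v,)))) & ctx.x
            if (reach & q.side_a) and (reach & q.side_b):
                raise AssertionError(f"sv({q}) cannot insert {q} by splitting")
        # invariant 2
        for ex in tr_star(ctx, q):
            if state.extra_root[ex] not in tree.neighbors(v):
                raise AssertionError(f"TR*({q}) extra not adjacent to sv({q})")
    # invariant 3
    eb = edge_bipartitions(tree)
    for q in cur:
        path_edges = [ek for ek, bp in eb.items() if bp.restrict(ctx.x) == q]
        blocked_pairs = {frozenset(ek) for ek in path_edges}
        comp_nodes: dict[str, set[int]] = {}
        for side_name, side in (("a", q.side_a), ("b", q.side_b)):
            start = tree.node_of(min(side))
            seen = {start}
            stack = [start]
            while stack:
                nd = stack.pop()
                for u in tree.neighbors(nd):
                    if frozenset((nd, u)) in blocked_pairs or u in seen:
                        continue
                    seen.add(u)
                    stack.append(u)
            comp_nodes[side_name] = seen
        for ex in trs_side(ctx, q.side_a):
            if state.extra_root[ex] not in comp_nodes["a"]:
                raise AssertionError(f"TRS(A) extra on wrong side of {q}")
        for ex in trs_side(ctx, q.side_b):
            if state.extra_root[ex] not in comp_nodes["b"]:
                raise AssertionError(f"TRS(B) extra on wrong side of {q}")


# ---------------------------------------------------------------------------
# Binary resolution
# ---------------------------------------------------------------------------


def _branch_key(t: PhyloTree, v: int, u: int) -> str:
    return min(t.labels_in(t.component(u, blocked=frozenset((v,)))))


def resolve_to_binary(t: PhyloTree, seed: int = 0) -> PhyloTree:
    """Arbitrary but seed-deterministic binary refinement.

    Each multifurcation is resolved by repeatedly pairing two of its
    branches (chosen by a seeded RNG over canonically ordered branches),
    so C(t) ⊆ C(result) and the split support score never decreases.
    """
    nt = t.copy()
    if len(nt.leaves) < 4:
        return nt
    rng = random.Random(seed)
    while True:
        multis = [v for v in nt.nodes if not nt.is_leaf(v) and nt.degree(v) > 3]
        if not multis:
            break
        multis.sort(key=lambda v: min(_branch_key(nt, v, u) for u in nt.neighbors(v)))
        v = multis[0]
        nbs = sorted(nt.neighbors(v), key=lambda u: _branch_key(nt, v, u))
        i, j = sorted(rng.sample(range(len(nbs)), 2))
        w = nt.new_node()
        for u in (nbs[i], nbs[j]):
            nt.remove_edge(v, u)
            nt.add_edge(w, u)
        nt.add_edge(v, w)
    return nt


# ---------------------------------------------------------------------------
# The full algorithm
# ---------------------------------------------------------------------------


def _require_binary(t: PhyloTree, name: str) -> None:
    t.validate()
    for v in t.nodes:
        if not t.is_leaf(v) and t.degree(v) != 3 and len(t.leaves) >= 3:
            near = min(t.labels_in(t.component(v)))
            raise PhyloError(
                f"{name} is not binary: internal vertex {v} (tree containing "
                f"leaf {near!r}) has degree {t.degree(v)}"
            )


def exact_rfs_2(
    t1: PhyloTree,
    t2: PhyloTree,
    seed: int = 0,
    relax: bool = False,
    check_invariants: bool = False,
    order_seed: int | None = None,
) -> tuple[PhyloTree, ScoreReport]:
    """Optimal Robinson-Foulds (equivalently Split-Fit) supertree of two
    binary trees.

    With ``relax=True`` the pre-resolution tree T* is returned: it is an
    optimal solution of the relaxed (not necessarily binary) Split-Fit
    problem.  ``order_seed`` permutes the order in which the selected
    non-trivial splits are applied; the resulting scores are invariant.
    """
    _require_binary(t1, "first tree")
    _require_binary(t2, "second tree")
    profile = Profile((t1, t2))
    s = profile.universe
    x = t1.leaves & t2.leaves
    if not x:
        raise PhyloError("source trees share no leaves")

    if len(s) <= 3:
        out = PhyloTree()
        if len(s) == 1:
            out.new_node(min(s))
        elif len(s) == 2:
            a, b = sorted(s)
            out.add_edge(out.new_node(a), out.new_node(b))
        else:
            c = out.new_node()
            for lbl in sorted(s):
                out.add_edge(c, out.new_node(lbl))
        return out, profile_scores(out, profile)

    ctx = build_context(t1, t2)
    state = initial_state(ctx)
    add_trivial_bipartitions(state)
    if check_invariants:
        check_state_invariants(state)

    selected: frozenset[Bipartition] = frozenset(ctx.triv)
    if len(x) >= 4:
        g = _mwis.build_graph(ctx)
        ids = _mwis.max_weight_independent_set(g)
        selected = _mwis.selected_splits(g, ids)
        chosen = sorted(
            (p for p in selected if not p.is_trivial), key=Bipartition.sort_key
        )
        if order_seed is not None:
            random.Random(order_seed).shuffle(chosen)
        for p in chosen:
            refine_with_bipartition(state, p, check=check_invariants)
    if check_invariants:
        p1, _ = state.p_scores()
        if p1 != w_star_set(ctx, selected):
            raise AssertionError("p1(T*) != w*(I) after the refinement phase")

    t_star = state.tree.copy()
    t_star.suppress_degree_two()
    if relax:
        return t_star, profile_scores(t_star, profile)
    result = resolve_to_binary(t_star, seed)
    result.validate()
    return result, profile_scores(result, profile)
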