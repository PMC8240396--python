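"""Unrooted leaf-labelled trees, Newick I/O, restriction, bipartitions and scores.

Everything downstream (decomposition, supertree merging, the brute-force
oracles) speaks in terms of two objects defined here: :class:`PhyloTree`,
an unrooted, possibly multifurcating tree whose leaves carry unique string
labels, and :class:`Bipartition`, the canonical two-sided split of a leaf
set induced by deleting one tree edge.

Conventions
-----------
* Trees are unrooted.  Rooted Newick input is accepted and the artificial
  degree-2 root is suppressed on construction.
* Branch lengths and internal node labels are parsed and discarded: all
  scores here are purely topological.
* No internal vertex ever has degree 2; suppression happens on
  construction and after every edit that could create one.
* A bipartition is stored canonically: the side containing the smallest
  label (lexicographic) is ``side_a`` so that sets of bipartitions hash
  and compare deterministically.
* Robinson-Foulds (RF) distance and split support (SF) between trees with
  different leaf sets are computed after restricting both trees to the
  shared leaf set X.  When |X| < 3 both restrictions carry no conflicting
  structure, so RF is 0; SF is the honest count of shared splits of the
  restrictions (|X| trivial splits for |X| >= 3, one split for |X| = 2,
  zero for a single shared leaf).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy
from dendropy.dataio import newickreader

__all__ = [
    "PhyloError",
    "NewickParseError",
    "DuplicateLabelError",
    "PhyloTree",
    "Bipartition",
    "Profile",
    "ScoreReport",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "edge_bipartitions",
    "restrict",
    "rf_distance",
    "sf_support",
    "profile_scores",
    "are_compatible",
]


class PhyloError(ValueError):
    """Base class for all domain errors raised by this package."""


class NewickParseError(PhyloError):
    """Malformed Newick input; the message includes the source position."""


class DuplicateLabelError(PhyloError):
    """The same leaf label occurs more than once in one tree."""


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------


class PhyloTree:
    """Unrooted leaf-labelled tree.

    Node ids are opaque integers.  Labels live only on leaves and are
    unique within a tree.  The adjacency is symmetric and the tree is
    always connected with ``|E| = |V| - 1``.
    """

    __slots__ = ("_adj", "_label", "_node_of", "_next_id")

    def __init__(self) -> None:
        self._adj: dict[int, set[int]] = {}
        self._label: dict[int, str] = {}
        self._node_of: dict[str, int] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------

    def new_node(self, label: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self._adj[nid] = set()
        if label is not None:
            if label in self._node_of:
                raise DuplicateLabelError(f"duplicate leaf label {label!r}")
            self._label[nid] = label
            self._node_of[label] = nid
        return nid

    def add_edge(self, u: int, v: int) -> None:
        self._adj[u].add(v)
        self._adj[v].add(u)

    def remove_edge(self, u: int, v: int) -> None:
        self._adj[u].discard(v)
        self._adj[v].discard(u)

    def remove_node(self, v: int) -> None:
        for u in list(self._adj[v]):
            self.remove_edge(u, v)
        del self._adj[v]
        lbl = self._label.pop(v, None)
        if lbl is not None:
            del self._node_of[lbl]

    def copy(self) -> "PhyloTree":
        t = PhyloTree()
        t._adj = {v: set(nb) for v, nb in self._adj.items()}
        t._label = dict(self._label)
        t._node_of = dict(self._node_of)
        t._next_id = self._next_id
        return t

    # -- queries -------------------------------------------------------

    @property
    def nodes(self) -> list[int]:
        return sorted(self._adj)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (min(u, v), max(u, v)) for u in self._adj for v in self._adj[u] if u < v
        )

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def neighbors(self, v: int) -> set[int]:
        return set(self._adj[v])

    @property
    def leaves(self) -> frozenset[str]:
        return frozenset(self._node_of)

    def label_of(self, v: int) -> str | None:
        return self._label.get(v)

    def node_of(self, label: str) -> int:
        return self._node_of[label]

    def is_leaf(self, v: int) -> bool:
        return v in self._label

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v)
            for (u, v) in self.edges
            if not self.is_leaf(u) and not self.is_leaf(v)
        ]

    def is_binary(self) -> bool:
        """True iff every internal (unlabelled) vertex has degree exactly 3."""
        return all(
            self.degree(v) == 3 for v in self._adj if not self.is_leaf(v)
        ) and all(self.degree(v) <= 1 for v in self._label)

    def component(self, start: int, blocked: frozenset[int] = frozenset()) -> set[int]:
        """Nodes reachable from ``start`` without entering ``blocked``."""
        seen = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for u in self._adj[v]:
                if u not in seen and u not in blocked:
                    seen.add(u)
                    stack.append(u)
        return seen

    def labels_in(self, nodes: Iterable[int]) -> frozenset[str]:
        return frozenset(self._label[v] for v in nodes if v in self._label)

    # -- edits ---------------------------------------------------------

    def suppress_degree_two(self) -> None:
        """Remove every unlabelled degree-2 vertex, fusing its two edges."""
        again = True
        while again:
            again = False
            for v in list(self._adj):
                if v not in self._label and len(self._adj[v]) == 2:
                    a, b = sorted(self._adj[v])
                    self.remove_node(v)
                    self.add_edge(a, b)
                    again = True

    def subdivide(self, u: int, v: int) -> int:
        """Insert a fresh unlabelled vertex on edge (u, v); return its id."""
        if v not in self._adj[u]:
            raise PhyloError(f"({u}, {v}) is not an edge")
        w = self.new_node()
        self.remove_edge(u, v)
        self.add_edge(u, w)
        self.add_edge(w, v)
        return w

    # -- validation & comparison --------------------------------------

    def validate(self) -> None:
        n_nodes = len(self._adj)
        n_edges = sum(len(nb) for nb in self._adj.values()) // 2
        if n_nodes == 0:
            raise PhyloError("empty tree")
        if n_edges != n_nodes - 1:
            raise PhyloError("not a tree: |E| != |V| - 1")
        if len(self.component(next(iter(self._adj)))) != n_nodes:
            raise PhyloError("not connected")
        if len(self.leaves) >= 2:
            for v in self._label:
                if len(self._adj[v]) != 1:
                    raise PhyloError(
                        f"leaf {self._label[v]!r} has degree {len(self._adj[v])}"
                    )
        for v in self._adj:
            if v not in self._label and len(self._adj[v]) == 2:
                raise PhyloError(f"internal vertex {v} has degree 2")

    def topologically_equal(self, other: "PhyloTree") -> bool:
        """Leaf-label isomorphism test via bipartition-set equality.

        Valid because trees here never contain suppressed-away degree-2
        vertices, so the split set determines the topology.
        """
        if self.leaves != other.leaves:
            return False
        if len(self.leaves) < 2:
            return True
        return bipartitions(self) == bipartitions(other)


# ---------------------------------------------------------------------------
# Bipartition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bipartition:
    """A two-sided split [A|B] of a leaf-label universe.

    ``side_a`` always contains the smallest label of the universe, which
    makes the representation canonical (idempotent) and hashing
    deterministic.
    """

    side_a: frozenset[str]
    side_b: frozenset[str]

    @staticmethod
    def of(a: Iterable[str], b: Iterable[str]) -> "Bipartition":
        fa, fb = frozenset(a), frozenset(b)
        if not fa or not fb:
            raise PhyloError("bipartition sides must be non-empty")
        if fa & fb:
            raise PhyloError("bipartition sides must be disjoint")
        if min(fa) > min(fb):
            fa, fb = fb, fa
        return Bipartition(fa, fb)

    @property
    def universe(self) -> frozenset[str]:
        return self.side_a | self.side_b

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) == 1

    def restrict(self, r: Iterable[str]) -> "Bipartition | None":
        """The induced split [A∩R | B∩R], or None if a side is emptied."""
        fr = frozenset(r)
        a, b = self.side_a & fr, self.side_b & fr
        if not a or not b:
            return None
        return Bipartition.of(a, b)

    def sort_key(self) -> tuple:
        return (tuple(sorted(self.side_a)), tuple(sorted(self.side_b)))

    def __repr__(self) -> str:  # compact, deterministic
        return f"[{','.join(sorted(self.side_a))}|{','.join(sorted(self.side_b))}]"


def are_compatible(p1: Bipartition, p2: Bipartition) -> bool:
    """Split compatibility: some tree on the common universe holds both.

    Equivalent to at least one of the four pairwise side-intersections
    being empty.
    """
    if p1.universe != p2.universe:
        raise PhyloError("bipartitions live on different universes")
    return (
        not (p1.side_a & p2.side_a)
        or not (p1.side_a & p2.side_b)
        or not (p1.side_b & p2.side_a)
        or not (p1.side_b & p2.side_b)
    )


# ---------------------------------------------------------------------------
# Newick I/O (via dendropy; topology only)
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse one Newick string into an unrooted :class:`PhyloTree`.

    Branch lengths and internal labels are discarded.  A degree-2 root
    produced by rooted input is suppressed.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise DuplicateLabelError(str(exc)) from exc
    except Exception as exc:  # dendropy raises many parse error subclasses
        raise NewickParseError(str(exc)) from exc

    t = PhyloTree()
    node_map: dict[object, int] = {}
    for nd in dtree.preorder_node_iter():
        label = nd.taxon.label if (nd.taxon is not None and nd.is_leaf()) else None
        node_map[nd] = t.new_node(label)
        if nd.parent_node is not None:
            t.add_edge(node_map[nd.parent_node], node_map[nd])
    t.suppress_degree_two()
    t.validate()
    return t


def _min_descendant(t: PhyloTree, v: int, parent: int | None) -> str:
    best = t.label_of(v)
    stack = [(v, parent)]
    while stack:
        node, par = stack.pop()
        lbl = t.label_of(node)
        if lbl is not None and (best is None or lbl < best):
            best = lbl
        for u in t.neighbors(node):
            if u != par:
                stack.append((u, node))
    assert best is not None
    return best


def write_newick(t: PhyloTree) -> str:
    """Deterministic Newick for an unrooted tree.

    The tree is written rooted at the internal vertex adjacent to the
    smallest leaf label; at every level children are emitted in sorted
    order of their smallest descendant label.  Round-trips through
    :func:`parse_newick` to a topologically equal tree.
    """
    lvs = sorted(t.leaves)
    if not lvs:
        raise PhyloError("cannot write a tree with no leaves")
    if len(lvs) == 1:
        return f"{lvs[0]};"
    if len(lvs) == 2:
        return f"({lvs[0]},{lvs[1]});"
    root = next(iter(t.neighbors(t.node_of(lvs[0]))))

    def emit(v: int, parent: int) -> tuple[str, str]:
        lbl = t.label_of(v)
        if lbl is not None:
            return lbl, lbl
        parts = [emit(u, v) for u in t.neighbors(v) if u != parent]
        parts.sort(key=lambda p: p[1])
        return "(" + ",".join(p[0] for p in parts) + ")", min(p[1] for p in parts)

    parts = [emit(u, root) for u in t.neighbors(root)]
    parts.sort(key=lambda p: p[1])
    return "(" + ",".join(p[0] for p in parts) + ");"


# ---------------------------------------------------------------------------
# Bipartitions of a tree, restriction
# ---------------------------------------------------------------------------


def edge_bipartitions(t: PhyloTree) -> dict[frozenset[int], Bipartition]:
    """Map every edge {u, v} to the bipartition it induces."""
    universe = t.leaves
    if len(universe) < 2:
        raise PhyloError("bipartitions require at least 2 leaves")
    root = t.node_of(min(universe))
    # iterative post-order accumulation of descendant label sets
    desc: dict[tuple[int, int], frozenset[str]] = {}
    order: list[tuple[int, int | None]] = []
    stack: list[tuple[int, int | None]] = [(root, None)]
    while stack:
        v, par = stack.pop()
        order.append((v, par))
        for u in t.neighbors(v):
            if u != par:
                stack.append((u, v))
    out: dict[frozenset[int], Bipartition] = {}
    for v, par in reversed(order):
        lbl = t.label_of(v)
        acc = {lbl} if lbl is not None else set()
        for u in t.neighbors(v):
            if u != par:
                acc |= desc[(v, u)]
        desc_set = frozenset(acc)
        if par is not None:
            desc[(par, v)] = desc_set
            other = universe - desc_set
            if desc_set and other:
                out[frozenset((par, v))] = Bipartition.of(desc_set, other)
    return out


def bipartitions(t: PhyloTree, nontrivial_only: bool = False) -> frozenset[Bipartition]:
    """The split set C(T): one bipartition per edge.

    With ``nontrivial_only`` the pendant-edge (trivial) splits are
    excluded.
    """
    out = edge_bipartitions(t).values()
    if nontrivial_only:
        return frozenset(p for p in out if not p.is_trivial)
    return frozenset(out)


def restrict(t: PhyloTree, r: Iterable[str]) -> PhyloTree:
    """The homeomorphic subtree induced by the label set ``r``.

    Minimal spanning subtree of ``r`` with all degree-2 vertices
    suppressed; node ids of retained vertices are preserved.  Satisfies
    C(t|_r) = {pi|_r : pi in C(t), both sides meet r}.
    """
    fr = frozenset(r)
    if not fr:
        raise PhyloError("cannot restrict to an empty label set")
    missing = fr - t.leaves
    if missing:
        raise PhyloError(f"labels not in tree: {sorted(missing)}")
    nt = t.copy()
    # strip leaves (and unlabelled tips) outside r, cascading inward
    pending = [v for v in nt.nodes if nt.degree(v) <= 1 and nt.label_of(v) not in fr]
    while pending:
        v = pending.pop()
        if v not in nt._adj:
            continue
        nbs = list(nt.neighbors(v))
        nt.remove_node(v)
        for u in nbs:
            if nt.degree(u) <= 1 and nt.label_of(u) not in fr:
                pending.append(u)
    nt.suppress_degree_two()
    return nt


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def _restricted_split_sets(
    t1: PhyloTree, t2: PhyloTree
) -> tuple[frozenset[Bipartition], frozenset[Bipartition], frozenset[str]]:
    x = t1.leaves & t2.leaves
    if not x:
        raise PhyloError("trees share no leaves")
    if len(x) < 2:
        return frozenset(), frozenset(), x
    c1 = bipartitions(restrict(t1, x))
    c2 = bipartitions(restrict(t2, x))
    return c1, c2, x


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance on the shared leaf set (all splits counted)."""
    c1, c2, _ = _restricted_split_sets(t1, t2)
    return len(c1 ^ c2)


def sf_support(t1: PhyloTree, t2: PhyloTree) -> int:
    """Split support |C(t1|_X) ∩ C(t2|_X)|, trivial splits included."""
    c1, c2, _ = _restricted_split_sets(t1, t2)
    return len(c1 & c2)


@dataclass(frozen=True)
class Profile:
    """An ordered collection of source trees; the universe is the leaf union."""

    trees: tuple[PhyloTree, ...]

    def __post_init__(self) -> None:
        if not self.trees:
            raise PhyloError("a profile needs at least one tree")

    @property
    def universe(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for t in self.trees:
            out |= t.leaves
        return out


@dataclass(frozen=True)
class ScoreReport:
    """Per-source and total RF / SF / false-negative scores of a supertree."""

    per_tree: tuple[tuple[int, int, int], ...]  # (rf, sf, fn) per source tree

    @property
    def rf_total(self) -> int:
        return sum(r for r, _, _ in self.per_tree)

    @property
    def sf_total(self) -> int:
        return sum(s for _, s, _ in self.per_tree)

    @property
    def fn_total(self) -> int:
        return sum(f for _, _, f in self.per_tree)


def profile_scores(t: PhyloTree, a: Profile) -> ScoreReport:
    """Score a supertree against every source tree in the profile.

    For each source tree T_i with leaf set S_i the supertree is restricted
    to S_i; rf/sf are computed on that common leaf set and fn counts the
    source splits absent from the restriction.
    """
    rows: list[tuple[int, int, int]] = []
    for ti in a.trees:
        si = ti.leaves
        missing = si - t.leaves
        if missing:
            raise PhyloError(
                f"supertree is missing source-tree leaf {sorted(missing)[0]!r}"
            )
        if len(si) < 2:
            rows.append((0, 0, 0))
            continue
        ct = bipartitions(restrict(t, si))
        ci = bipartitions(ti)
        rows.append((len(ct ^ ci), len(ct & ci), len(ci - ct)))
    return ScoreReport(tuple(rows))
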