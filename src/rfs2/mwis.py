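"""Weighted incompatibility graph of the two backbone trees, and its MWIS.

One vertex per bipartition *occurrence*: a split present in both
backbones produces two vertices, each weighted by its own path length
w(e_i(pi)).  Edges join incompatible splits; since all splits of one
tree are mutually compatible, the graph is bipartite by source index.

The maximum-weight independent set of a bipartite graph is found
exactly via the classic max-flow/min-cut reduction (König duality):
source -> T1-vertices with capacity = weight, T2-vertices -> sink with
capacity = weight, incompatibility edges with effectively infinite
capacity; the complement of the minimum vertex cover read off the
minimum cut is a maximum-weight independent set.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .decompose import SharedContext
from .treecore import Bipartition, PhyloError, are_compatible

__all__ = ["GraphVertex", "IncompatGraph", "build_graph", "max_weight_independent_set", "selected_splits"]


@dataclass(frozen=True)
class GraphVertex:
    bip: Bipartition
    source: int  # 1 or 2
    weight: int


@dataclass(frozen=True)
class IncompatGraph:
    vertices: tuple[GraphVertex, ...]
    edges: frozenset[frozenset[int]]  # pairs of vertex indices

    def neighbors(self, i: int) -> set[int]:
        out = set()
        for e in self.edges:
            if i in e:
                out |= e - {i}
        return out


def build_graph(ctx: SharedContext) -> IncompatGraph:
    """The weighted incompatibility graph of T1|_X and T2|_X.

    Carries every split of both backbones, trivial ones included (they
    are compatible with everything, hence isolated and always selected).
    """
    vertices: list[GraphVertex] = []
    for i in (1, 2):
        d = ctx.decomp(i)
        for p in sorted(d.splits, key=Bipartition.sort_key):
            vertices.append(GraphVertex(p, i, d.weight[d.edge_of[p]]))
    edges: set[frozenset[int]] = set()
    for a, va in enumerate(vertices):
        for b in range(a + 1, len(vertices)):
            vb = vertices[b]
            if va.source != vb.source and not are_compatible(va.bip, vb.bip):
                edges.add(frozenset((a, b)))
    return IncompatGraph(tuple(vertices), frozenset(edges))


def _check_bipartite(g: IncompatGraph) -> None:
    for e in g.edges:
        a, b = tuple(e)
        if g.vertices[a].source == g.vertices[b].source:
            raise PhyloError(
                "incompatibility graph is not bipartite by source index: "
                f"edge within source {g.vertices[a].source}"
            )


def max_weight_independent_set(g: IncompatGraph) -> frozenset[int]:
    """Vertex ids of a maximum-weight independent set, via min-cut.

    Deterministic: the flow network is built in canonical vertex order.
    All isolated vertices are always included.
    """
    _check_bipartite(g)
    n = len(g.vertices)
    if not g.edges:
        return frozenset(range(n))
    big = sum(v.weight for v in g.vertices) + 1
    net = nx.DiGraph()
    s, t = "s", "t"
    for i, v in enumerate(g.vertices):
        if v.source == 1:
            net.add_edge(s, i, capacity=v.weight)
        else:
            net.add_edge(i, t, capacity=v.weight)
    for e in sorted(g.edges, key=sorted):
        a, b = sorted(e)
        u1, u2 = (a, b) if g.vertices[a].source == 1 else (b, a)
        net.add_edge(u1, u2, capacity=big)
    cut_value, (reach, _) = nx.minimum_cut(net, s, t)
    cover = {
        i
        for i in range(n)
        if (g.vertices[i].source == 1 and i not in reach)
        or (g.vertices[i].source == 2 and i in reach)
    }
    independent = frozenset(range(n)) - cover
    # sanity: König duality — IS weight = total - cut
    total = sum(v.weight for v in g.vertices)
    assert sum(g.vertices[i].weight for i in independent) == total - cut_value
    return independent


def selected_splits(g: IncompatGraph, ids) -> frozenset[Bipartition]:
    """De-duplicated bipartitions of an independent vertex set."""
    fid = frozenset(ids)
    for e in g.edges:
        if e <= fid:
            a, b = tuple(e)
            raise PhyloError(f"vertex ids {a} and {b} are not independent")
    return frozenset(g.vertices[i].bip for i in fid)
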