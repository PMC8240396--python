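"""Brute-force reference implementations.

These are deliberately naive: exhaustive enumeration of unrooted binary
topologies, exhaustive supertree search under the RF / split-support
criteria, and exhaustive maximum-weight independent set.  They exist to
certify the polynomial-time algorithm on small instances, so they are
kept independent of the decomposition / merge machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .treecore import (
    Bipartition,
    PhyloError,
    PhyloTree,
    Profile,
    bipartitions,
    write_newick,
)

__all__ = [
    "enumerate_binary_trees",
    "brute_force_supertree",
    "brute_force_mwis",
    "BruteForceResult",
]

_MAX_ENUM = 9  # (2n-5)!! growth: n=9 already gives 135,135 topologies
_MAX_MWIS = 20


def enumerate_binary_trees(labels) -> Iterator[PhyloTree]:
    """Yield every unrooted binary topology on ``labels`` exactly once.

    Stepwise leaf insertion in sorted label order: the tree on the first
    three labels is unique, and each further leaf is attached on every
    edge of every partial tree.  Emits (2n-5)!! trees deterministically.
    """
    lab = sorted(set(labels))
    n = len(lab)
    if not (3 <= n <= _MAX_ENUM):
        raise PhyloError(f"enumeration supports 3..{_MAX_ENUM} labels, got {n}")
    base = PhyloTree()
    c = base.new_node()
    for l in lab[:3]:
        base.add_edge(c, base.new_node(l))

    def grow(t: PhyloTree, idx: int) -> Iterator[PhyloTree]:
        if idx == n:
            yield t
            return
        for (u, v) in t.edges:
            t2 = t.copy()
            w = t2.subdivide(u, v)
            t2.add_edge(w, t2.new_node(lab[idx]))
            yield from grow(t2, idx + 1)

    yield from grow(base, 3)


@dataclass(frozen=True)
class BruteForceResult:
    min_rf: int
    max_sf: int
    argmin: tuple[str, ...]  # canonical Newick of every RF-optimal tree
    argmax: tuple[str, ...]  # canonical Newick of every SF-optimal tree


def _restricted(splits: frozenset[Bipartition], si: frozenset[str]) -> frozenset[Bipartition]:
    out = set()
    for p in splits:
        r = p.restrict(si)
        if r is not None:
            out.add(r)
    return frozenset(out)


def brute_force_supertree(profile: Profile) -> BruteForceResult:
    """Exact RF-minimal (and SF-maximal) binary supertrees by enumeration.

    Scores every binary topology on the profile's leaf union; candidate
    restrictions are computed by restricting the candidate's splits to
    each source leaf set (the split-set characterisation of homeomorphic
    restriction).  Asserts that the RF-argmin and SF-argmax tree sets
    coincide, which must hold for binary supertrees.
    """
    s = profile.universe
    if len(s) > _MAX_ENUM:
        raise PhyloError(f"leaf union too large for enumeration: {len(s)}")
    sources = [(ti.leaves, bipartitions(ti)) for ti in profile.trees]
    best_rf: int | None = None
    best_sf: int | None = None
    argmin: list[str] = []
    argmax: list[str] = []
    for cand in enumerate_binary_trees(s):
        cs = bipartitions(cand)
        rf = sf = 0
        for si, ci in sources:
            cres = _restricted(cs, si)
            rf += len(cres ^ ci)
            sf += len(cres & ci)
        if best_rf is None or rf < best_rf:
            best_rf, argmin = rf, [write_newick(cand)]
        elif rf == best_rf:
            argmin.append(write_newick(cand))
        if best_sf is None or sf > best_sf:
            best_sf, argmax = sf, [write_newick(cand)]
        elif sf == best_sf:
            argmax.append(write_newick(cand))
    assert set(argmin) == set(argmax), (
        "RF-argmin and SF-argmax differ on a binary enumeration: "
        "this contradicts the RF/SF duality"
    )
    assert best_rf is not None and best_sf is not None
    return BruteForceResult(best_rf, best_sf, tuple(argmin), tuple(argmax))


def brute_force_mwis(g) -> int:
    """Maximum weight over all independent sets, by bitmask search.

    Accepts any graph shaped like :class:`rfs2.mwis.IncompatGraph`
    (``vertices`` with ``weight`` attributes and ``edges`` as id pairs).
    """
    n = len(g.vertices)
    if n > _MAX_MWIS:
        raise PhyloError(f"too many vertices for exhaustive MWIS: {n}")
    adj = [0] * n
    for e in g.edges:
        u, v = sorted(e)
        adj[u] |= 1 << v
        adj[v] |= 1 << u
    weights = [vx.weight for vx in g.vertices]

    best = 0

    def rec(i: int, taken_mask: int, w: int, remaining: int) -> None:
        nonlocal best
        if w + remaining <= best:
            return
        if i == n:
            best = max(best, w)
            return
        rec(i + 1, taken_mask, w, remaining - weights[i])
        if not (adj[i] & taken_mask):
            rec(i + 1, taken_mask | (1 << i), w + weights[i], remaining - weights[i])

    rec(0, 0, 0, sum(weights))
    return best
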