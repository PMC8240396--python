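# Methods

## Scope and model

The package solves the two-tree Robinson-Foulds supertree problem
exactly: given unrooted **binary** trees `T₁, T₂` on leaf sets
`S₁, S₂` with `X = S₁ ∩ S₂ ≠ ∅`, find a binary tree on `S = S₁ ∪ S₂`
minimizing `RF(T,T₁) + RF(T,T₂)`, where RF between trees with
different leaf sets is computed after restricting both to the shared
leaves.  All distances are purely topological: branch lengths and
internal node labels are parsed and discarded.  Because
`RF + 2·SF` is constant over binary supertrees, the implementation
maximizes the total split support SF; the relaxed (non-binary) SF
optimum is available via `relax=True`.

For three or more source trees the problem is NP-hard; the package
deliberately offers only scoring (`profile_scores`) and brute-force
search (`oracle`) for that case, not heuristics.

## Conventions and degenerate inputs

* **Unrooted representation.**  Rooted Newick input is unrooted by
  suppressing the artificial degree-2 root.  Output Newick is written
  rooted at the internal vertex adjacent to the smallest leaf label,
  children ordered by smallest descendant label, making the writer a
  canonical form (a fixed point under re-parsing).
* **Bipartitions** are stored canonically (the side containing the
  smallest label first), so split sets hash and compare
  deterministically across the whole package.
* **Small shared leaf sets.**  For `|X| < 3` the restrictions of both
  trees to `X` carry no conflicting structure; `rf_distance` returns 0
  and `sf_support` the honest count of shared splits of the
  restrictions (1 for `|X| = 2`, 0 for a single shared leaf).  The
  supertree entry point accepts any `|X| ≥ 1`: with at most three
  shared leaves there are no non-trivial backbone splits, so the
  incompatibility-graph phase is skipped and the initial tree plus the
  trivial-split phase (followed by seeded binary resolution) is
  already optimal — for compatible inputs this reconstructs each
  source exactly (total RF 0).
* **Multifurcating trees** are accepted by all scoring functions
  (scores are well defined for them); binarity is enforced only by the
  `exact_rfs_2` entry point, which names an offending vertex.

## The algorithm, as implemented

*Pre-processing* (`decompose`).  The Steiner subtree of `X` in each
source is computed by iteratively pruning non-shared leaves; its
branch vertices and `X`-leaves survive as backbone vertices, and each
maximal Steiner path becomes a backbone edge `e` with `path P(e)`,
weight `w(e) = |P(e)|`, oriented from the canonical first side of its
split.  Components of the source minus the Steiner subtree are the
extra subtrees; each records its root, label set and attachment
(internal path vertex ⇒ member of `TR(e)`, in path position order;
backbone vertex ⇒ vertex-attached, possible only for multifurcating
sources and treated as unconstrained downstream).  From the two
decompositions the context derives the trivial/non-trivial split
classes of `C(T₁|X) ∪ C(T₂|X)`, the per-source split classes Π₁/Π₂
(both sides meet `X` vs. not), the potential
`w*(π) ∈ {0, w(e₁), w(e₂), w(e₁)+w(e₂)}`, and the score decomposition
`p₁ + p₂ = SF`.

*Initial tree and trivial phase* (`merge`).  `T_init` is the star over
`X` plus all extra subtrees grafted at the centre; it attains
`p₂ = |Π₂|`, the maximum possible.  Each trivial split `[{x}|X−x]`
with attached extras is realised by threading its `TR*` extras onto
`x`'s pendant edge, closest-to-`x` first, source 1 before source 2
(each source in its own path order; the paper's argument fixes the
per-source order but not the interleaving, and we do not interleave).
After this phase `p₁ = w*(Triv)`.

*Split selection* (`mwis`).  One graph vertex per split occurrence
(shared splits appear twice, each with its own weight), edges between
incompatible occurrences.  The graph is bipartite by source index, so
the maximum-weight independent set is exact via max-flow/min-cut
(source → tree-1 vertices and tree-2 vertices → sink with capacities
equal to the weights; incompatibility edges with capacity exceeding
the total weight; the complement of the min vertex cover read off the
cut).  The flow network is built in canonical vertex order, so results
are reproducible; any optimum would be equally correct, since only the
selected weight matters for the score.

*Refinement.*  Non-trivial selected splits are applied in canonical
sorted order (a seeded override exists purely to exercise order
invariance).  Applying `π = [A|B]` splits the tracked vertex `sv(π)`
into `v_a—v_b`, routes neighbors by which side of `π` their `X`-leaves
lie on, threads the `TR*(π)` extras onto the new edge in path order
(source 1 first), sends `TRS(A)` extras to `v_a`, `TRS(B)` to `v_b`,
and unconstrained extras to `v_a` (any choice preserves the
invariants; a fixed choice aids testing).  Pending splits at the old
vertex are reassigned to `v_a`/`v_b` by strict side containment or
discarded if incompatible with `π`.  Each application raises `p₁` by
exactly `w*(π)` and leaves `p₂` unchanged, giving
`p₁(T*) = w*(I)` — the optimum.

*Resolution.*  Remaining multifurcations are resolved by repeatedly
pairing two branches chosen by a seeded RNG over canonically ordered
branches; deterministic per seed, never decreasing SF.

### A nuance in the per-step restriction identity

One may expect a refinement step to satisfy
`C(T'|Sᵢ) = C(T|Sᵢ) ∪ {π' ∈ C(Tᵢ) : π'|X = π}` for both sources.  This
holds exactly for every source whose backbone contains `π`.  For a
source whose backbone does *not* contain `π`, an extra subtree of that
source can be unconstrained (its path's split is incompatible with
`π`); wherever it is attached, the new edge induces one additional
split in that source's restriction that projects to `π` but matches no
source split.  This surplus split contributes nothing to `p₁`/`p₂`
(and disappears into the fixed split budget of the final binary tree),
so the score guarantees and optimality are unaffected.  The test suite
asserts the exact identity where it holds and the guaranteed
superset-plus-projection property otherwise.

## Synthetic data

`fixtures.random_binary_tree` draws uniformly over unrooted binary
topologies by sequential leaf insertion on a uniformly random edge.
`fixtures.overlapping_pair` emulates the package's target setting: two
binary source trees obtained by restricting a common model tree to the
shared set plus disjoint private leaf samples, with disagreement
introduced by unrooted SPR moves on the second tree, each accepted
only if it changes the restriction to the shared set (so requested
disagreement always reaches the shared backbone rather than being
absorbed by private leaves).  With zero moves the pair is compatible
and the optimal score is 0.

What the generator does *not* emulate: estimation error correlated
with branch lengths, rogue taxa, multifurcating sources, or
non-uniform taxon sampling.  Passing tests therefore certify the
combinatorial optimality machinery, not robustness of any estimation
pipeline built on top of it.

Deterministic in-literature fixtures: the worked two-tree example with
optimum 2, and the `n`-leaf single-internal-edge profile whose star
and caterpillar supertrees have closed-form scores
(`RF(star) = n−3`, `SF(star) = (n−3)n`, `SF(caterpillar) = (n−3)(n+1)`,
`RF(caterpillar) = (n−4)(n−3)`), exhibiting that the relaxed RF and
relaxed SF optima can differ.

## Divide-and-conquer module

`decompose_by_edge` deletes an internal guide edge and its endpoints,
and collects from each of the four resulting subtrees the `p` leaves
topologically nearest to the edge, including all ties; the two
overlapping subsets are `A ∪ P` and `B ∪ P`.  The default edge choice
is a most-balanced internal edge (the criterion is a free parameter;
any rule works, balance keeps subsets comparable).  `short_quartets`
enumerates, per internal edge, every combination of one nearest leaf
per subtree with its induced 2|2 topology; when every short quartet of
a model tree lies inside one subset, the model is the unique
compatibility supertree of its two restrictions and the merge returns
it exactly — the property test and the pipeline acceptance test check
precisely this conditional.  A single decomposition level is
implemented; recursion is out of scope.

## Test and certification sizes

Oracle-backed tests enumerate all binary topologies, which grows as
`(2n−5)!!`; the suite therefore certifies optimality exhaustively on
unions of up to 7 leaves (200 seeded instances; 945 topologies each)
and on the 8-label worked example (10,395 topologies), sizes at which
enumeration is still a few seconds of work.  Structural invariants
(per-step `Δp₁ = w*`, the `H`/`sv` bookkeeping, extra-subtree
side-placement) are asserted after every refinement step on 100 seeded
10-leaf fixtures via `check_invariants=True`.  MWIS is validated
against exhaustive search on 500 random bipartite graphs (≤ 16
vertices) and the selected-set optimality over *all* compatible split
subsets exhaustively for `|X| ≤ 6`.  The divide-and-conquer recovery
guarantee is exercised on 100 random models of 10–20 leaves with
`p = 2`.  The empirical `O(n²|X|)` behaviour is visible at these sizes
but is not asserted as a test (wall-clock assertions are flaky by
nature).

## Known limitations

* Exact optimization only for `N = 2` source trees (NP-hard beyond).
* Topology-only: no weighted-RF or branch-length-aware variant.
* The brute-force oracles are guarded to ≤ 9 labels / ≤ 20 graph
  vertices by design.
* When several optimal supertrees exist, the algorithm returns one,
  deterministically; no enumeration of co-optima outside the oracle.
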