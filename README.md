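# rfs2 — exact Robinson-Foulds supertrees of two binary trees

`rfs2` computes an **optimal Robinson-Foulds supertree of two unrooted
binary trees with overlapping leaf sets**, exactly and in polynomial
time, together with the machinery needed to certify it and to use it
inside divide-and-conquer phylogeny estimation.

It is aimed at people building large phylogenies by
divide-and-conquer: a taxon set is split into two overlapping subsets,
trees are estimated on each subset, and the subset trees are merged
into one tree on all taxa.  The merge step is a supertree problem, and
the Robinson-Foulds supertree (RFS) criterion — minimize the total RF
distance from the supertree to the source trees — is one of the main
criteria in use.  RFS is NP-hard for three or more source trees, but
for exactly two binary trees it admits an exact `O(n²|X|)` algorithm
(`n` = leaves per tree, `X` = shared leaf set), which this package
implements.

## The problem and the algorithm

For trees `T, T'` on a shared leaf set, `C(T)` is the set of
bipartitions (splits) induced by the edges of `T`, and

    RF(T, T') = |C(T) \ C(T')| + |C(T') \ C(T)|
    SF(T, T') = |C(T) ∩ C(T')|

with trees on different leaf sets first restricted to their shared
leaves.  Over binary supertrees `T` of a profile `{T₁, …, T_N}`,
`RF(T, ·) + 2·SF(T, ·)` is a constant, so minimizing the total RF
distance and maximizing the total split support (SF) are the same
problem.

For two binary sources `T₁, T₂` with shared leaves `X = S₁ ∩ S₂`, the
exact algorithm works on the *backbone trees* `Tᵢ|X`:

1. Each backbone edge `e` corresponds to a path `P(e)` in the source
   tree, with weight `w(e) = |P(e)|`; the components of `Tᵢ − Tᵢ|X`
   are rooted *extra subtrees* attached along those paths.
2. Start from `T_init`: a star whose centre is adjacent to every shared
   leaf and every extra-subtree root.  `T_init` already realises every
   source split with a side disjoint from `X` (the Π₂ splits).
3. Build the **weighted incompatibility graph** of the two backbones
   (one vertex per split occurrence, weight `w(e)`, edges between
   incompatible splits — bipartite, because splits of one tree are
   mutually compatible) and take a **maximum-weight independent set**
   via the max-flow/min-cut reduction.  The selected splits `I` form
   the best compatible set of backbone splits, weighted by how many
   source edges project onto each (`w*`).
4. Insert each selected split into the growing supertree by splitting
   one vertex, re-homing the extra subtrees along the new edge in
   source path order; every insertion of `π` raises the realised
   support by exactly `w*(π)`.  Finally resolve multifurcations
   arbitrarily (deterministically, seeded) — refinement never loses
   support.

A brute-force module (exhaustive enumeration of all `(2n−5)!!` binary
topologies) certifies optimality on small instances, and a
divide-and-conquer module (`dactal`) performs guide-tree edge
decomposition with tie-inclusive nearest leaves, short-quartet
computation, and the two-subset merge.

## Worked example

The library ships the published worked example as a fixture: two
source trees on overlapping leaf sets

```
T1 = (A,(B,x),((C,y),(D,E)));        leaves {A,B,C,D,E,x,y}
T2 = (A,((B,(D,E)),z),C);            leaves {A,B,C,D,E,z}
```

```
$ rfs2 fixtures --preset lemma4 --out demo/
$ rfs2 merge demo/T1.nwk demo/T2.nwk --report report.tsv
(A,(((B,x),(D,E)),z),(C,y));
$ cat report.tsv
tree_index	rf	sf	fn
1	2	10	1
2	0	9	0
total	2	19	1
```

The merged supertree spans all 8 labels and has total RF distance 2 to
the pair (2 to `T1`, 0 to `T2`) — `T1` and `T2` genuinely conflict, so
0 is impossible, and 2 is optimal.  The exhaustive oracle confirms it,
enumerating all 10,395 binary topologies on the 8-label union:

```
$ rfs2 oracle demo/T1.nwk demo/T2.nwk
min_rf	2
max_sf	19
optima	1
```

Equivalent library calls:

```python
from rfs2 import lemma4_trees, exact_rfs_2, write_newick

t1, t2, _ = lemma4_trees()
tree, report = exact_rfs_2(t1, t2)
print(write_newick(tree), report.rf_total)   # ... 2
```

Other subcommands: `rfs2 score` (TSV score report of any supertree
against source trees), `rfs2 dactal` (guide-tree decomposition and
two-subset merge), `rfs2 fixtures` (seeded synthetic inputs),
`rfs2 dump-decomposition` / `rfs2 dump-graph` (introspection tables).

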