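# Methods

## Model and problem

A multi-labeled tree is a rooted unordered tree `T = (V, E)` with root `r`;
every vertex `v ≠ r` carries a label set `L_v ⊆ 𝕃` and label sets of
distinct vertices are disjoint. `L(T)` is the union of all label sets. In
the tumor-phylogeny reading, labels are mutations, vertices are clones, the
root is the healthy-cell population, and disjointness encodes the infinite
sites assumption; labels known to violate it must be removed before
comparison.

Three edit operations define the measure: label deletion, unlabeled-leaf
deletion, and vertex expansion (split `L_v` over a new parent–child pair;
children follow the lower vertex). A common tree of `T1` and `T2` is
obtainable from both; the dissimilarity is

    MLTD(T1, T2) = |L(T1)| + |L(T2)| − 2·g,   g = labels in a maximum common tree,

i.e. the number of label deletions an optimal edit sequence performs, and
the similarity `MLTD-normalized = g / max(|L(T1)|, |L(T2)|)` lies in
[0, 1]. Expansion and leaf deletion are free: granularity differences cost
nothing, while placing mutations on different lineages does.

All algorithms run on *root-normalized* trees (`normalize_root` prepends a
fresh label-free root when the root is labeled — the healthy-cell vertex
that figures conventionally omit). `to_clonal` canonicalizes a general
multi-labeled tree by merging label-free non-root vertices upward and then
normalizing the root.

## Set alignment

For two downward paths with label sequences `S_1..S_n` and `P_1..P_m`, the
largest label set retainable on a common path is the generalized LCS

    D(i, j) = max(D(i, j−1), D(i−1, j)) + |S_i ∩ P_j|,   D(i, 0) = D(0, j) = 0.

The retained set must have *weakly compatible* positions: no pair with
`f(a) < f(b)` and `g(b) < g(a)` (`f`, `g` = positions in the two
sequences). Ties are allowed in either coordinate — two labels sharing a
vertex on one side may appear in any order on the other, because an
expansion can split them either way. This is the semantics the defining
examples force (a two-label path aligns fully with its one-vertex
coarsening); a strict if-and-only-if reading of order compatibility would
contradict them. The DP is checked against an exhaustive subset search on
random instances and reduces to the classical LCS when all sets are
singletons.

Intersection sizes are counted in one pass over the shared-label index
(time `O(Σ|S_i| + Σ|P_j| + nm)`), never by pairwise set intersection. The
witness traceback prefers the `D(i−1, j)` branch on ties, making the
retained set deterministic; only the *size* is canonical.

## Path-alignment index

`D(a, c, b, d)` — the alignment of paths `a..b` and `c..d` (`a ⪯ b`,
`c ⪯ d`) — is filled for all ancestor-consistent quadruples in one sweep by
increasing depth of the bottoms, reusing `(p(b), d)` and `(b, p(d))`
entries. Storage is a hash map keyed `(top1, top2, bottom1, bottom2)`;
only valid quadruples exist, bounded by `|V1||V2|·h1·h2` for tree heights
`h1`, `h2`. Label-free tops (e.g. the normalized root) need no special
case: they contribute empty intersections.

## Maximum common tree

For subtrees rooted at `a ∈ V1`, `b ∈ V2`:

* `G'(a, b)`: best score with the labels of `a`, `b` themselves excluded —
  a maximum-weight bipartite matching between the children of `a` and `b`
  with edge weights `G(child_i, child_j)`; 0 if either vertex is a leaf.
* `G(a, b) = max over x ⪰ a, y ⪰ b within the subtrees of
  G'(x, y) + D(a, b, x, y)`.

Both tables are filled in lockstep over post-order vertex pairs, so every
needed entry exists when read; the loops are iterative (no recursion), so
mutation-tree chains of hundreds of vertices pose no depth problem. The
answer is `G(root1, root2)`. The `(x, y)` maximization is free; the
"minimal depth" phrasing of the optimal split is a property of optima, not
an extra constraint — the exhaustive oracle suite (below) found no
discrepancy under this reading.

The maximization deliberately includes the roots: the common tree's top
branch point may correspond to the (label-free) root of one tree and an
internal vertex of the other, which is equivalent to allowing expansion of
the healthy-cell root. The exhaustive oracle enumerates root-inclusive
mappings for the same reason.

The matching is solved exactly with `scipy.optimize.linear_sum_assignment`;
with non-negative integer weights the optimal full assignment of the
smaller side equals the optimal partial bijection, and zero-weight pairs
are dropped from the reported matching. Among equally optimal matchings
scipy's deterministic choice is returned (the value is unique; the witness
is not).

Complexity as implemented: building the index costs one dictionary write
per valid quadruple; the `G` loop costs `O(Σ_a |sub(a)| · Σ_b |sub(b)|)`
dictionary reads plus one assignment solve per vertex pair. This favors
clarity over the tightest published bound and is instant at the problem
sizes the package targets (tens of mutations per tree).

## Witness reconstruction

The traceback walks the optimal `(x, y)` choices and child matchings
top-down. Each matched pair contributes its path segment's set-alignment
witness: retained labels are grouped by their (position-in-`T1`,
position-in-`T2`) pair — groups are totally ordered because the witness is
inversion-free — and emitted as a chain of multi-label vertices. A
label-free *anchor* vertex is created only when a branch point retains no
labels of its own and has two or more matched child branches.

The witness is then simplified by merging label-free non-root vertices into
their parents, but only when the merge is reversible by a single vertex
expansion: the vertex has at most one child, or is its parent's only child.
Merging a label-free branching vertex that has siblings would collapse two
distinct branch points and can strictly reduce the witness's common-tree
score against the inputs (a three-label counterexample exists), so such
vertices are kept. For clonal inputs the result is clonal.

The contract is self-verifying and tested: the witness `W` satisfies
`max_common_tree_size(W, T_i) = |L(W)| = max_common_tree_size(T1, T2)` for
both inputs.

## Exhaustive oracle

`oracle_common_size` provides independent ground truth for trees of at most
7 vertices. It enumerates every partial injection `M` between the two
vertex sets (roots included) that is closed under lowest common ancestors
and commutes with lca — these two conditions imply that `M` preserves the
ancestor order — and scores each mapping by summing set alignments over the
maximal path segments between consecutive matched vertices. Mappings, not
edit sequences, are enumerated: edit sequences are unbounded, while the
mapping determines the optimal common tree. The search is exponential and
guarded; the polynomial DP is required to agree with it exactly on 200
seeded random pairs in the acceptance suite.

## Synthetic data

`generate_tree(GeneratorConfig(...))` grows a tree vertex by vertex: with
probability `branching_bias` a new vertex attaches to a uniformly random
existing vertex, otherwise to the previously added one (0 yields paths,
1 star-like trees). Per-vertex label counts are uniform on
`[labels_min, labels_max]`, drawn without replacement from a shuffled
universe `M00..`; draws are clipped to the remaining universe and an error
is raised only when the configured minimum cannot be met. Two trees
generated over the same universe overlap in labels, which is what makes
random pairs informative. A single integer seed drives all draws; no
global random state is touched.

The generator emulates only the combinatorics of clonal trees — topology,
granularity, shared label content. It does not model subclone fractions,
sequencing noise, read depth, or mutation-rate heterogeneity, so passing
tests certify the correctness of the measure, not the behavior of any
inference tool on real sequencing data.

`derive_pair` produces related pairs with a certified score lower bound:
both sides refine the same ancestor using one shared per-vertex label
order (drawn from the seed) so their expansions can never invert each
other, then delete at most `k` labels between them; the ancestor's refined
form minus the deleted labels is a common tree by construction. With fully
independent expansion orders the bound would be false — two sides splitting
`{A, B}` in opposite orders forfeit a label — which is why the order is
shared.

## Problem sizes and determinism

The acceptance-style property tests use 100 random clonal trees of up to 12
vertices and 4 labels per vertex (granularity invariance), 200 pairs of up
to 6 vertices and an 8-label universe (oracle agreement), and 100 pairs
each for path specialization and witness self-verification; the whole suite
runs in a few seconds. All randomness is seeded; serialization sorts
children by smallest contained label then vertex id, so every output is
byte-stable. Normalized scores are exact `Fraction`s in the library and are
formatted to four decimal places (banker's rounding) only at the CLI
boundary, so 3/10 prints as 0.3000.

## Known limitations

* MLTD is not a metric (no triangle inequality) — by design.
* The `G` maximization is quadratic in subtree sizes per vertex pair;
  trees with many thousands of vertices would need the tighter bookkeeping
  of the published bound.
* `reconstruct_common_tree` returns *one* maximum witness; the set of all
  optimal witnesses is not enumerated.
* Newick import/export is not provided: Newick cannot carry per-vertex
  label sets unambiguously without inventing a dialect.
* Labels private to one tree count in `|L(T)|` and therefore inflate MLTD
  and deflate the normalized similarity; no pre-filtering to the shared
  universe is performed, exactly as the defining formula dictates.
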