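# mltd — multi-labeled tree dissimilarity for clonal trees

`mltd` compares rooted **multi-labeled trees**: trees in which every
non-root vertex carries a set of labels and no label appears twice. The
motivating objects are *clonal trees* of tumor evolution, where each vertex
is a clone, each label is a somatic mutation assigned to the clone where it
first appears, and label uniqueness is the infinite sites assumption. Tools
that reconstruct such trees from bulk or single-cell sequencing data report
them at very different granularities — from coarse clonal trees to fully
resolved *mutation trees* with one mutation per vertex — so a useful
distance must see through granularity and compare evolutionary content.

## The measure

Three edit operations are allowed on a multi-labeled tree:

* **delete a label** from a vertex's label set;
* **delete an unlabeled leaf** (no labels, no children);
* **expand a vertex** `v` into a parent–child pair `v1 → v2`, partitioning
  `L_v` between them (children of `v` move to `v2`).

A **common tree** of `T1` and `T2` is any tree obtainable from both by such
operations; a **maximum common tree** retains the largest number of labels.
Writing `g` for that number and `a = |L(T1)|`, `b = |L(T2)|`:

```
MLTD(T1, T2)            = a + b − 2g          (a dissimilarity, in labels)
MLTD-normalized(T1, T2) = g / max(a, b)       (a similarity in [0, 1])
```

Vertex expansion is free, so a clonal tree is at distance 0 from every one
of its mutation-tree refinements. MLTD is not a metric: with `T1 = {A}`
above `{B}`, `T2 = {B}` above `{A}` and `T3` a single vertex `{A,B}`,
`MLTD(T1,T3) = MLTD(T2,T3) = 0` but `MLTD(T1,T2) = 2`.

The maximum common tree is computed in polynomial time by a post-order
dynamic program over vertex pairs: `G(a,b)` (best score for the subtrees at
`a` and `b`) interleaves with `G'(a,b)` (the same with the labels of `a`
and `b` excluded), where `G'` is a maximum-weight bipartite matching
between children and `G` maximizes `G'(x,y) + D(a,b,x,y)` over descendant
pairs, with `D` a precomputed table of generalized-LCS alignments between
all pairs of downward paths. See `docs/methods.md` for the details and the
numerical conventions.

## Worked example

A 10-mutation truth — driver `A`, then sibling clusters `{B..F}` and
`{G..J}` — against an inferred tree that keeps the clusters but chains them
linearly:

```text
$ cat true.tree                  $ cat inferred.tree
r	-	                 r	-	
a	r	A                a	r	A
c1	a	B,C,D,E,F        g1	a	B,C,D,E,F
c2	a	G,H,I,J          g2	g1	G,H,I,J

$ mltd score true.tree inferred.tree
labels in tree 1:     10
labels in tree 2:     10
common tree size:     6
MLTD:                 8
MLTD-normalized:      0.6000
```

The best common tree keeps `A` and the five-mutation cluster (6 labels):
the linear tree places `{G..J}` *below* `{B..F}`, while the truth puts them
on a different branch, so one cluster must be sacrificed. The similarity
0.6 rewards the shared backbone and penalizes the wrong lineage placement.
`--witness` writes that common tree out, `--json` emits the same report
machine-readably:

```text
$ mltd score --json --witness witness.tree true.tree inferred.tree
{"common_size": 6, "labels_t1": 10, "labels_t2": 10, "mltd": 8, "mltd_normalized": "0.6000"}
$ cat witness.tree
w0	-	
w1	w0	A
w2	w1	B,C,D,E,F
```

`mltd convert --to-mutation-tree/--to-clonal` switches granularities and
`mltd fixtures` emits seeded random clonal trees for experiments.

### Tree file format

One vertex per line: `vertex_id<TAB>parent_id<TAB>comma-separated-labels`;
the root uses parent id `-`; the label field may be empty; `#` starts a
comment line.

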