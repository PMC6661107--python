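"""Maximum common tree, MLTD dissimilarity and MLTD-normalized similarity.

The measure is defined through three cost-free-structure edit operations on
multi-labeled trees: deleting a label, deleting an unlabeled leaf, and
expanding a vertex (splitting its label set over a new parent-child pair).
A *common tree* of T1 and T2 is obtainable from both by such operations; the
*maximum* common tree retains the most labels.  Then::

    MLTD(T1, T2)            = |L(T1)| + |L(T2)| - 2 * |maximum common tree|
    MLTD-normalized(T1, T2) = |maximum common tree| / max(|L(T1)|, |L(T2)|)

MLTD is a dissimilarity, not a metric (the triangle inequality fails, akin to
inverse set intersection).  MLTD-normalized is a similarity in [0, 1]; it is
1 between any clonal tree and any of its mutation-tree refinements.

The polynomial algorithm is a post-order dynamic program over vertex pairs.
``G(a, b)`` is the maximum common tree size of the subtrees rooted at ``a``
and ``b``; ``G'(a, b)`` is the same with the labels of ``a`` and ``b``
excluded, computed as a maximum-weight bipartite matching between their
children weighted by ``G``.  The two interleave through the downward-path
alignment index ``D``::

    G(a, b) = max over x in subtree(a), y in subtree(b) of
              G'(x, y) + D(a, b, x, y)

A witness common tree is rebuilt by tracing the optimal ``(x, y)`` choices
and matchings top-down and placing each path segment's retained labels with
the Set Alignment witness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping

import numpy as np
from scipy.optimize import linear_sum_assignment

from .path_alignment import PathAlignmentIndex, build_path_index, path_labels
from .set_alignment import align_sets
from .tree_model import MultiLabeledTree, TreeError, normalize_root

__all__ = [
    "MatchingProblem",
    "ScoreTables",
    "CommonTreeResult",
    "max_weight_matching",
    "compute_score_tables",
    "max_common_tree_size",
    "mltd",
    "mltd_normalized",
    "reconstruct_common_tree",
]


@dataclass(frozen=True)
class MatchingProblem:
    """Maximum-weight partial bijection between two child lists."""

    left: tuple[str, ...]
    right: tuple[str, ...]
    weight: Mapping[tuple[str, str], int]


def max_weight_matching(problem: MatchingProblem) -> tuple[int, frozenset[tuple[str, str]]]:
    """Optimal value and a witness matching; zero-weight pairs are omitted.

    With non-negative weights the optimal full assignment of the smaller side
    (Hungarian method via ``scipy.optimize.linear_sum_assignment``) attains
    the optimum over all partial bijections.
    """
    if not problem.left or not problem.right:
        return 0, frozenset()
    W = np.array(
        [[problem.weight.get((l, r), 0) for r in problem.right]
         for l in problem.left],
        dtype=np.int64,
    )
    rows, cols = linear_sum_assignment(W, maximize=True)
    value = int(W[rows, cols].sum())
    pairs = frozenset(
        (problem.left[i], problem.right[j])
        for i, j in zip(rows, cols) if W[i, j] > 0
    )
    return value, pairs


@dataclass(frozen=True)
class ScoreTables:
    """Per-vertex-pair DP values, plus the traceback metadata needed to
    reconstruct a witness common tree."""

    G: dict
    G_prime: dict
    best_pair: dict = field(repr=False)     # (a, b) -> argmax (x, y) of G(a, b)
    matching: dict = field(repr=False)      # (a, b) -> matched child pairs of G'(a, b)


def compute_score_tables(
    t1: MultiLabeledTree,
    t2: MultiLabeledTree,
    index: PathAlignmentIndex | None = None,
) -> ScoreTables:
    """Fill G and G' for all vertex pairs of two root-normalized trees in
    post-order, so children always precede their parents."""
    if index is None:
        index = build_path_index(t1, t2)
    D = index.D

    post1, post2 = t1.postorder(), t2.postorder()
    sub1 = _subtree_lists(t1, post1)
    sub2 = _subtree_lists(t2, post2)

    G: dict[tuple[str, str], int] = {}
    Gp: dict[tuple[str, str], int] = {}
    best: dict[tuple[str, str], tuple[str, str]] = {}
    match: dict[tuple[str, str], tuple[tuple[str, str], ...]] = {}

    for a in post1:
        ch_a = t1.children(a)
        suba = sub1[a]
        for b in post2:
            ch_b = t2.children(b)
            # G'(a, b): matching over children; 0 when a or b is a leaf
            if ch_a and ch_b:
                weight = {(x, y): G[(x, y)] for x in ch_a for y in ch_b}
                val, pairs = max_weight_matching(MatchingProblem(ch_a, ch_b, weight))
                Gp[(a, b)] = val
                match[(a, b)] = tuple(sorted(pairs))
            else:
                Gp[(a, b)] = 0
                match[(a, b)] = ()
            # G(a, b): best split point (x, y) in the subtree pair
            best_val = -1
            best_xy = (a, b)
            for x in suba:
                Dx = D
                for y in sub2[b]:
                    v = Gp[(x, y)] + Dx[(a, b, x, y)]
                    if v > best_val:
                        best_val = v
                        best_xy = (x, y)
            G[(a, b)] = best_val
            best[(a, b)] = best_xy
    return ScoreTables(G, Gp, best, match)


def _subtree_lists(tree: MultiLabeledTree, post: list[str]) -> dict[str, list[str]]:
    sub: dict[str, list[str]] = {}
    for v in post:
        acc: list[str] = []
        for c in tree.children(v):
            acc.extend(sub[c])
        acc.append(v)
        sub[v] = acc
    return sub


def max_common_tree_size(t1: MultiLabeledTree, t2: MultiLabeledTree) -> int:
    """Number of labels in a maximum common tree of ``t1`` and ``t2``."""
    n1, n2 = normalize_root(t1), normalize_root(t2)
    tables = compute_score_tables(n1, n2)
    return tables.G[(n1.root, n2.root)]


def mltd(t1: MultiLabeledTree, t2: MultiLabeledTree) -> int:
    """MLTD dissimilarity: labels deleted from the two trees on the way to
    their maximum common tree."""
    return t1.n_labels + t2.n_labels - 2 * max_common_tree_size(t1, t2)


def mltd_normalized(t1: MultiLabeledTree, t2: MultiLabeledTree) -> Fraction:
    """MLTD-normalized similarity in [0, 1]: maximum common tree size over
    the larger label count.  Exact rational; undefined when both trees are
    label-free."""
    a, b = t1.n_labels, t2.n_labels
    if max(a, b) == 0:
        raise TreeError("MLTD-normalized is undefined for two label-free trees")
    return Fraction(max_common_tree_size(t1, t2), max(a, b))


@dataclass(frozen=True)
class CommonTreeResult:
    """A maximum common tree together with the certificates of its score:
    the crucial-vertex correspondence and the retained label set."""

    size: int
    common_tree: MultiLabeledTree
    correspondence: dict    # matched vertex pairs, t1 vertex -> t2 vertex
    retained_labels: frozenset


def reconstruct_common_tree(t1: MultiLabeledTree, t2: MultiLabeledTree) -> CommonTreeResult:
    """Build a witness maximum common tree.

    Top-down over the optimal traceback: every matched pair contributes the
    Set Alignment witness of its path segment as a chain of label groups;
    matched child pairs of the segment bottom branch below it.  Unlabeled
    vertices are created only as branching anchors and merged afterwards
    whenever the merge is reversible by a single vertex expansion, so clonal
    inputs yield a clonal witness.
    """
    n1, n2 = normalize_root(t1), normalize_root(t2)
    tables = compute_score_tables(n1, n2)

    parent: dict[str, str] = {}
    labels: dict[str, set[str]] = {}
    counter = [0]

    def new_vertex(attach: str | None, labs: set[str]) -> str:
        vid = f"w{counter[0]}"
        counter[0] += 1
        if attach is not None:
            parent[vid] = attach
        labels[vid] = labs
        return vid

    w_root = new_vertex(None, set())
    correspondence: dict[str, str] = {n1.root: n2.root}
    retained_all: set[str] = set()

    # (a, b, attach): a/b are segment tops, attach is the witness vertex the
    # segment hangs from
    stack: list[tuple[str, str, str]] = [(n1.root, n2.root, w_root)]
    while stack:
        a, b, attach = stack.pop()
        x, y = tables.best_pair[(a, b)]
        correspondence[x] = y
        seq1 = path_labels(n1, a, x)
        seq2 = path_labels(n2, b, y)
        result = align_sets(seq1, seq2)
        retained_all |= result.retained

        groups: dict[tuple[int, int], set[str]] = {}
        for lab in result.retained:
            groups.setdefault((seq1.index_of(lab), seq2.index_of(lab)), set()).add(lab)
        last = attach
        for key in sorted(groups):
            last = new_vertex(last, groups[key])

        pairs = tables.matching[(x, y)]
        if pairs:
            if last is attach and len(pairs) > 1:
                # distinct branch point with no retained labels of its own
                last = new_vertex(attach, set())
            for ca, cb in pairs:
                stack.append((ca, cb, last))

    tree = MultiLabeledTree(w_root, parent, labels)
    tree = _merge_reversible(tree)
    size = tables.G[(n1.root, n2.root)]
    assert len(retained_all) == size
    return CommonTreeResult(size, tree, correspondence, frozenset(retained_all))


def _merge_reversible(tree: MultiLabeledTree) -> MultiLabeledTree:
    """Merge label-free non-root vertices into their parents when the merge
    can be undone by one vertex expansion: the vertex has at most one child,
    or it is its parent's only child.  (Merging an unlabeled branching vertex
    that has siblings would collapse two distinct branch points.)"""
    while True:
        victim = None
        for v in tree.preorder():
            if v == tree.root or tree.label_set(v):
                continue
            if len(tree.children(v)) <= 1 or len(tree.children(tree.parent(v))) == 1:
                victim = v
                break
        if victim is None:
            return tree
        p = tree.parent(victim)
        parent = {v: (p if tree.parent(v) == victim else tree.parent(v))
                  for v in tree.vertices if v not in (tree.root, victim)}
        labels = {v: tree.label_set(v) for v in tree.vertices if v != victim}
        tree = MultiLabeledTree(tree.root, parent, labels)
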