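"""Seeded synthetic tree generation, edit scripts, and an exhaustive
small-instance oracle for the maximum common tree size.

The generator emulates the shape of clonal trees only: random topologies with
tunable branching, and random disjoint label (mutation) sets per clone drawn
from a shared universe.  It does not model subclone fractions, sequencing
noise, or mutation rates — it exists to exercise the combinatorics, not to
simulate tumors.

The oracle enumerates every lca-consistent partial injection between the
vertex sets of two (small) trees and scores it by the induced path-segment
alignments; it is exponential and guarded, and serves as independent ground
truth for the polynomial algorithm.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Sequence

from .set_alignment import LabelSequence, align_sets
from .tree_model import MultiLabeledTree, TreeError, normalize_root

__all__ = [
    "GeneratorConfig",
    "DeleteLabel",
    "DeleteUnlabeledLeaf",
    "ExpandVertex",
    "EditScript",
    "generate_tree",
    "apply_edit_script",
    "derive_pair",
    "oracle_common_size",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducible random-tree recipe: identical config => identical tree.

    ``labels_min``/``labels_max`` bound the uniform per-vertex label-count
    draw; draws are clipped to the remaining universe, and an error is raised
    only when ``labels_min`` cannot be met.  ``branching_bias`` is the
    probability that a new vertex attaches to a uniformly random existing
    vertex instead of the previously added one (0 gives paths, 1 gives
    star-like trees).
    """

    seed: int
    n_vertices: int
    labels_min: int = 1
    labels_max: int = 3
    universe_size: int = 32
    branching_bias: float = 0.5
    label_prefix: str = "M"

    def __post_init__(self):
        if self.n_vertices < 1:
            raise TreeError("n_vertices must be >= 1")
        if not (0 <= self.labels_min <= self.labels_max):
            raise TreeError("need 0 <= labels_min <= labels_max")


def generate_tree(config: GeneratorConfig) -> MultiLabeledTree:
    """Random multi-labeled tree with a label-free root; deterministic per
    config.  Labels are drawn without replacement from the universe
    ``{prefix}00..{prefix}{universe_size-1}``, so two trees generated from
    the same universe share labels."""
    rng = random.Random(config.seed)
    pool = [f"{config.label_prefix}{i:02d}" for i in range(config.universe_size)]
    rng.shuffle(pool)

    root = "v0"
    parent: dict[str, str] = {}
    labels: dict[str, list[str]] = {}
    existing = [root]
    for i in range(1, config.n_vertices):
        vid = f"v{i}"
        if i == 1 or rng.random() >= config.branching_bias:
            parent[vid] = existing[-1]
        else:
            parent[vid] = rng.choice(existing)
        k = rng.randint(config.labels_min, config.labels_max)
        if len(pool) < config.labels_min:
            raise TreeError(
                f"label universe exhausted: {len(pool)} labels left but at "
                f"least {config.labels_min} requested for vertex {vid!r}")
        k = min(k, len(pool))
        labels[vid] = [pool.pop() for _ in range(k)]
        existing.append(vid)
    return MultiLabeledTree(root, parent, labels)


# ---------------------------------------------------------------------------
# edit scripts


@dataclass(frozen=True)
class DeleteLabel:
    label: str


@dataclass(frozen=True)
class DeleteUnlabeledLeaf:
    vertex: str


@dataclass(frozen=True)
class ExpandVertex:
    """Split ``vertex`` into a parent-child pair; ``top_labels`` go to the
    new parent, the rest (and all children) stay with the vertex."""

    vertex: str
    top_labels: frozenset

    def __init__(self, vertex: str, top_labels):
        object.__setattr__(self, "vertex", vertex)
        object.__setattr__(self, "top_labels", frozenset(top_labels))


@dataclass(frozen=True)
class EditScript:
    """Ordered list of edit operations; each must be valid at its
    application point."""

    operations: tuple = ()


def apply_edit_script(tree: MultiLabeledTree, script: EditScript) -> MultiLabeledTree:
    """Apply the operations in order, validating each one."""
    for op in script.operations:
        tree = _apply_one(tree, op)
    return tree


def _apply_one(tree: MultiLabeledTree, op) -> MultiLabeledTree:
    parent = {v: tree.parent(v) for v in tree.vertices if v != tree.root}
    labels = {v: set(tree.label_set(v)) for v in tree.vertices}

    if isinstance(op, DeleteLabel):
        if op.label not in tree.label_universe:
            raise TreeError(f"cannot delete unknown label {op.label!r}")
        labels[tree.vertex_of_label(op.label)].discard(op.label)
    elif isinstance(op, DeleteUnlabeledLeaf):
        v = op.vertex
        if v not in tree:
            raise TreeError(f"cannot delete unknown vertex {v!r}")
        if v == tree.root:
            raise TreeError("cannot delete the root")
        if tree.children(v):
            raise TreeError(f"cannot delete {v!r}: it still has children")
        if tree.label_set(v):
            raise TreeError(f"cannot delete {v!r}: it still has labels")
        del parent[v]
        del labels[v]
    elif isinstance(op, ExpandVertex):
        v = op.vertex
        if v not in tree:
            raise TreeError(f"cannot expand unknown vertex {v!r}")
        if v == tree.root:
            raise TreeError("cannot expand the root")
        if not op.top_labels <= tree.label_set(v):
            raise TreeError(
                f"top_labels {sorted(op.top_labels)} are not a subset of the "
                f"labels of {v!r}")
        top = f"{v}^"
        while top in tree:
            top += "^"
        parent[top] = parent[v]
        parent[v] = top
        labels[top] = set(op.top_labels)
        labels[v] -= op.top_labels
    else:
        raise TreeError(f"unknown edit operation {op!r}")
    return MultiLabeledTree(tree.root, parent, labels)


def derive_pair(
    tree: MultiLabeledTree,
    k_deletions: int,
    seed: int,
) -> tuple[MultiLabeledTree, MultiLabeledTree, int]:
    """Derive two trees from a common ancestor by random edit scripts
    (expansions plus ``k_deletions`` label deletions split between the
    sides), with a certified score lower bound.

    Both sides expand each original vertex contiguously with respect to a
    single per-vertex label order drawn from ``seed``.  This keeps the two
    granularity refinements mutually order-consistent, so the ancestor's
    fully-expanded form minus the deleted labels is a common tree of the
    pair by construction and ``lower_bound = |L(tree)| - #deleted``
    certifies ``max_common_tree_size(t1, t2) >= lower_bound``.  (Two
    *conflicting* expansions of the same vertex — A above B on one side, B
    above A on the other — would forfeit a label, which is why the order is
    shared.)"""
    if k_deletions > tree.n_labels:
        raise TreeError("cannot delete more labels than the tree has")
    rng = random.Random(seed)
    order = {v: rng.sample(sorted(tree.label_set(v)), len(tree.label_set(v)))
             for v in tree.vertices}
    deleted: set[str] = set()
    sides = []
    for side in range(2):
        t = tree
        # ordered label block carried by each current vertex
        block = {v: list(order[v]) for v in tree.vertices}
        for _ in range(rng.randint(0, tree.n_vertices)):
            cands = [v for v in sorted(block) if len(block[v]) >= 2]
            if not cands:
                break
            v = rng.choice(cands)
            ls = block[v]
            k = rng.randint(1, len(ls) - 1)
            top = f"{v}^"
            while top in t:
                top += "^"
            t = _apply_one(t, ExpandVertex(v, ls[:k]))
            block[top] = ls[:k]
            block[v] = ls[k:]
        n_del = k_deletions - len(deleted) if side == 1 else rng.randint(0, k_deletions)
        for _ in range(n_del):
            pool = sorted(t.label_universe)
            if not pool:
                break
            lab = rng.choice(pool)
            deleted.add(lab)
            t = _apply_one(t, DeleteLabel(lab))
        sides.append(t)
    lower_bound = tree.n_labels - len(deleted)
    return sides[0], sides[1], lower_bound


# ---------------------------------------------------------------------------
# exhaustive oracle

_ORACLE_MAX_VERTICES = 7


def oracle_common_size(t1: MultiLabeledTree, t2: MultiLabeledTree) -> int:
    """Exact maximum common tree size by exhaustive search (guarded to
    trees of at most 7 vertices each).

    Enumerates every partial injection between the vertex sets (roots
    included: the branch point of the common tree may correspond to the
    label-free root on one side and an internal vertex on the other) whose
    matched pairs are closed under lowest common ancestors and commute with
    lca; each valid mapping is scored by summing Set Alignment optima over
    the maximal downward path segments between consecutive matched vertices.
    """
    for t in (t1, t2):
        if t.n_vertices > _ORACLE_MAX_VERTICES:
            raise TreeError(
                f"oracle guard: tree has {t.n_vertices} vertices "
                f"(> {_ORACLE_MAX_VERTICES}); exhaustive search refused")
    n1, n2 = normalize_root(t1), normalize_root(t2)
    A = list(n1.preorder())
    B = list(n2.preorder())

    lca1 = {(u, v): n1.lca(u, v) for u in A for v in A}
    lca2 = {(u, v): n2.lca(u, v) for u in B for v in B}
    seg1 = {v: _segment_cache(n1, v) for v in A}
    seg2 = {v: _segment_cache(n2, v) for v in B}

    best = 0
    for k in range(1, min(len(A), len(B)) + 1):
        for sa in itertools.combinations(A, k):
            for sb in itertools.combinations(B, k):
                for perm in itertools.permutations(sb):
                    score = _score_mapping(n1, n2, sa, perm, lca1, lca2, seg1, seg2)
                    if score > best:
                        best = score
    return best


def _segment_cache(tree: MultiLabeledTree, v: str) -> tuple[tuple[str, ...], tuple]:
    """Root-first strict ancestors of v, and the label sets along them + v."""
    anc = tree.ancestors(v)
    return anc, tuple(tree.label_set(w) for w in anc)


def _score_mapping(n1, n2, sa, sb, lca1, lca2, seg1, seg2) -> int:
    M = dict(zip(sa, sb))
    # lca-closure and commutation: the lca of any two matched vertices must
    # itself be matched, to the lca of their images.
    for u, v in itertools.combinations(sa, 2):
        image = M.get(lca1[(u, v)])
        if image is None or image != lca2[(M[u], M[v])]:
            return -1
    matched1 = set(sa)
    matched2 = set(sb)
    total = 0
    for u in sa:
        v = M[u]
        anc_u, labs_u = seg1[u]
        anc_v, labs_v = seg2[v]
        # segment runs from just below the nearest matched strict ancestor
        # (from the root when there is none) down to the vertex itself
        iu = max((i for i, w in enumerate(anc_u[:-1]) if w in matched1),
                 default=-1)
        iv = max((i for i, w in enumerate(anc_v[:-1]) if w in matched2),
                 default=-1)
        s = LabelSequence(labs_u[iu + 1:])
        p = LabelSequence(labs_v[iv + 1:])
        total += align_sets(s, p).size
    return total
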