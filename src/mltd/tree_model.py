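"""Rooted multi-labeled trees: data model, validation, serialization, conversions.

A multi-labeled tree is a rooted, unordered tree in which every vertex other
than the root carries a (possibly empty) set of labels, and the label sets of
distinct vertices are disjoint.  In the tumor-evolution application a label is
a somatic mutation and a vertex is a clone; label disjointness is the infinite
sites assumption (ISA): each mutation arises exactly once and is never lost.

Two canonical granularities are supported:

* a *clonal tree* has a label-free root and a non-empty label set on every
  other vertex (one vertex per clone);
* a *mutation tree* is the maximally refined clonal tree with exactly one
  label per non-root vertex.

``to_clonal`` and ``expand_to_mutation_tree`` convert between the two;
``count_mutation_trees`` counts how many distinct mutation trees a clonal
tree can be refined into (the product of the factorials of its label-set
sizes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Mapping, Sequence

__all__ = [
    "TreeError",
    "TreeFormatError",
    "ISAViolationError",
    "MultiLabeledTree",
    "VertexClassification",
    "parse_tree",
    "serialize_tree",
    "normalize_root",
    "to_clonal",
    "expand_to_mutation_tree",
    "count_mutation_trees",
    "classify_vertices",
    "isomorphic",
    "to_dot",
]

_ROOT_MARK = "-"


class TreeError(ValueError):
    """Invalid multi-labeled tree structure or operation."""


class TreeFormatError(TreeError):
    """Malformed tree-format document."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class ISAViolationError(TreeError):
    """A label is assigned to more than one vertex (infinite sites violation)."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(
            f"ISA violation: label {label!r} is assigned to more than one vertex"
        )


class MultiLabeledTree:
    """Immutable rooted tree with disjoint per-vertex label sets.

    Parameters
    ----------
    root:
        Vertex id of the root.
    parent:
        Map from every non-root vertex id to its parent id.  The parent map
        must induce a single connected, acyclic tree rooted at ``root``.
    labels:
        Map from vertex id to an iterable of label strings.  Vertices may be
        omitted (empty label set); label sets of distinct vertices must be
        disjoint.  The root may carry labels in a general multi-labeled tree;
        :func:`normalize_root` prepends a fresh label-free root when needed.
    """

    __slots__ = ("_root", "_parent", "_labels", "_children", "_depth",
                 "_ancestors", "_universe", "_label_vertex")

    def __init__(
        self,
        root: str,
        parent: Mapping[str, str],
        labels: Mapping[str, Iterable[str]] | None = None,
    ):
        labels = labels or {}
        if root in parent:
            raise TreeError(f"root {root!r} must not have a parent")
        vertices = {root} | set(parent) | set(parent.values())
        for v in parent.values():
            if v != root and v not in parent:
                raise TreeError(f"orphan vertex: parent {v!r} is never defined")
        for v in labels:
            if v not in vertices:
                raise TreeError(f"labels given for unknown vertex {v!r}")

        self._root = root
        self._parent = dict(parent)
        lab = {v: frozenset(labels.get(v, ())) for v in vertices}
        self._labels = lab

        # depth via upward walks; doubles as cycle detection
        depth: dict[str, int] = {root: 0}
        for v in vertices:
            chain = []
            u = v
            seen_here = set()
            while u not in depth:
                if u in seen_here:
                    raise TreeError(f"cycle detected through vertex {u!r}")
                seen_here.add(u)
                chain.append(u)
                u = self._parent[u]
            base = depth[u]
            for i, w in enumerate(reversed(chain), start=1):
                depth[w] = base + i
        self._depth = depth

        # label disjointness + universe
        label_vertex: dict[str, str] = {}
        for v in sorted(vertices):
            for l in lab[v]:
                if l in label_vertex:
                    raise ISAViolationError(l)
                label_vertex[l] = v
        self._label_vertex = label_vertex
        self._universe = frozenset(label_vertex)

        # deterministic child order: by smallest contained label, then id
        children: dict[str, list[str]] = {v: [] for v in vertices}
        for v, p in self._parent.items():
            children[p].append(v)
        key = lambda v: (min(lab[v]) if lab[v] else "", v)
        self._children = {v: tuple(sorted(cs, key=key)) for v, cs in children.items()}

        # root-first ancestor tuples (inclusive of the vertex itself)
        anc: dict[str, tuple[str, ...]] = {root: (root,)}
        for v in self.preorder():
            if v != root:
                anc[v] = anc[self._parent[v]] + (v,)
        self._ancestors = anc

    # -- basic accessors ---------------------------------------------------

    @property
    def root(self) -> str:
        return self._root

    @property
    def vertices(self) -> frozenset[str]:
        return frozenset(self._labels)

    @property
    def n_vertices(self) -> int:
        return len(self._labels)

    @property
    def label_universe(self) -> frozenset[str]:
        """L(T): the union of all per-vertex label sets."""
        return self._universe

    @property
    def n_labels(self) -> int:
        return len(self._universe)

    def parent(self, v: str) -> str | None:
        self._check(v)
        return self._parent.get(v)

    def children(self, v: str) -> tuple[str, ...]:
        self._check(v)
        return self._children[v]

    def label_set(self, v: str) -> frozenset[str]:
        self._check(v)
        return self._labels[v]

    def vertex_of_label(self, label: str) -> str:
        return self._label_vertex[label]

    def is_leaf(self, v: str) -> bool:
        return not self.children(v)

    def depth(self, v: str) -> int:
        self._check(v)
        return self._depth[v]

    def ancestors(self, v: str) -> tuple[str, ...]:
        """Ancestors of ``v`` in root-first order, including ``v`` itself."""
        self._check(v)
        return self._ancestors[v]

    def is_ancestor(self, u: str, v: str) -> bool:
        """u ⪯ v in the ancestor partial order (reflexive)."""
        self._check(u)
        anc = self.ancestors(v)
        d = self._depth[u]
        return d < len(anc) and anc[d] == u

    def lca(self, u: str, v: str) -> str:
        """Lowest common ancestor: the deepest vertex that is ⪯ both."""
        au, av = self.ancestors(u), self.ancestors(v)
        k = min(len(au), len(av))
        last = self._root
        for i in range(k):
            if au[i] != av[i]:
                break
            last = au[i]
        return last

    # -- traversals --------------------------------------------------------

    def preorder(self) -> list[str]:
        out: list[str] = []
        stack = [self._root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(reversed(self._children[v]))
        return out

    def postorder(self) -> list[str]:
        out: list[str] = []
        stack: list[tuple[str, bool]] = [(self._root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                out.append(v)
            else:
                stack.append((v, True))
                for c in reversed(self._children[v]):
                    stack.append((c, False))
        return out

    # -- misc ----------------------------------------------------------------

    def _check(self, v: str) -> None:
        if v not in self._labels:
            raise TreeError(f"vertex {v!r} not in tree")

    def __contains__(self, v: str) -> bool:
        return v in self._labels

    def __iter__(self) -> Iterator[str]:
        return iter(self.preorder())

    def __repr__(self) -> str:
        return (f"MultiLabeledTree(n_vertices={self.n_vertices}, "
                f"n_labels={self.n_labels}, root={self._root!r})")


@dataclass(frozen=True)
class VertexClassification:
    """Partition of vertices into crucial (leaves, or ≥2 children) and
    non-crucial (exactly one child)."""

    crucial: frozenset[str]
    non_crucial: frozenset[str]


# ---------------------------------------------------------------------------
# serialization


def parse_tree(text: str) -> MultiLabeledTree:
    """Parse a tree-format document into a :class:`MultiLabeledTree`.

    Format: one vertex per line, ``vertex_id<TAB>parent_id<TAB>labels`` with
    labels comma-separated (field may be empty); the root uses parent id
    ``-``; blank lines and lines starting with ``#`` are ignored.
    """
    rows: list[tuple[int, str, str, list[str]]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (2, 3):
            raise TreeFormatError(
                "expected 'vertex_id<TAB>parent_id<TAB>labels'", lineno)
        vid, pid = fields[0].strip(), fields[1].strip()
        if not vid or not pid:
            raise TreeFormatError("empty vertex or parent id", lineno)
        label_field = fields[2] if len(fields) == 3 else ""
        labs = [tok.strip() for tok in label_field.split(",") if tok.strip()]
        rows.append((lineno, vid, pid, labs))
    if not rows:
        raise TreeFormatError("empty document")

    seen: dict[str, int] = {}
    roots: list[str] = []
    parent: dict[str, str] = {}
    labels: dict[str, list[str]] = {}
    for lineno, vid, pid, labs in rows:
        if vid in seen:
            raise TreeFormatError(
                f"duplicate vertex id {vid!r} (first defined on line {seen[vid]})",
                lineno)
        seen[vid] = lineno
        if pid == _ROOT_MARK:
            roots.append(vid)
        else:
            parent[vid] = pid
        labels[vid] = labs
    if not roots:
        raise TreeFormatError("no root vertex (parent id '-') found")
    if len(roots) > 1:
        raise TreeFormatError(f"multiple roots: {', '.join(sorted(roots))}")
    for lineno, vid, pid, _ in rows:
        if pid != _ROOT_MARK and pid not in seen:
            raise TreeFormatError(f"orphan vertex {vid!r}: unknown parent {pid!r}",
                                  lineno)
    seen_labels: dict[str, str] = {}
    for _, vid, _, labs in rows:
        for l in labs:
            if l in seen_labels:
                raise ISAViolationError(l)
            seen_labels[l] = vid
    return MultiLabeledTree(roots[0], parent, labels)


def serialize_tree(tree: MultiLabeledTree) -> str:
    """Deterministic tree-format document; inverse of :func:`parse_tree` up to
    vertex-id-preserving identity (children emitted in sorted order)."""
    lines = []
    for v in tree.preorder():
        p = tree.parent(v)
        lines.append(f"{v}\t{p if p is not None else _ROOT_MARK}\t"
                     f"{','.join(sorted(tree.label_set(v)))}")
    return "\n".join(lines) + "\n"


def to_dot(tree: MultiLabeledTree) -> str:
    """Graphviz DOT export (labels joined by commas inside node boxes)."""
    lines = ["digraph T {", "  node [shape=box];"]
    for v in tree.preorder():
        text = ",".join(sorted(tree.label_set(v))) or "∅"
        lines.append(f'  "{v}" [label="{text}"];')
    for v in tree.preorder():
        p = tree.parent(v)
        if p is not None:
            lines.append(f'  "{p}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# conversions


def _fresh_id(base: str, taken: set[str]) -> str:
    cand = base
    i = 0
    while cand in taken:
        i += 1
        cand = f"{base}{i}"
    return cand


def normalize_root(tree: MultiLabeledTree) -> MultiLabeledTree:
    """Ensure a label-free root by prepending a fresh unlabeled root if the
    current root carries labels; identity otherwise."""
    if not tree.label_set(tree.root):
        return tree
    taken = set(tree.vertices)
    new_root = _fresh_id("root", taken)
    parent = {v: tree.parent(v) for v in tree.vertices if v != tree.root}
    parent[tree.root] = new_root
    labels = {v: tree.label_set(v) for v in tree.vertices}
    return MultiLabeledTree(new_root, parent, labels)


def to_clonal(tree: MultiLabeledTree) -> MultiLabeledTree:
    """Convert to the unique clonal tree: merge every label-free non-root
    vertex into its parent (repeatedly), then ensure a label-free root."""
    tree = normalize_root(tree)
    root = tree.root
    kept = {root} | {v for v in tree.vertices
                     if v != root and tree.label_set(v)}

    def nearest_kept(v: str) -> str:
        anc = tree.ancestors(v)
        for u in reversed(anc[:-1]):
            if u in kept:
                return u
        return root

    parent = {v: nearest_kept(v) for v in kept if v != root}
    labels = {v: tree.label_set(v) for v in kept}
    return MultiLabeledTree(root, parent, labels)


OrderPolicy = Callable[[str, frozenset], Sequence[str]]


def expand_to_mutation_tree(
    tree: MultiLabeledTree,
    order_policy: OrderPolicy | None = None,
) -> MultiLabeledTree:
    """Refine a clonal tree into a mutation tree: every vertex with k labels
    becomes a top-down chain of k single-label vertices.

    ``order_policy(vertex, label_set)`` must return a total order of the
    vertex's labels (default lexicographic).  The first label in the order is
    placed closest to the root.
    """
    if tree.label_set(tree.root):
        raise TreeError("expand_to_mutation_tree requires a label-free root "
                        "(apply normalize_root first)")
    for v in tree.vertices:
        if v != tree.root and not tree.label_set(v):
            raise TreeError(f"not a clonal tree: non-root vertex {v!r} has no labels")
    if order_policy is None:
        order_policy = lambda v, ls: sorted(ls)

    taken = set(tree.vertices)
    parent: dict[str, str] = {}
    labels: dict[str, frozenset[str]] = {tree.root: frozenset()}
    for v in tree.preorder():
        if v == tree.root:
            continue
        ls = tree.label_set(v)
        order = list(order_policy(v, ls))
        if sorted(order) != sorted(ls):
            raise TreeError(f"order_policy did not return a permutation of the "
                            f"labels of vertex {v!r}")
        chain_ids = []
        for l in order[:-1]:
            nid = _fresh_id(f"{v}.{l}", taken)
            taken.add(nid)
            chain_ids.append(nid)
        chain_ids.append(v)  # original id keeps its children
        up = tree.parent(v)
        for nid, l in zip(chain_ids, order):
            parent[nid] = up
            labels[nid] = frozenset({l})
            up = nid
    return MultiLabeledTree(tree.root, parent, labels)


def count_mutation_trees(tree: MultiLabeledTree) -> int:
    """Number of distinct mutation trees obtainable from a clonal tree:
    the product over non-root vertices of |L_v|! ."""
    return math.prod(
        math.factorial(len(tree.label_set(v)))
        for v in tree.vertices if v != tree.root
    )


def classify_vertices(tree: MultiLabeledTree) -> VertexClassification:
    """Crucial vertices are leaves and vertices with two or more children;
    non-crucial vertices have exactly one child.  The root is classified by
    its child count like any other vertex."""
    crucial, non_crucial = set(), set()
    for v in tree.vertices:
        (non_crucial if len(tree.children(v)) == 1 else crucial).add(v)
    return VertexClassification(frozenset(crucial), frozenset(non_crucial))


def isomorphic(t1: MultiLabeledTree, t2: MultiLabeledTree) -> bool:
    """Structural equality ignoring vertex ids: same (parent-relation,
    label-set) shape as unordered trees."""

    def canon(tree: MultiLabeledTree) -> tuple:
        forms: dict[str, tuple] = {}
        for v in tree.postorder():
            kids = tuple(sorted(forms[c] for c in tree.children(v)))
            forms[v] = (tuple(sorted(tree.label_set(v))), kids)
        return forms[tree.root]

    return canon(t1) == canon(t2)
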