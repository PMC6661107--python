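"""Pairwise alignments on a tree: Set Alignment scores for every pair of
downward paths of two trees.

For vertices ``a ⪯ b`` in the first tree and ``c ⪯ d`` in the second, the
index stores ``D(a, c, b, d)``: the Set Alignment optimum between the label
sequences of the downward paths ``a..b`` and ``c..d``.  All entries are
filled in one sweep in increasing depth of the path bottoms, reusing the
parent entries::

    D(a, c, b, d) = max(D(a, c, p(b), d), D(a, c, b, p(d))) + |L_b ∩ L_d|

with the obvious degenerate cases when ``a = b`` or ``c = d``.  Only
ancestor-consistent quadruples exist, so storage is a sparse map keyed by
``(top1, top2, bottom1, bottom2)`` rather than a dense 4-D array.
"""

from __future__ import annotations

from dataclasses import dataclass

from .set_alignment import LabelSequence
from .tree_model import MultiLabeledTree, TreeError

__all__ = ["PathAlignmentIndex", "path_labels", "build_path_index"]


@dataclass(frozen=True)
class PathAlignmentIndex:
    """Sparse table of downward-path alignment scores for one tree pair."""

    D: dict

    def get(self, top1: str, top2: str, bottom1: str, bottom2: str) -> int:
        """D(top1, top2, bottom1, bottom2); requires top1 ⪯ bottom1 in the
        first tree and top2 ⪯ bottom2 in the second."""
        try:
            return self.D[(top1, top2, bottom1, bottom2)]
        except KeyError:
            raise TreeError(
                f"no downward-path pair ({top1!r}..{bottom1!r}, "
                f"{top2!r}..{bottom2!r}) in the index") from None

    def __len__(self) -> int:
        return len(self.D)


def path_labels(tree: MultiLabeledTree, u: str, v: str) -> LabelSequence:
    """Label sequence along the downward path ``u..v`` inclusive, in
    root-to-leaf order.  ``u`` must be an ancestor-or-self of ``v``."""
    anc = tree.ancestors(v)
    du = tree.depth(u)
    if du >= len(anc) or anc[du] != u:
        raise TreeError(f"{u!r} is not an ancestor of {v!r}")
    return LabelSequence(tuple(tree.label_set(w) for w in anc[du:]))


def build_path_index(t1: MultiLabeledTree, t2: MultiLabeledTree) -> PathAlignmentIndex:
    """Fill D for all ancestor-consistent quadruples of the two trees.

    Work is proportional to the number of valid quadruples plus the label
    counts: the per-vertex-pair intersection sizes come from a single pass
    over the shared labels.
    """
    # |L_b ∩ L_d| for all vertex pairs, via the shared-label map
    inter: dict[tuple[str, str], int] = {}
    for label in t1.label_universe & t2.label_universe:
        key = (t1.vertex_of_label(label), t2.vertex_of_label(label))
        inter[key] = inter.get(key, 0) + 1

    order1 = sorted(t1.vertices, key=t1.depth)
    order2 = sorted(t2.vertices, key=t2.depth)
    D: dict[tuple[str, str, str, str], int] = {}
    for b in order1:
        anc_b = t1.ancestors(b)
        pb = t1.parent(b)
        for d in order2:
            anc_d = t2.ancestors(d)
            pd = t2.parent(d)
            c_bd = inter.get((b, d), 0)
            for a in anc_b:
                a_is_b = a == b
                for c in anc_d:
                    if a_is_b and c == d:
                        val = c_bd
                    elif a_is_b:
                        val = D[(a, c, b, pd)] + c_bd
                    elif c == d:
                        val = D[(a, c, pb, d)] + c_bd
                    else:
                        val = max(D[(a, c, pb, d)], D[(a, c, b, pd)]) + c_bd
                    D[(a, c, b, d)] = val
    return PathAlignmentIndex(D)
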