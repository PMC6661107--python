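"""The Set Alignment Problem: a generalized longest common subsequence over
ordered sequences of disjoint label sets.

Given sequences ``S_1..S_n`` and ``P_1..P_m`` (each label occurring in exactly
one set per sequence), the goal is a maximum-size label subset whose positions
in the two sequences are weakly compatible: no pair of retained labels is
strictly inverted (``f(a) < f(b)`` and ``g(b) < g(a)``).  Labels sharing a set
on one side may be split in any order on the other — this is what makes a
multi-label vertex alignable against its own expansion into a chain.

When every set is a singleton the problem reduces to the classical LCS.  The
dynamic program is the LCS recurrence with the match term replaced by the
intersection size::

    D(i, j) = max(D(i, j-1), D(i-1, j)) + |S_i ∩ P_j|
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .tree_model import TreeError

__all__ = [
    "LabelSequence",
    "AlignmentTable",
    "AlignmentResult",
    "intersection_counts",
    "build_alignment_table",
    "align_sets",
]


@dataclass(frozen=True)
class LabelSequence:
    """Ordered sequence of pairwise-disjoint label sets (the label content of
    a downward path).  Positions are 1-based, matching the recurrences."""

    sets: tuple[frozenset[str], ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        index: dict[str, int] = {}
        for i, s in enumerate(self.sets, start=1):
            for l in s:
                if l in index:
                    raise TreeError(
                        f"label {l!r} occurs in more than one set of the sequence")
                index[l] = i
        object.__setattr__(self, "_index", index)

    @classmethod
    def of(cls, *sets: Iterable[str]) -> "LabelSequence":
        return cls(tuple(frozenset(s) for s in sets))

    def index_of(self, label: str) -> int:
        """1-based position of ``label`` in the sequence."""
        return self._index[label]

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self._index)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class AlignmentTable:
    """DP table D (``(n+1) x (m+1)``) and intersection counts I (``n x m``)."""

    D: tuple[tuple[int, ...], ...]
    I: tuple[tuple[int, ...], ...]

    @property
    def size(self) -> int:
        return self.D[-1][-1]


@dataclass(frozen=True)
class AlignmentResult:
    size: int
    retained: frozenset[str]


def intersection_counts(s: LabelSequence, p: LabelSequence) -> list[list[int]]:
    """``I[i][j] = |S_{i+1} ∩ P_{j+1}|`` computed in one pass over the shared
    labels (no pairwise set intersections)."""
    I = [[0] * len(p) for _ in range(len(s))]
    for label in s.universe & p.universe:
        I[s.index_of(label) - 1][p.index_of(label) - 1] += 1
    return I


def build_alignment_table(s: LabelSequence, p: LabelSequence) -> AlignmentTable:
    n, m = len(s), len(p)
    I = intersection_counts(s, p)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        row, above = D[i], D[i - 1]
        Irow = I[i - 1]
        for j in range(1, m + 1):
            row[j] = max(row[j - 1], above[j]) + Irow[j - 1]
    return AlignmentTable(tuple(map(tuple, D)), tuple(map(tuple, I)))


def align_sets(s: LabelSequence, p: LabelSequence) -> AlignmentResult:
    """Solve the Set Alignment Problem.

    Returns the optimal size ``D(n, m)`` together with a witness label set
    achieving it.  The witness is deterministic: the traceback prefers
    consuming from the first sequence (the ``D(i-1, j)`` branch) on ties.
    """
    table = build_alignment_table(s, p)
    D = table.D
    # labels grouped by DP cell
    cell: dict[tuple[int, int], list[str]] = {}
    for label in s.universe & p.universe:
        cell.setdefault((s.index_of(label), p.index_of(label)), []).append(label)

    retained: list[str] = []
    i, j = len(s), len(p)
    while i > 0 and j > 0:
        retained.extend(cell.get((i, j), ()))
        if D[i - 1][j] >= D[i][j - 1]:
            i -= 1
        else:
            j -= 1
    result = AlignmentResult(D[len(s)][len(p)], frozenset(retained))
    assert len(result.retained) == result.size
    return result
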