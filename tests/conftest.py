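"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import itertools

import pytest

from mltd import MultiLabeledTree


def make_tree(parent, labels, root="r"):
    return MultiLabeledTree(root, parent, labels)


# ---------------------------------------------------------------------------
# the three trees of the triangle-inequality counterexample


@pytest.fixture
def tri_a_above_b():
    return make_tree({"a": "r", "b": "a"}, {"a": ["A"], "b": ["B"]})


@pytest.fixture
def tri_b_above_a():
    return make_tree({"a": "r", "b": "a"}, {"a": ["B"], "b": ["A"]})


@pytest.fixture
def tri_single_ab():
    return make_tree({"a": "r"}, {"a": ["A", "B"]})


# ---------------------------------------------------------------------------
# the worked synthetic example: one early mutation A, then a 5-mutation and a
# 4-mutation sibling cluster


@pytest.fixture
def true_tree():
    return make_tree(
        {"a": "r", "c1": "a", "c2": "a"},
        {"a": ["A"], "c1": list("BCDEF"), "c2": list("GHIJ")},
    )


@pytest.fixture
def star_tree():
    parent = {"a": "r"}
    labels = {"a": ["A"]}
    for x in "BCDEFGHIJ":
        parent[f"s{x}"] = "a"
        labels[f"s{x}"] = [x]
    return make_tree(parent, labels)


@pytest.fixture
def linear_tree():
    return make_tree(
        {"a": "r", "g1": "a", "g2": "g1"},
        {"a": ["A"], "g1": list("BCDEF"), "g2": list("GHIJ")},
    )


# ---------------------------------------------------------------------------
# independent brute-force oracles


def brute_force_alignment_size(s_sets, p_sets) -> int:
    """Exhaustive Set Alignment optimum: try every subset of the shared
    labels and keep the largest one with no strictly inverted pair."""
    f = {l: i for i, s in enumerate(s_sets, 1) for l in s}
    g = {l: j for j, p in enumerate(p_sets, 1) for l in p}
    shared = sorted(set(f) & set(g))
    best = 0
    for k in range(len(shared), 0, -1):
        if k <= best:
            break
        for combo in itertools.combinations(shared, k):
            if all((f[a] - f[b]) * (g[a] - g[b]) >= 0
                   for a, b in itertools.combinations(combo, 2)):
                best = max(best, k)
                break
    return best


def textbook_lcs(x, y) -> int:
    """Classical longest-common-subsequence length."""
    n, m = len(x), len(y)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if x[i - 1] == y[j - 1]:
                D[i][j] = D[i - 1][j - 1] + 1
            else:
                D[i][j] = max(D[i - 1][j], D[i][j - 1])
    return D[n][m]


def brute_force_matching(weights) -> int:
    """Exhaustive maximum-weight partial bijection of an n x m matrix."""
    n = len(weights)
    m = len(weights[0]) if n else 0
    best = 0
    cols = range(m)
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for perm in itertools.permutations(cols, k):
                best = max(best, sum(weights[i][j] for i, j in zip(rows, perm)))
    return best
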