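"""Tree data model: parsing, serialization, granularity conversions."""

import itertools
import random

import pytest

from mltd import (
    ISAViolationError,
    MultiLabeledTree,
    TreeError,
    TreeFormatError,
    classify_vertices,
    count_mutation_trees,
    expand_to_mutation_tree,
    generate_tree,
    GeneratorConfig,
    isomorphic,
    normalize_root,
    parse_tree,
    serialize_tree,
    to_clonal,
)
from conftest import make_tree


class TestParse:
    def test_three_vertex_path(self):
        t = parse_tree("r\t-\t\nv1\tr\tA\nv2\tv1\tB")
        assert t.root == "r"
        assert t.parent("v2") == "v1" and t.parent("v1") == "r"
        assert t.label_set("v1") == {"A"} and t.label_set("v2") == {"B"}

    def test_multi_label_vertex(self):
        t = parse_tree("r\t-\t\nv1\tr\tA,B")
        assert t.label_set("v1") == {"A", "B"}
        assert t.n_labels == 2

    def test_comments_and_blank_lines_ignored(self):
        t = parse_tree("# a comment\n\nr\t-\t\n# another\nv1\tr\tA\n")
        assert t.n_vertices == 2

    def test_duplicate_label_is_isa_violation(self):
        with pytest.raises(ISAViolationError, match="'A'"):
            parse_tree("r\t-\t\nv1\tr\tA\nv2\tv1\tA")

    @pytest.mark.parametrize("doc,pattern", [
        ("r\t-\t\nr\tr\tA", "duplicate vertex"),
        ("r\t-\t\nv1\tghost\tA", "orphan"),
        ("r\t-\t\nx\ty\t\ny\tx\t", "cycle"),
        ("r\t-\t\ns\t-\t", "multiple roots"),
        ("", "empty document"),
        ("just one field", "expected"),
    ])
    def test_malformed_documents(self, doc, pattern):
        with pytest.raises(TreeError, match=pattern):
            parse_tree(doc)

    @pytest.mark.parametrize("seed", range(10))
    def test_injected_duplicate_label_always_rejected(self, seed):
        rng = random.Random(seed)
        tree = generate_tree(GeneratorConfig(seed=seed, n_vertices=6,
                                             universe_size=20))
        lines = serialize_tree(tree).splitlines()
        dup = rng.choice(sorted(tree.label_universe))
        i = rng.randrange(len(lines))
        vid, pid, labs = lines[i].split("\t")
        if dup in labs.split(","):
            labs_list = [l for l in labs.split(",") if l] + [dup]
            lines[i] = "\t".join([vid, pid, ",".join(labs_list)])
        else:
            lines[i] = "\t".join([vid, pid, (labs + "," if labs else "") + dup])
        with pytest.raises(ISAViolationError):
            parse_tree("\n".join(lines))


class TestSerialize:
    @pytest.mark.parametrize("seed", [1, 7, 23])
    def test_round_trip_preserves_structure(self, seed):
        t = generate_tree(GeneratorConfig(seed=seed, n_vertices=8,
                                          universe_size=30))
        assert isomorphic(parse_tree(serialize_tree(t)), t)

    def test_deterministic_output(self):
        t = make_tree({"b": "r", "a": "r"}, {"a": ["X"], "b": ["Q", "Z"]})
        assert serialize_tree(t) == serialize_tree(t)
        # children ordered by smallest contained label
        lines = serialize_tree(t).splitlines()
        assert lines[1].startswith("b\t")  # Q < X

    def test_multi_label_round_trip(self, tri_single_ab):
        again = parse_tree(serialize_tree(tri_single_ab))
        assert again.label_set("a") == {"A", "B"}


class TestNormalizeRoot:
    def test_labeled_root_gets_fresh_parent(self):
        t = MultiLabeledTree("x", {}, {"x": ["A"]})
        n = normalize_root(t)
        assert not n.label_set(n.root)
        assert n.parent("x") == n.root and n.label_set("x") == {"A"}

    def test_unlabeled_root_is_identity(self, tri_a_above_b):
        assert normalize_root(tri_a_above_b) is tri_a_above_b

    def test_single_labeled_vertex(self):
        n = normalize_root(MultiLabeledTree("x", {}, {"x": ["A", "B"]}))
        assert n.n_vertices == 2 and n.n_labels == 2


class TestToClonal:
    def test_empty_vertex_merged_into_parent(self):
        t = make_tree({"u": "r", "v": "u"}, {"v": ["A"]})
        c = to_clonal(t)
        assert isomorphic(c, make_tree({"v": "r"}, {"v": ["A"]}))

    def test_already_clonal_is_fixpoint(self, true_tree):
        assert isomorphic(to_clonal(true_tree), true_tree)

    def test_cascading_merge(self):
        t = make_tree(
            {"u": "r", "w": "u", "x": "w", "y": "x", "z": "x"},
            {"u": ["A"], "y": ["B"], "z": ["C"]},
        )
        expected = make_tree({"u": "r", "y": "u", "z": "u"},
                             {"u": ["A"], "y": ["B"], "z": ["C"]})
        assert isomorphic(to_clonal(t), expected)

    def test_labeled_root_is_normalized(self):
        t = MultiLabeledTree("x", {"y": "x"}, {"x": ["A"], "y": ["B"]})
        c = to_clonal(t)
        assert not c.label_set(c.root) and c.n_labels == 2


class TestExpansion:
    def test_chain_follows_order_policy(self):
        t = make_tree({"v": "r"}, {"v": ["M1", "M2", "M3"]})
        m = expand_to_mutation_tree(t)
        # top-down single-label chain M1, M2, M3
        seq = []
        v = m.root
        while m.children(v):
            (v,) = m.children(v)
            seq.append(sorted(m.label_set(v)))
        assert seq == [["M1"], ["M2"], ["M3"]]

    def test_mutation_tree_is_fixpoint(self, tri_a_above_b):
        assert isomorphic(expand_to_mutation_tree(tri_a_above_b), tri_a_above_b)

    @pytest.mark.parametrize("seed", range(8))
    def test_labels_and_ancestry_preserved(self, seed):
        rng = random.Random(seed)
        t = generate_tree(GeneratorConfig(seed=seed, n_vertices=7,
                                          labels_max=4, universe_size=40))
        m = expand_to_mutation_tree(
            t, lambda v, ls: rng.sample(sorted(ls), len(ls)))
        assert m.label_universe == t.label_universe
        for x, y in itertools.combinations(sorted(t.label_universe), 2):
            u, v = t.vertex_of_label(x), t.vertex_of_label(y)
            if u == v:
                continue  # order within a vertex is the policy's choice
            assert t.is_ancestor(u, v) == m.is_ancestor(
                m.vertex_of_label(x), m.vertex_of_label(y))

    def test_requires_clonal_input(self):
        with pytest.raises(TreeError, match="clonal"):
            expand_to_mutation_tree(make_tree({"u": "r", "v": "u"},
                                              {"v": ["A"]}))


class TestCountMutationTrees:
    @pytest.mark.parametrize("sizes,expected", [
        ([1, 1, 1], 1),
        ([3], 6),
        ([1, 3, 2], 12),
    ])
    def test_product_of_factorials(self, sizes, expected):
        labels, parent = {}, {}
        prev = "r"
        pool = iter(f"M{i}" for i in range(100))
        for i, k in enumerate(sizes):
            v = f"v{i}"
            parent[v] = prev
            labels[v] = [next(pool) for _ in range(k)]
            prev = v
        assert count_mutation_trees(make_tree(parent, labels)) == expected

    @pytest.mark.parametrize("labels", [
        {"u": ["a"], "v": ["b", "c"]},
        {"u": ["a", "b", "c"], "v": ["d"]},
        {"u": ["a", "b"], "v": ["c", "d"]},
    ])
    def test_counts_distinct_expansions_exhaustively(self, labels):
        t = make_tree({"u": "r", "v": "u"}, labels)
        seen = set()
        orders = [
            dict(zip(labels, combo))
            for combo in itertools.product(
                *(itertools.permutations(labels[v]) for v in labels))
        ]
        for order in orders:
            m = expand_to_mutation_tree(t, lambda v, ls: list(order[v]))
            seen.add(serialize_tree(m))
        assert len(seen) == count_mutation_trees(t)


class TestClassifyAndLca:
    def test_path_has_one_crucial_vertex(self):
        t = make_tree({"a": "r", "b": "a", "c": "b"},
                      {"a": ["A"], "b": ["B"], "c": ["C"]})
        cls = classify_vertices(t)
        assert cls.crucial == {"c"}
        assert cls.non_crucial == {"r", "a", "b"}

    def test_star_root_and_leaves_crucial(self):
        t = make_tree({"a": "r", "b": "r", "c": "r"},
                      {"a": ["A"], "b": ["B"], "c": ["C"]})
        assert classify_vertices(t).crucial == {"r", "a", "b", "c"}

    def test_caterpillar(self):
        t = make_tree({"a": "r", "b": "a", "c": "b", "d": "b"},
                      {"a": ["A"], "b": ["B"], "c": ["C"], "d": ["D"]})
        assert classify_vertices(t).crucial == {"b", "c", "d"}

    @pytest.mark.parametrize("seed", range(6))
    def test_crucial_count_at_least_leaves(self, seed):
        t = generate_tree(GeneratorConfig(seed=seed, n_vertices=9,
                                          universe_size=40))
        leaves = {v for v in t.vertices if t.is_leaf(v)}
        assert leaves <= classify_vertices(t).crucial

    def test_lca_reflexive_and_siblings(self, true_tree):
        assert true_tree.lca("c1", "c1") == "c1"
        assert true_tree.lca("c1", "c2") == "a"
        assert true_tree.lca("a", "c2") == "a"

    @pytest.mark.parametrize("seed", range(5))
    def test_lca_matches_ancestor_set_intersection(self, seed):
        t = generate_tree(GeneratorConfig(seed=seed, n_vertices=10,
                                          universe_size=40))
        verts = sorted(t.vertices)
        for u in verts:
            for v in verts:
                common = set(t.ancestors(u)) & set(t.ancestors(v))
                deepest = max(common, key=t.depth)
                assert t.lca(u, v) == deepest

    def test_unknown_vertex_rejected(self, true_tree):
        with pytest.raises(TreeError, match="not in tree"):
            true_tree.lca("a", "nope")
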