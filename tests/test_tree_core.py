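"""Tree model, Euler strings, occurrence enumeration, class tables."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treegram import (
    LabeledTree,
    SubtreeRef,
    TreeError,
    DegreeCapError,
    build_class_table,
    canonical_string_unordered,
    edge_labels_from_vertices,
    enumerate_refs,
    euler_string,
    string_key,
)
from treegram.tree_core import (
    TAG_TOKEN,
    enumerate_splits,
    key_edge_count,
    key_is_tagged,
    ref_edge_count,
    ref_is_base,
    _internal_of_untagged,
)
from treegram.oracle_synth import GeneratorConfig, random_tree

from conftest import path_tree, star_tree, random_instance


# ---------------------------------------------------------------------------
# construction and indexing
# ---------------------------------------------------------------------------

class TestLabeledTree:
    def test_preorder_renumbering_and_indexing(self):
        # arbitrary input numbering is normalized to preorder with root 1
        t = LabeledTree("t", {7: 9, 3: 9, 5: 3}, {7: "b", 3: "a", 5: "c"},
                        child_order={9: [3, 7]})
        assert t.vertices == (1, 2, 3, 4)
        assert t.ch(1) == (2, 4)       # 'a' child first, then 'b'
        assert t.edge_label[2] == "a" and t.edge_label[4] == "b"
        assert t.anc(3) == {1, 2}
        assert t.anc(1) == frozenset()
        assert t.subtree_edges(1) == 3 and t.subtree_edges(2) == 1
        assert t.lch(1) == 2 and t.rch(1) == 4

    def test_single_vertex_rejected(self):
        with pytest.raises(TreeError, match="single-vertex"):
            LabeledTree("t", {}, {})

    @pytest.mark.parametrize("parent", [
        {2: 2},                   # self-loop, no root
        {2: 3, 3: 2},             # cycle, no root
        {2: 1, 4: 3},             # two roots
    ])
    def test_invalid_structures_rejected(self, parent):
        labels = {v: "a" for v in parent}
        with pytest.raises(TreeError):
            LabeledTree("t", parent, labels)

    def test_reserved_labels_rejected(self):
        for bad in ("", "a b", "/a", TAG_TOKEN):
            with pytest.raises(TreeError):
                LabeledTree("t", {2: 1}, {2: bad})


class TestEdgeLabelsFromVertices:
    def test_root_label_dropped(self):
        t = edge_labels_from_vertices("g", {2: 1}, {1: "Glc", 2: "Gal"})
        assert list(t.edge_label.values()) == ["Gal"]

    def test_chain_preserves_shape(self):
        t = edge_labels_from_vertices(
            "g", {2: 1, 3: 2}, {1: "Glc", 2: "Gal", 3: "Man"})
        assert t.edge_label == {2: "Gal", 3: "Man"}
        assert t.parent == {2: 1, 3: 2}

    def test_single_vertex_rejected(self):
        with pytest.raises(TreeError, match="at least 2 vertices"):
            edge_labels_from_vertices("g", {}, {1: "Glc"})


# ---------------------------------------------------------------------------
# Euler strings
# ---------------------------------------------------------------------------

class TestEulerString:
    def test_three_leaf_star(self):
        t = star_tree(["a", "a", "b"])
        assert string_key(euler_string(t, t.whole_ref())) == "a /a a /a b /b"

    def test_tagged_single_edge(self):
        t = path_tree(["a", "b"])
        ref = SubtreeRef(0, 1, 2, (1, 1))  # edge into internal child, tagged
        assert string_key(euler_string(t, ref)) == f"a {TAG_TOKEN} /a"

    def test_untagged_single_edge(self):
        t = path_tree(["b"])
        assert string_key(euler_string(t, t.whole_ref())) == "b /b"

    def test_multicharacter_labels_do_not_collide(self):
        # "GC" as one token differs from two single-character tokens
        t1 = star_tree(["GC"])
        t2 = star_tree(["G", "C"])
        s1 = string_key(euler_string(t1, t1.whole_ref()))
        s2 = string_key(euler_string(t2, t2.whole_ref()))
        assert s1 != s2 and s1 == "GC /GC"

    def test_balanced_with_at_most_one_tag(self):
        trees, mode = random_instance(17)
        for alpha, t in enumerate(trees):
            for ref in enumerate_refs(t, alpha, mode):
                toks = (euler_string(t, ref) if mode == "ordered"
                        else canonical_string_unordered(t, ref))
                depth = 0
                stack = []
                for tok in toks:
                    if tok == TAG_TOKEN:
                        continue
                    if tok.startswith("/"):
                        assert stack and stack[-1] == tok[1:]
                        stack.pop()
                        depth -= 1
                    else:
                        stack.append(tok)
                        depth += 1
                assert depth == 0 and not stack
                assert list(toks).count(TAG_TOKEN) == (0 if ref.tag is None else 1)


def _iso_ordered(t1: LabeledTree, v1: int, t2: LabeledTree, v2: int) -> bool:
    """Independent recursive ordered-isomorphism check (roots v1, v2)."""
    k1, k2 = t1.ch(v1), t2.ch(v2)
    if len(k1) != len(k2):
        return False
    return all(t1.edge_label[a] == t2.edge_label[b] and _iso_ordered(t1, a, t2, b)
               for a, b in zip(k1, k2))


class TestIsomorphismCharacterization:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_euler_equality_iff_ordered_isomorphism(self, s1, s2):
        rng1, rng2 = np.random.default_rng(s1), np.random.default_rng(s2)
        cfg = GeneratorConfig(n_vertices=5, labels=("a", "b"), seed=0)
        t1 = random_tree(cfg, "t1", rng1)
        t2 = random_tree(cfg, "t2", rng2)
        same_string = (string_key(euler_string(t1, t1.whole_ref()))
                       == string_key(euler_string(t2, t2.whole_ref())))
        assert same_string == _iso_ordered(t1, 1, t2, 1)

    def test_isomorphic_pair_detected(self):
        t1 = path_tree(["a", "b"], "x")
        t2 = path_tree(["a", "b"], "y")
        assert string_key(euler_string(t1, t1.whole_ref())) == \
            string_key(euler_string(t2, t2.whole_ref()))
        assert _iso_ordered(t1, 1, t2, 1)


class TestCanonicalUnordered:
    def test_child_permutation_invariance(self):
        a = star_tree(["b", "a"], ordered=False)
        b = star_tree(["a", "b"], ordered=False)
        assert canonical_string_unordered(a, a.whole_ref()) == \
            canonical_string_unordered(b, b.whole_ref())

    def test_matches_sorted_sibling_order(self, t3_tree):
        t = t3_tree
        ref = t.whole_ref(mode="unordered")
        assert string_key(canonical_string_unordered(t, ref)) == "a /a a /a b /b"

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_random_shuffles(self, seed):
        rng = np.random.default_rng(seed)
        cfg = GeneratorConfig(n_vertices=7, max_degree=4, seed=seed)
        t = random_tree(cfg, "t", rng)
        ref = t.whole_ref(mode="unordered")
        base = canonical_string_unordered(t, ref)
        for _ in range(50):
            order = {v: list(rng.permutation(t.ch(v)).astype(int))
                     for v in t.vertices if t.ch(v)}
            shuffled = LabeledTree("t", t.parent, t.edge_label, ordered=False,
                                   child_order=order)
            assert canonical_string_unordered(
                shuffled, shuffled.whole_ref()) == base

    def test_tagged_permutation_invariance(self):
        t1 = LabeledTree("t", {2: 1, 3: 2, 4: 1}, {2: "a", 3: "b", 4: "c"},
                         ordered=False, child_order={1: [2, 4]})
        t2 = LabeledTree("t", {2: 1, 3: 2, 4: 1}, {2: "a", 3: "b", 4: "c"},
                         ordered=False, child_order={1: [4, 2]})
        r1 = SubtreeRef(0, 1, 2, frozenset(t1.ch(1)))
        r2 = SubtreeRef(0, 1, t2.ch(1)[-1] if t2.edge_label[t2.ch(1)[-1]] == "a"
                        else t2.ch(1)[0], frozenset(t2.ch(1)))
        assert canonical_string_unordered(t1, r1) == \
            canonical_string_unordered(t2, r2)


# ---------------------------------------------------------------------------
# occurrence enumeration and class tables
# ---------------------------------------------------------------------------

class TestEnumerateRefs:
    def test_single_edge(self):
        t = path_tree(["a"])
        assert len(enumerate_refs(t, 0, "ordered")) == 1

    def test_two_edge_path(self):
        t = path_tree(["a", "b"])
        refs = enumerate_refs(t, 0, "ordered")
        assert len(refs) == 3  # whole, whole tagged at the middle, lower edge
        assert sum(r.tag is not None for r in refs) == 1

    def test_three_leaf_star_ranges(self):
        t = star_tree(["a", "a", "b"])
        refs = enumerate_refs(t, 0, "ordered")
        assert [r.sel for r in refs] == [(1, 1), (1, 2), (1, 3), (2, 2),
                                         (2, 3), (3, 3)]
        assert all(r.tag is None for r in refs)

    def test_ordered_count_by_independent_formula(self):
        for seed in range(10):
            trees, _ = random_instance(seed)
            for alpha, t in enumerate(trees):
                refs = enumerate_refs(t, alpha, "ordered")
                expected = sum(
                    1 + len(_internal_of_untagged(t, i, (h, k)))
                    for i in t.vertices if t.ch(i)
                    for h in range(1, len(t.ch(i)) + 1)
                    for k in range(h, len(t.ch(i)) + 1))
                assert len(refs) == expected

    def test_degree_cap_error(self):
        t = star_tree(["a"] * 9, ordered=False)
        with pytest.raises(DegreeCapError, match="blow-up"):
            enumerate_refs(t, 0, "unordered")
        assert len(enumerate_refs(t, 0, "unordered", degree_cap=9)) == 2 ** 9 - 1

    def test_no_duplicates_and_deterministic(self):
        trees, mode = random_instance(5)
        t = trees[0]
        refs = enumerate_refs(t, 0, mode)
        assert len(refs) == len(set(refs))
        assert refs == enumerate_refs(t, 0, mode)


class TestSplits:
    def test_base_refs_have_no_splits(self):
        t = path_tree(["a"])
        assert enumerate_splits(t, t.whole_ref()) == []

    def test_parts_are_strictly_smaller(self):
        for seed in range(8):
            trees, mode = random_instance(seed)
            for alpha, t in enumerate(trees):
                for ref in enumerate_refs(t, alpha, mode):
                    n = ref_edge_count(t, ref)
                    for sp in enumerate_splits(t, ref):
                        a = ref_edge_count(t, sp.first)
                        b = ref_edge_count(t, sp.second)
                        assert a >= 1 and b >= 1 and a + b == n

    def test_unordered_partitions_counted_once(self):
        t = star_tree(["a", "b", "c"], ordered=False)
        sps = enumerate_splits(t, t.whole_ref())
        assert len(sps) == 3  # {1}|{2,3}, {1,2}|{3}, {1,3}|{2}
        seen = {frozenset([sp.first.sel, sp.second.sel]) for sp in sps}
        assert len(seen) == 3


class TestClassTable:
    def test_three_leaf_star_classes(self, t3_tree):
        table = build_class_table([t3_tree], "ordered")
        assert sorted(table.keys) == sorted(
            ["a /a", "b /b", "a /a a /a", "a /a b /b", "a /a a /a b /b"])

    def test_two_edge_path_classes(self):
        t = path_tree(["a", "b"])
        table = build_class_table([t], "ordered")
        assert sorted(table.keys) == sorted(
            ["b /b", f"a {TAG_TOKEN} /a", "a b /b /a"])

    def test_duplicate_tree_same_classes(self, t3_tree):
        one = build_class_table([t3_tree], "ordered")
        t2 = LabeledTree("copy", t3_tree.parent, t3_tree.edge_label,
                         child_order={v: t3_tree.ch(v) for v in t3_tree.vertices})
        two = build_class_table([t3_tree, t2], "ordered")
        assert one.keys == two.keys
        assert all(len(two.occurrences[k]) == 2 * len(one.occurrences[k])
                   for k in one.keys)

    def test_key_helpers(self):
        assert key_edge_count("a /a a /a b /b") == 3
        assert key_is_tagged(f"a {TAG_TOKEN} /a")
        assert not key_is_tagged("a /a")

    def test_tagged_and_untagged_distinct(self):
        t = path_tree(["a", "a"])
        table = build_class_table([t], "ordered")
        tagged = [k for k in table.keys if key_is_tagged(k)]
        untagged = [k for k in table.keys if not key_is_tagged(k)]
        assert tagged and untagged and not set(tagged) & set(untagged)
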