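"""Shared helpers: tiny hand-built trees and seeded random instances."""

from __future__ import annotations

import numpy as np
import pytest

from treegram import LabeledTree
from treegram.oracle_synth import GeneratorConfig, random_tree


def path_tree(labels, tree_id="path", ordered=True) -> LabeledTree:
    """Chain of edges root -> ... -> leaf with the given labels, top down."""
    parent = {v: v - 1 for v in range(2, len(labels) + 2)}
    edge_label = {v: lab for v, lab in zip(range(2, len(labels) + 2), labels)}
    return LabeledTree(tree_id, parent, edge_label, ordered=ordered)


def star_tree(labels, tree_id="star", ordered=True) -> LabeledTree:
    """Root with one leaf child per label, in the given sibling order."""
    parent = {v: 1 for v in range(2, len(labels) + 2)}
    edge_label = {v: lab for v, lab in zip(range(2, len(labels) + 2), labels)}
    return LabeledTree(tree_id, parent, edge_label, ordered=ordered,
                       child_order={1: list(range(2, len(labels) + 2))})


def random_instance(seed: int, max_vertices: int = 8,
                    labels=("a", "b")) -> tuple[list[LabeledTree], str]:
    """1-2 random trees plus an alternating mode, fully seed-determined."""
    rng = np.random.default_rng(seed)
    n_trees = int(rng.integers(1, 3))
    trees = []
    for i in range(n_trees):
        nv = int(rng.integers(2, max_vertices))
        cfg = GeneratorConfig(n_vertices=nv, max_degree=3, labels=tuple(labels),
                              seed=seed)
        trees.append(random_tree(cfg, f"r{seed}_{i}", rng))
    mode = "ordered" if seed % 2 == 0 else "unordered"
    return trees, mode


@pytest.fixture(scope="session")
def fig5_trees():
    from treegram import load_fixture_trees

    return load_fixture_trees("fig5")


@pytest.fixture(scope="session")
def fig11_tree():
    from treegram import load_fixture_trees

    return load_fixture_trees("fig11")[0]


@pytest.fixture(scope="session")
def t3_tree():
    from treegram import load_fixture_trees

    return load_fixture_trees("t3")[0]
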