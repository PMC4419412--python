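"""Brute-force minimum oracle, random tree generators, and in-text fixtures.

The oracle restates the IP combinatorially: find the smallest set of
isomorphism classes U' that contains all forced classes (untagged leaf
edges, tagged edges into internal children, whole trees) such that every
forced occurrence is *constructible* — a base occurrence is constructible
outright; a larger one needs at least one bisection whose two part
occurrences have classes in U' and are themselves constructible.  The
search enumerates candidate class subsets by increasing size, so the first
hit is the exact minimum.  It is exponential and guarded to tiny instances;
it exists to certify the IP, never to replace it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tree_core import (
    DEFAULT_DEGREE_CAP,
    IsoClassTable,
    LabeledTree,
    SubtreeRef,
    enumerate_splits,
    ref_is_base,
)

__all__ = [
    "GeneratorConfig",
    "OracleGuardError",
    "oracle_min_nonterminals",
    "random_tree",
    "sample_related_trees",
    "fixtures",
]

ORACLE_EDGE_GUARD = 10


class OracleGuardError(ValueError):
    """Instance too large for exhaustive search."""


def oracle_min_nonterminals(trees: Sequence[LabeledTree], mode: str,
                            guard: int = ORACLE_EDGE_GUARD) -> int:
    """Exact minimum number of nonterminal symbols by exhaustive search.

    Independent of the IP machinery: uses only occurrence enumeration and
    split enumeration.  Refuses instances with more than ``guard`` total
    edges.
    """
    total_edges = sum(t.n_edges for t in trees)
    if total_edges > guard:
        raise OracleGuardError(
            f"{total_edges} total edges exceed the oracle guard ({guard})")
    table = IsoClassTable(trees, mode)

    # forced occurrences: every single edge (RNC) and every whole tree
    forced_refs: list[SubtreeRef] = []
    for alpha, tree in enumerate(trees):
        for i in tree.vertices:
            for j in tree.ch(i):
                if mode == "ordered":
                    sel: object = (tree.child_position(j), tree.child_position(j))
                else:
                    sel = frozenset([j])
                tag = j if tree.is_internal(j) else None
                forced_refs.append(SubtreeRef(alpha, i, tag, sel))  # type: ignore[arg-type]
        forced_refs.append(tree.whole_ref(alpha, mode))
    forced_keys = frozenset(table.key_of[r] for r in forced_refs)

    # precompute splits with part class keys
    split_info: dict[SubtreeRef, list[tuple[SubtreeRef, SubtreeRef, str, str]]] = {}
    for ref in table.key_of:
        tree = trees[ref.alpha]
        if ref_is_base(tree, ref):
            continue
        split_info[ref] = [
            (sp.first, sp.second, table.key_of[sp.first], table.key_of[sp.second])
            for sp in enumerate_splits(tree, ref)]

    targets = [r for r in forced_refs if not ref_is_base(trees[r.alpha], r)]
    extras = [k for k in table.keys if k not in forced_keys]

    def feasible(allowed: frozenset[str]) -> bool:
        memo: dict[SubtreeRef, bool] = {}

        def constructible(ref: SubtreeRef) -> bool:
            got = memo.get(ref)
            if got is not None:
                return got
            if ref not in split_info:  # base
                memo[ref] = True
                return True
            ok = any(k1 in allowed and k2 in allowed
                     and constructible(r1) and constructible(r2)
                     for r1, r2, k1, k2 in split_info[ref])
            memo[ref] = ok
            return ok

        return all(constructible(r) for r in targets)

    for n_extra in range(len(extras) + 1):
        for combo in itertools.combinations(extras, n_extra):
            if feasible(forced_keys | frozenset(combo)):
                return len(forced_keys) + n_extra
    raise AssertionError("all-classes set must be feasible")  # pragma: no cover


# ---------------------------------------------------------------------------
# synthetic trees
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Parameters of the synthetic generators; the seed fully determines output.

    Defaults emulate small glycan-like trees: a handful of vertices, branch
    factor capped well below the subset-enumeration limit, and a small label
    alphabet so that subtree classes actually repeat between trees.
    """

    n_trees: int = 3
    n_vertices: int = 6
    max_degree: int = 3
    labels: tuple[str, ...] = ("a", "b")
    ordered: bool = True
    seed: int = 0
    # shared-grammar mode: number of composite rules to sample and the
    # probability that a sampled rule is a vertical (rather than horizontal)
    # bisection
    shared_rules: int = 4
    p_vertical: float = 0.4

    def __post_init__(self) -> None:
        if self.n_vertices < 2:
            raise ValueError("trees need at least 2 vertices (1 edge)")
        if self.max_degree < 1:
            raise ValueError("max_degree must be >= 1")
        if self.max_degree > DEFAULT_DEGREE_CAP:
            raise ValueError(f"max_degree above the degree cap {DEFAULT_DEGREE_CAP}")
        if not self.labels:
            raise ValueError("empty label alphabet")


def random_tree(config: GeneratorConfig, tree_id: str = "synthetic",
                rng: np.random.Generator | None = None) -> LabeledTree:
    """Uniform-attachment random tree respecting the degree cap.

    Each new vertex attaches to a uniformly chosen existing vertex that
    still has room; labels are i.i.d. from the alphabet.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_vertices
    if (n - 1) > config.max_degree * max(1, n - 1):  # pragma: no cover
        raise ValueError("degree capacity cannot host the requested edges")
    parent: dict[int, int] = {}
    degree = {1: 0}
    for v in range(2, n + 1):
        avail = [u for u in degree if degree[u] < config.max_degree]
        if not avail:
            raise ValueError("degree constraints make the tree impossible")
        p = int(avail[rng.integers(len(avail))])
        parent[v] = p
        degree[p] += 1
        degree[v] = 0
    labels = {v: str(config.labels[rng.integers(len(config.labels))])
              for v in parent}
    return LabeledTree(tree_id, parent, labels, ordered=config.ordered)


# -- shared-grammar sampling -------------------------------------------------

# sampled classes are derived-edge structures: (label, children, tagged)

def _struct_edges(edges: tuple) -> int:
    return sum(1 + (_struct_edges(kids) if not tagged else 0)
               for _, kids, tagged in edges)


def _struct_tagged(edges: tuple) -> bool:
    return any(tagged or _struct_tagged(kids) for _, kids, tagged in edges)


def _subst(edges: tuple, lower: tuple) -> tuple:
    out = []
    for lab, kids, tagged in edges:
        if tagged:
            out.append((lab, lower, False))
        else:
            out.append((lab, _subst(kids, lower), False))
    return tuple(out)


@dataclass
class _SampledRule:
    kind: str
    parts: tuple[int, ...]  # indices into the class list; () for RNC
    label: str | None = None


def sample_related_trees(config: GeneratorConfig,
                         ) -> tuple[list[LabeledTree], int]:
    """Sample a random grammar and derive N trees sharing its rules.

    Returns the trees together with the number of grammar rules reachable
    from the chosen start symbols — an upper bound on the minimum number of
    nonterminal symbols for the tree set, because the sampled derivations
    exhibit a feasible rule assignment of exactly that many classes.
    """
    rng = np.random.default_rng(config.seed)
    structs: list[tuple] = []
    rules: list[_SampledRule] = []
    untagged: list[int] = []
    tagged: list[int] = []

    for lab in config.labels:
        structs.append(((str(lab), (), False),))
        rules.append(_SampledRule("RNC", (), str(lab)))
        untagged.append(len(structs) - 1)
    for lab in config.labels:
        structs.append(((str(lab), (), True),))
        rules.append(_SampledRule("RNC", (), str(lab)))
        tagged.append(len(structs) - 1)

    def top_degree(s: tuple) -> int:
        return len(s)

    for _ in range(config.shared_rules):
        make_vertical = bool(tagged) and rng.random() < config.p_vertical
        if make_vertical:
            up = int(tagged[rng.integers(len(tagged))])
            want_tagged = rng.random() < 0.3
            pool = tagged if (want_tagged and tagged) else untagged
            lo = int(pool[rng.integers(len(pool))])
            struct = _subst(structs[up], structs[lo])
            rule = _SampledRule("RVB", (up, lo))
        else:
            pool_first = untagged + tagged
            a = int(pool_first[rng.integers(len(pool_first))])
            # at most one part of a horizontal bisection may carry the tag
            pool_b = untagged if _struct_tagged(structs[a]) else untagged + tagged
            b = int(pool_b[rng.integers(len(pool_b))])
            struct = structs[a] + structs[b]
            if top_degree(struct) > config.max_degree:
                continue
            rule = _SampledRule("RHB", (a, b))
        if _struct_edges(struct) > 3 * config.n_vertices:
            continue
        structs.append(struct)
        rules.append(rule)
        (tagged if _struct_tagged(struct) else untagged).append(len(structs) - 1)

    composite_untagged = [i for i in untagged if rules[i].kind != "RNC"]
    pool = composite_untagged or untagged
    starts = [int(pool[rng.integers(len(pool))]) for _ in range(config.n_trees)]

    reachable: set[int] = set()
    stack = list(starts)
    while stack:
        i = stack.pop()
        if i in reachable:
            continue
        reachable.add(i)
        stack.extend(rules[i].parts)

    trees = []
    for n, idx in enumerate(starts):
        trees.append(_struct_to_tree(structs[idx], f"related{n + 1}",
                                     config.ordered))
    return trees, len(reachable)


def _struct_to_tree(edges: tuple, tree_id: str, ordered: bool) -> LabeledTree:
    parent: dict[int, int] = {}
    label: dict[int, str] = {}
    order: dict[int, list[int]] = {1: []}
    counter = [1]

    def walk(kids: tuple, p: int) -> None:
        for lab, sub, tagged_flag in kids:
            counter[0] += 1
            v = counter[0]
            parent[v] = p
            label[v] = lab
            order.setdefault(p, []).append(v)
            order.setdefault(v, [])
            walk(sub, v)

    walk(edges, 1)
    return LabeledTree(tree_id, parent, label, ordered=ordered,
                       child_order={v: tuple(c) for v, c in order.items()})


# ---------------------------------------------------------------------------
# in-text fixtures
# ---------------------------------------------------------------------------

def fixtures() -> dict:
    """Named transcriptions of the worked examples used throughout the tests.

    Tree shapes are transcribed from drawings (see the shipped JSON data
    files); the transcriptions are validated against the printed optima (7
    rules / grammar size 11 for the three-tree set; 3 nonterminals for the
    multiple-optima example) before anything else trusts them.
    """
    from .io_formats import load_fixture_trees

    figs = {name: load_fixture_trees(name) for name in ("fig5", "fig11", "t3")}
    return {
        "fig5": figs["fig5"],
        "fig11": figs["fig11"][0],
        "t3": figs["t3"][0],
        "cfg_small": [("S", ("a", "S", "b")), ("S", ("a", "b"))],
        "cfg_chain": [("S", ("a", "X", "b")), ("X", ("a", "Y", "b")),
                      ("Y", ("a", "b"))],
    }
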