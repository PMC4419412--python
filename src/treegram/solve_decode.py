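"""Solving the IP, decoding the grammar, and verifying its derivations.

A solved model is turned into an explicit bisection-type tree grammar: one
production rule per used isomorphism class — RNC for single (possibly
tagged) edges, RHB for horizontal bisections, RVB for vertical ones — plus
one start symbol per input tree.  The verifier then re-derives every tree
from its start symbol with derivation machinery that is independent of the
IP (it only walks the rule list), and compares Euler strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence, Union

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .ipmodel import IPModel
from .tree_core import (
    TAG_TOKEN,
    IsoClassTable,
    LabeledTree,
    SubtreeRef,
    _token_rank,
    canonical_string_unordered,
    close_token,
    euler_string,
    key_edge_count,
    key_is_tagged,
    open_token,
    string_key,
)

__all__ = [
    "SolveError",
    "IntegrityError",
    "Solution",
    "solve",
    "register_backend",
    "Rule",
    "Grammar",
    "decode_grammar",
    "grammar_size",
    "derive_and_verify",
]


class SolveError(RuntimeError):
    """Solver failed (infeasible, unbounded, or backend error)."""


class IntegrityError(RuntimeError):
    """Solution violates the formulation's support structure (solver numerics)."""


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

@dataclass
class Solution:
    """Outcome of a MILP solve: proven-optimal flag, objective, assignment."""

    objective: int
    values: np.ndarray
    optimal: bool
    status: str
    backend: str

    def is_active(self, idx: int) -> bool:
        return self.values[idx] > 0.5  # frozen read-back tolerance


def _solve_scipy_highs(model: IPModel, time_limit: float | None) -> Solution:
    c, A, clb, cub, integrality, lb, ub = model.to_arrays()
    options: dict = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(c, constraints=LinearConstraint(A, clb, cub),
               integrality=integrality, bounds=Bounds(lb, ub), options=options)
    if res.status == 2:
        raise SolveError("model reported infeasible (should not happen: every "
                         "instance admits the all-classes grammar)")
    if res.x is None:
        if res.status == 1:
            return Solution(-1, np.array([]), False, "time_limit", "scipy-highs")
        raise SolveError(f"solver failed: status {res.status} ({res.message})")
    optimal = res.status == 0
    return Solution(int(round(res.fun)), np.asarray(res.x), optimal,
                    "optimal" if optimal else "time_limit", "scipy-highs")


_BACKENDS: dict[str, Callable[[IPModel, float | None], Solution]] = {
    "scipy-highs": _solve_scipy_highs,
    "highs": _solve_scipy_highs,
}


def register_backend(name: str,
                     fn: Callable[[IPModel, float | None], Solution]) -> None:
    """Plug in an alternative MILP backend (must prove optimality)."""
    _BACKENDS[name] = fn


def solve(model: IPModel, backend: str = "scipy-highs",
          time_limit: float | None = None) -> Solution:
    """Solve a built model to proven optimality.

    The objective value (number of nonterminal symbols) is backend-
    independent; if the time limit strikes first the solution is flagged
    non-optimal and must not be decoded as a minimum grammar.
    """
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise SolveError(f"unknown backend {backend!r}; available: "
                         f"{sorted(set(_BACKENDS))}") from None
    return fn(model, time_limit)


# ---------------------------------------------------------------------------
# grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    """One production rule; the left-hand side is an isomorphism-class key.

    ``RNC`` rewrites a nonterminal into a terminal edge (``label``); ``RHB``
    glues the two right-hand-side classes at a shared root; ``RVB`` attaches
    the second class's root at the first class's tag vertex.  Whether a
    right-hand-side part carries a tag is encoded in its class key.
    """

    lhs_key: str
    kind: str                      # 'RNC' | 'RHB' | 'RVB'
    rhs_keys: tuple[str, ...]      # () for RNC, (first, second) otherwise
    label: str | None = None       # terminal symbol of an RNC rule
    tagged_lhs: bool = False

    @property
    def rhs_size(self) -> int:
        """Number of symbols on the right-hand side (1 for RNC, 2 otherwise)."""
        return 1 if self.kind == "RNC" else 2


@dataclass
class Grammar:
    """Decoded bisection-type tree grammar with named start symbols."""

    mode: str
    terminals: frozenset[str]
    rules: dict[str, Rule]                 # class key -> its single rule
    start: dict[str, str]                  # tree_id -> class key
    names: dict[str, str]                  # class key -> display name
    annotations: dict[str, list[dict]] = field(default_factory=dict)

    @property
    def nonterminals(self) -> list[str]:
        return list(self.rules)

    def size(self) -> int:
        return grammar_size(self)

    def rule_lines(self) -> list[str]:
        """Human-readable one-rule-per-line rendering."""
        out = []
        for key, rule in self.rules.items():
            lhs = self.names[key]
            if rule.kind == "RNC":
                tag = " [tagged]" if rule.tagged_lhs else ""
                out.append(f"{lhs} -> edge({rule.label}){tag}")
            else:
                a, b = (self.names[k] for k in rule.rhs_keys)
                out.append(f"{lhs} -> {rule.kind}({a}, {b})")
        return out


def grammar_size(rules: Union[Grammar, Iterable]) -> int:
    """Total number of symbols on rule right-hand sides.

    Accepts a decoded :class:`Grammar` (RNC counts 1, bisections count 2) or
    any iterable of ``(lhs, rhs_sequence)`` pairs, e.g. a plain CFG given as
    ``[("S", "aSb"), ("S", "ab")]`` — whose size is 5.
    """
    if isinstance(rules, Grammar):
        return sum(r.rhs_size for r in rules.rules.values())
    total = 0
    for _, rhs in rules:
        total += len(rhs)
    return total


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _occurrence_edge_vertices(tree: LabeledTree, ref: SubtreeRef) -> list[int]:
    """Non-root vertices of an occurrence == its covered edges."""
    from .tree_core import selected_children

    out: list[int] = []
    stack = list(selected_children(tree, ref))
    while stack:
        v = stack.pop()
        out.append(v)
        if v != ref.tag:
            stack.extend(tree.ch(v))
    return sorted(out)


def decode_grammar(solution: Solution, model: IPModel) -> Grammar:
    """Turn a proven-optimal solution into an explicit grammar.

    For every used class the rule is chosen among the active bisections of
    its constructed occurrences by a frozen tie-break: smallest total source
    edge count, then lexicographic on the pair of source class keys (several
    minimum grammars may exist; the choice only fixes which one is printed).
    """
    if not solution.optimal:
        raise SolveError("refusing to decode a non-optimal solution")
    table: IsoClassTable = model.meta["class_table"]
    trees: list[LabeledTree] = model.meta["trees"]
    x_of: dict[SubtreeRef, int] = model.meta["x_of"]
    p_of: dict[str, int] = model.meta["p_of"]
    supports = model.meta["supports"]

    used = [k for k in table.keys if solution.is_active(p_of[k])]
    rules: dict[str, Rule] = {}
    annotations: dict[str, list[dict]] = {}
    for key in used:
        active_occ = [r for r in table.occurrences[key]
                      if solution.is_active(x_of[r])]
        annotations[key] = [
            {"tree_id": trees[r.alpha].tree_id, "root": r.i,
             "tag": r.tag,
             "children": sorted(r.sel) if isinstance(r.sel, frozenset)
             else list(r.sel),
             "edge_vertices": _occurrence_edge_vertices(trees[r.alpha], r)}
            for r in active_occ]
        if key_edge_count(key) == 1:
            label = key.split()[0]
            rules[key] = Rule(key, "RNC", (), label, key_is_tagged(key))
            continue
        candidates: list[tuple[int, tuple[str, str], str]] = []
        for ref in active_occ:
            found = False
            for sp, vidx in supports.get(ref, []):
                if solution.is_active(vidx):
                    found = True
                    k1 = table.key_of[sp.first]
                    k2 = table.key_of[sp.second]
                    kind = "RHB" if sp.kind == "H" else "RVB"
                    candidates.append(
                        (key_edge_count(k1) + key_edge_count(k2), (k1, k2), kind))
            if not found:
                raise IntegrityError(
                    f"constructed occurrence {ref} of class {key!r} has no "
                    f"active bisection (solver numerics?)")
        if not candidates:
            raise IntegrityError(f"used class {key!r} has no constructed occurrence")
        candidates.sort(key=lambda c: (c[0], c[1]))
        _, (k1, k2), kind = candidates[0]
        rules[key] = Rule(key, kind, (k1, k2), None, key_is_tagged(key))

    start: dict[str, str] = {}
    names: dict[str, str] = {}
    for alpha, tree in enumerate(trees):
        key = table.key_of[tree.whole_ref(alpha, model.mode)]
        start[tree.tree_id] = key
        names.setdefault(key, f"S{alpha + 1}")
    n_base = n_comp = 0
    for key in used:
        if key in names:
            continue
        if key_edge_count(key) == 1:
            n_base += 1
            names[key] = f"A{n_base}"
        else:
            n_comp += 1
            names[key] = f"U{n_comp}"

    terminals = frozenset(r.label for r in rules.values() if r.kind == "RNC")
    return Grammar(mode=model.mode, terminals=terminals, rules=rules,
                   start=start, names=names, annotations=annotations)


# ---------------------------------------------------------------------------
# derivation & verification
# ---------------------------------------------------------------------------

# a derived (sub)tree is a tuple of edges; an edge is (label, children, tagged)
_Edges = tuple

def _substitute_tag(edges: _Edges, lower: _Edges) -> tuple[_Edges, int]:
    out = []
    hits = 0
    for lab, kids, tagged in edges:
        if tagged:
            out.append((lab, lower, False))
            hits += 1
        else:
            kids2, h = _substitute_tag(kids, lower)
            out.append((lab, kids2, False))
            hits += h
    return tuple(out), hits


def _edges_tokens(edges: _Edges, canonical: bool) -> list[str]:
    pieces = []
    for lab, kids, tagged in edges:
        body = [TAG_TOKEN] if tagged else _edges_tokens(kids, canonical)
        pieces.append([open_token(lab)] + body + [close_token(lab)])
    if canonical:
        pieces.sort(key=lambda p: [_token_rank(t) for t in p])
    return [t for p in pieces for t in p]


def derive_and_verify(grammar: Grammar, trees: Sequence[LabeledTree]) -> dict:
    """Expand every start symbol bottom-up and compare against the inputs.

    Every rule is also checked individually: the tree derived from its
    left-hand side must reproduce the class key (ordered mode: the Euler
    string; unordered mode: the canonical string).  The derivation machinery
    is independent of the IP and of the tree indexing, so a decoding bug
    cannot hide from this check.
    """
    canonical = grammar.mode == "unordered"
    memo: dict[str, _Edges] = {}
    visiting: set[str] = set()

    def derive(key: str) -> _Edges:
        if key in memo:
            return memo[key]
        if key in visiting:
            raise IntegrityError(f"cyclic rule dependency at class {key!r}")
        visiting.add(key)
        rule = grammar.rules.get(key)
        if rule is None:
            raise IntegrityError(f"no rule for class {key!r}")
        if rule.kind == "RNC":
            edges: _Edges = ((rule.label, (), rule.tagged_lhs),)
        elif rule.kind == "RHB":
            edges = derive(rule.rhs_keys[0]) + derive(rule.rhs_keys[1])
        else:  # RVB
            upper = derive(rule.rhs_keys[0])
            lower = derive(rule.rhs_keys[1])
            edges, hits = _substitute_tag(upper, lower)
            if hits != 1:
                raise IntegrityError(
                    f"RVB upper part of {key!r} carries {hits} tags, expected 1")
        visiting.discard(key)
        memo[key] = edges
        return edges

    rule_failures: dict[str, dict] = {}
    for key in grammar.rules:
        derived = string_key(_edges_tokens(derive(key), canonical))
        if derived != key:
            rule_failures[key] = {"expected": key, "derived": derived}

    per_tree: dict[str, dict] = {}
    canon = canonical_string_unordered if canonical else euler_string
    for alpha, tree in enumerate(trees):
        expected = string_key(canon(tree, tree.whole_ref(alpha, grammar.mode)))
        key = grammar.start.get(tree.tree_id)
        if key is None:
            per_tree[tree.tree_id] = {"ok": False, "expected": expected,
                                      "derived": None}
            continue
        derived = string_key(_edges_tokens(derive(key), canonical))
        per_tree[tree.tree_id] = {"ok": derived == expected,
                                  "expected": expected, "derived": derived}

    all_ok = not rule_failures and all(r["ok"] for r in per_tree.values())
    return {
        "all_ok": all_ok,
        "per_tree": per_tree,
        "rule_failures": rule_failures,
        "nonterminals": {grammar.names[k]: k for k in grammar.rules},
        "annotations": grammar.annotations,
    }
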