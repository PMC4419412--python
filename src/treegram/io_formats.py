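"""Parsers (KCF glycans, RNA dot-bracket) and native JSON serialization.

Glycans arrive as KEGG KCF records: vertex-labeled trees whose vertices are
monosaccharides.  They become *unordered* edge-labeled trees, each edge
taking the label of its lower vertex (the root's label is dropped, linkage
annotations are discarded).

RNA secondary structures arrive as sequence + dot-bracket.  Every base pair
becomes a vertex whose parent is the innermost enclosing pair; a virtual
root sits above the outermost pairs so that every pair survives the
vertex-to-edge label transformation.  Edges are labeled with the two-base
token of the child pair (5' base first, e.g. ``GC``) and ordered 5'→3',
giving an *ordered* tree.  Unpaired bases are dropped; pseudoknots are
rejected.

The native JSON formats for trees and grammars round-trip exactly and are
validated field by field with JSON-path error messages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

from .solve_decode import Grammar, Rule
from .tree_core import LabeledTree, TreeError, edge_labels_from_vertices

__all__ = [
    "ValidationError",
    "KcfError",
    "PseudoknotError",
    "KcfRecord",
    "SecondaryStructure",
    "parse_kcf_record",
    "parse_kcf",
    "parse_dotbracket",
    "tree_to_dict",
    "tree_from_dict",
    "save_trees",
    "load_trees",
    "load_fixture_trees",
    "grammar_to_dict",
    "grammar_from_dict",
    "grammar_to_text",
    "save_grammar",
    "load_grammar",
]

TREE_FORMAT = "treegram-tree"
GRAMMAR_FORMAT = "treegram-grammar"


class ValidationError(ValueError):
    """Native JSON does not conform to the schema; message carries the path."""


class KcfError(ValueError):
    """Malformed KCF record."""


class PseudoknotError(ValueError):
    """Crossing base pairs: pseudoknotted structures are unsupported."""


# ---------------------------------------------------------------------------
# native JSON trees
# ---------------------------------------------------------------------------

def _expect(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{path}: {msg}")


def tree_to_dict(tree: LabeledTree) -> dict:
    return {
        "format": TREE_FORMAT,
        "version": 1,
        "tree_id": tree.tree_id,
        "ordered": tree.ordered,
        "parent": {str(v): p for v, p in sorted(tree.parent.items())},
        "edge_label": {str(v): l for v, l in sorted(tree.edge_label.items())},
        "child_order": {str(v): list(tree.ch(v)) for v in tree.vertices
                        if tree.ch(v)},
    }


def tree_from_dict(d: object, path: str = "$") -> LabeledTree:
    _expect(isinstance(d, dict), path, "expected an object")
    assert isinstance(d, dict)
    _expect(d.get("format") == TREE_FORMAT, f"{path}.format",
            f"expected {TREE_FORMAT!r}")
    for fieldname, typ in (("tree_id", str), ("ordered", bool),
                           ("parent", dict), ("edge_label", dict)):
        _expect(fieldname in d, f"{path}.{fieldname}", "missing required field")
        _expect(isinstance(d[fieldname], typ), f"{path}.{fieldname}",
                f"expected {typ.__name__}")
    parent: dict[int, int] = {}
    for k, v in d["parent"].items():
        _expect(k.isdigit() and isinstance(v, int), f"{path}.parent.{k}",
                "vertex ids must be integers")
        parent[int(k)] = v
    edge_label: dict[int, str] = {}
    for k, v in d["edge_label"].items():
        _expect(k.isdigit() and isinstance(v, str), f"{path}.edge_label.{k}",
                "expected string label keyed by integer vertex")
        edge_label[int(k)] = v
    child_order = None
    if "child_order" in d and d["child_order"] is not None:
        _expect(isinstance(d["child_order"], dict), f"{path}.child_order",
                "expected object")
        child_order = {}
        for k, seq in d["child_order"].items():
            _expect(k.isdigit() and isinstance(seq, list), f"{path}.child_order.{k}",
                    "expected list keyed by integer vertex")
            child_order[int(k)] = [int(c) for c in seq]
    try:
        return LabeledTree(d["tree_id"], parent, edge_label,
                           ordered=d["ordered"], child_order=child_order)
    except TreeError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def save_trees(trees: Sequence[LabeledTree], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([tree_to_dict(t) for t in trees], fh, indent=1)
        fh.write("\n")


def load_trees(path: str) -> list[LabeledTree]:
    """Load one tree or a list of trees from a native JSON file."""
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        return [tree_from_dict(data)]
    _expect(isinstance(data, list), "$", "expected an object or a list")
    return [tree_from_dict(d, f"$[{n}]") for n, d in enumerate(data)]


def load_fixture_trees(name: str) -> list[LabeledTree]:
    """Load a shipped fixture file (``fig5``, ``fig11``, ``t3``) by name."""
    text = (resources.files("treegram.data") / f"{name}.json").read_text()
    data = json.loads(text)
    if isinstance(data, dict):
        return [tree_from_dict(data)]
    return [tree_from_dict(d, f"$[{n}]") for n, d in enumerate(data)]


# ---------------------------------------------------------------------------
# native JSON grammars
# ---------------------------------------------------------------------------

def grammar_to_dict(g: Grammar) -> dict:
    return {
        "format": GRAMMAR_FORMAT,
        "version": 1,
        "mode": g.mode,
        "terminals": sorted(g.terminals),
        "start": dict(g.start),
        "names": dict(g.names),
        "rules": [
            {"lhs_key": r.lhs_key, "kind": r.kind,
             "rhs_keys": list(r.rhs_keys), "label": r.label,
             "tagged_lhs": r.tagged_lhs}
            for r in g.rules.values()],
        "annotations": g.annotations,
    }


def grammar_from_dict(d: object, path: str = "$") -> Grammar:
    _expect(isinstance(d, dict), path, "expected an object")
    assert isinstance(d, dict)
    _expect(d.get("format") == GRAMMAR_FORMAT, f"{path}.format",
            f"expected {GRAMMAR_FORMAT!r}")
    for fieldname, typ in (("mode", str), ("terminals", list),
                           ("start", dict), ("names", dict), ("rules", list)):
        _expect(fieldname in d, f"{path}.{fieldname}", "missing required field")
        _expect(isinstance(d[fieldname], typ), f"{path}.{fieldname}",
                f"expected {typ.__name__}")
    rules: dict[str, Rule] = {}
    for n, rd in enumerate(d["rules"]):
        rp = f"{path}.rules[{n}]"
        _expect(isinstance(rd, dict), rp, "expected an object")
        for fieldname in ("lhs_key", "kind", "rhs_keys", "tagged_lhs"):
            _expect(fieldname in rd, f"{rp}.{fieldname}", "missing required field")
        _expect(rd["kind"] in ("RNC", "RHB", "RVB"), f"{rp}.kind",
                "expected RNC, RHB, or RVB")
        rules[rd["lhs_key"]] = Rule(
            rd["lhs_key"], rd["kind"], tuple(rd["rhs_keys"]),
            rd.get("label"), bool(rd["tagged_lhs"]))
    return Grammar(mode=d["mode"], terminals=frozenset(d["terminals"]),
                   rules=rules, start=dict(d["start"]), names=dict(d["names"]),
                   annotations=dict(d.get("annotations", {})))


def grammar_to_text(g: Grammar) -> str:
    """One rule per line, start symbols listed first."""
    header = ["# start symbols: "
              + ", ".join(f"{tid} -> {g.names[k]}" for tid, k in g.start.items()),
              f"# terminals: {', '.join(sorted(g.terminals))}",
              f"# size: {g.size()}"]
    return "\n".join(header + g.rule_lines()) + "\n"


def save_grammar(g: Grammar, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(grammar_to_dict(g), fh, indent=1)
        fh.write("\n")


def load_grammar(path: str) -> Grammar:
    with open(path) as fh:
        return grammar_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# KCF glycan records
# ---------------------------------------------------------------------------

@dataclass
class KcfRecord:
    """Raw content of one KCF record: nodes with coordinates, edges with
    linkage annotations (annotations are kept here but dropped in the tree)."""

    entry: str
    nodes: dict[int, tuple[str, float, float]]      # id -> (name, x, y)
    edges: list[tuple[int, int, str, str]]          # (child, parent, anomer, position)


def _split_endpoint(token: str) -> tuple[int, str]:
    node, _, ann = token.partition(":")
    if not node.lstrip("-").isdigit():
        raise KcfError(f"bad EDGE endpoint {token!r}")
    return int(node), ann


def parse_kcf_record(text: str) -> KcfRecord:
    entry = ""
    nodes: dict[int, tuple[str, float, float]] = {}
    edges: list[tuple[int, int, str, str]] = []
    block = None
    expected = {"NODE": 0, "EDGE": 0}
    for raw in text.splitlines():
        if raw.startswith("///"):
            break
        if not raw.strip():
            continue
        if raw[0] not in " \t":  # new block keyword at column 0
            head, _, body = raw.strip().partition(" ")
            body = body.strip()
            block = head
            if head == "ENTRY":
                entry = body.split()[0] if body else ""
                continue
            if head in ("NODE", "EDGE"):
                try:
                    expected[head] = int(body.split()[0])
                except (ValueError, IndexError):
                    raise KcfError(f"bad {head} count line: {raw!r}") from None
                continue
            continue
        fields = raw.split()
        if block == "NODE":
            if len(fields) < 4:
                raise KcfError(f"bad NODE line: {raw!r}")
            try:
                nid = int(fields[0])
                x, y = float(fields[2]), float(fields[3])
            except ValueError:
                raise KcfError(f"bad NODE line: {raw!r}") from None
            if nid in nodes:
                raise KcfError(f"duplicate NODE id {nid} in line {raw!r}")
            nodes[nid] = (fields[1], x, y)
        elif block == "EDGE":
            if len(fields) < 3:
                raise KcfError(f"bad EDGE line: {raw!r}")
            child, anomer = _split_endpoint(fields[1])
            par, pos = _split_endpoint(fields[2])
            edges.append((child, par, anomer, pos))
    if expected["NODE"] and expected["NODE"] != len(nodes):
        raise KcfError(f"NODE count {expected['NODE']} != {len(nodes)} node lines")
    if expected["EDGE"] and expected["EDGE"] != len(edges):
        raise KcfError(f"EDGE count {expected['EDGE']} != {len(edges)} edge lines")
    return KcfRecord(entry, nodes, edges)


def parse_kcf(text: str, tree_id: str | None = None) -> LabeledTree:
    """KCF record -> unordered edge-labeled tree.

    The first endpoint of an EDGE line is the child (nonreducing side); the
    root is the node never appearing on the child side, ties broken by
    maximal x coordinate (the reducing end is drawn rightmost in KCF).
    """
    rec = parse_kcf_record(text)
    if len(rec.nodes) < 2:
        raise KcfError(f"record {rec.entry!r} has {len(rec.nodes)} nodes; "
                       "need at least 2 to form an edge-labeled tree")
    for n, (child, par, _, _) in enumerate(rec.edges):
        for endpoint in (child, par):
            if endpoint not in rec.nodes:
                raise KcfError(f"EDGE line {n + 1} references unknown node "
                               f"{endpoint}")
    children_side = {c for c, _, _, _ in rec.edges}
    seen: set[int] = set()
    parent: dict[int, int] = {}
    for n, (child, par, _, _) in enumerate(rec.edges):
        if child in seen:
            raise KcfError(f"EDGE line {n + 1}: node {child} already has a parent")
        seen.add(child)
        parent[child] = par
    candidates = [v for v in rec.nodes if v not in children_side]
    if not candidates:
        raise KcfError(f"record {rec.entry!r}: EDGE block forms a cycle "
                       "(every node appears on the child side)")
    root = max(candidates, key=lambda v: rec.nodes[v][1])
    if len(candidates) > 1:
        others = sorted(set(candidates) - {root})
        raise KcfError(f"record {rec.entry!r}: disconnected nodes {others} "
                       f"(root resolved to {root} by max x)")
    labels = {v: name for v, (name, _, _) in rec.nodes.items()}
    try:
        return edge_labels_from_vertices(tree_id or rec.entry or "kcf",
                                         parent, labels, ordered=False)
    except TreeError as exc:
        raise KcfError(f"record {rec.entry!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# RNA dot-bracket
# ---------------------------------------------------------------------------

@dataclass
class SecondaryStructure:
    """Sequence, dot-bracket string, and the derived base-pair list."""

    sequence: str
    structure: str
    pairs: list[tuple[int, int]]  # 0-based, i < j


def _pair_list(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for n, c in enumerate(structure):
        if c == "(":
            stack.append(n)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced structure: unmatched ')' at {n}")
            pairs.append((stack.pop(), n))
        elif c == ".":
            continue
        elif c in "[]{}<>":
            raise PseudoknotError(
                f"bracket {c!r} at position {n}: pseudoknots are unsupported "
                "(only '()' pairs and '.' are accepted)")
        else:
            raise ValueError(f"invalid structure character {c!r} at {n}")
    if stack:
        raise ValueError(f"unbalanced structure: unmatched '(' at {stack[-1]}")
    pairs.sort()
    return pairs


def parse_dotbracket(sequence: str, structure: str,
                     tree_id: str = "rna") -> LabeledTree:
    """Sequence + dot-bracket -> ordered base-pair tree.

    A virtual root is always added above the outermost pairs so every base
    pair contributes one labeled edge; edge labels are the two paired bases,
    5' base first.
    """
    sequence = sequence.strip().upper().replace("T", "U")
    structure = structure.strip()
    if len(sequence) != len(structure):
        raise ValueError(f"sequence length {len(sequence)} != structure "
                         f"length {len(structure)}")
    pairs = _pair_list(structure)
    if not pairs:
        raise ValueError("structure contains no base pair: the tree would "
                         "have no edges")
    ss = SecondaryStructure(sequence, structure, pairs)

    # pair -> vertex; parent = innermost enclosing pair, else the virtual root
    parent: dict[int, int] = {}
    labels: dict[int, str] = {}
    order: dict[int, list[int]] = {1: []}
    enclosing: list[tuple[int, int]] = []  # stack of (close_pos, vertex)
    for n, (i, j) in enumerate(ss.pairs):
        v = n + 2  # vertex 1 is the virtual root
        while enclosing and enclosing[-1][0] < j:
            enclosing.pop()
        p = enclosing[-1][1] if enclosing else 1
        parent[v] = p
        labels[v] = sequence[i] + sequence[j]
        order.setdefault(p, []).append(v)
        order.setdefault(v, [])
        enclosing.append((j, v))
    return LabeledTree(tree_id, parent, labels, ordered=True,
                       child_order={v: tuple(c) for v, c in order.items()})
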