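"""Edge-labeled rooted trees, subtree references, and Euler-string canonicalization.

The objects compressed by the grammar machinery are rooted trees whose *edges*
carry labels (a glycan tree labels each edge with the monosaccharide at its
lower end; an RNA base-pair tree labels each edge with a base pair such as
``GC``).  A bisection-type tree grammar never talks about whole trees directly
but about *subtree occurrences*: a root vertex, a contiguous range (ordered
trees) or a subset (unordered trees) of its children, and optionally a *tag*
vertex below which the subtree is cut off and marked as an attachment point.

Isomorphism classes of those occurrences are keyed by Euler strings: the
sequence of edge labels emitted on descent and their barred counterparts on
ascent during a depth-first traversal.  Two ordered trees are isomorphic
exactly when their Euler strings coincide; for unordered trees a canonical
child order (sorted recursively) makes the same test work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence, Union

__all__ = [
    "TreeError",
    "DegreeCapError",
    "LabeledTree",
    "SubtreeRef",
    "Split",
    "IsoClassTable",
    "TAG_TOKEN",
    "open_token",
    "close_token",
    "edge_labels_from_vertices",
    "euler_string",
    "canonical_string_unordered",
    "string_key",
    "key_edge_count",
    "key_is_tagged",
    "enumerate_refs",
    "enumerate_splits",
    "build_class_table",
    "DEFAULT_DEGREE_CAP",
]

TAG_TOKEN = "τ"
DEFAULT_DEGREE_CAP = 8


class TreeError(ValueError):
    """Invalid tree structure or invalid subtree reference."""


class DegreeCapError(TreeError):
    """Unordered subset enumeration refused: vertex degree exceeds the cap.

    Enumerating child subsets of a vertex with degree d creates 2^d - 1
    references; the cap guards against this exponential blow-up.
    """


def open_token(label: str) -> str:
    return label


def close_token(label: str) -> str:
    return "/" + label


def _check_label(label: str) -> str:
    if not isinstance(label, str) or not label:
        raise TreeError(f"edge label must be a nonempty string, got {label!r}")
    if any(c.isspace() for c in label) or label.startswith("/") or label == TAG_TOKEN:
        raise TreeError(
            f"edge label {label!r} invalid: whitespace, leading '/', and the "
            f"tag symbol {TAG_TOKEN!r} are reserved"
        )
    return label


class LabeledTree:
    """Rooted tree with one labeled edge into every non-root vertex.

    Vertices are renumbered in preorder at construction, the root being 1,
    so equal structures always present identical vertex numbering.  Ordered
    trees keep the given left-to-right child order; unordered trees keep a
    deterministic storage order (the order is ignored by the unordered
    canonicalization and IP construction).

    Parameters
    ----------
    tree_id:
        Identifier of the tree (the alpha of multi-tree formulations).
    parent:
        Mapping child-vertex -> parent-vertex; the root appears only as a
        parent.  Vertex names may be arbitrary ints; they are renumbered.
    edge_label:
        Mapping child-vertex -> label of its incoming edge.
    ordered:
        Whether sibling order is significant.
    child_order:
        Optional mapping vertex -> sequence of its children fixing sibling
        order; defaults to ascending original vertex number.
    """

    __slots__ = ("tree_id", "ordered", "parent", "children", "edge_label",
                 "_anc", "_subtree_edges", "_pre")

    def __init__(
        self,
        tree_id: str,
        parent: Mapping[int, int],
        edge_label: Mapping[int, str],
        ordered: bool = True,
        child_order: Mapping[int, Sequence[int]] | None = None,
    ) -> None:
        if not parent:
            raise TreeError("single-vertex trees are invalid: a grammar over "
                            "edges cannot generate a tree with no edge")
        verts = set(parent) | set(parent.values())
        roots = sorted(v for v in verts if v not in parent)
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {roots}")
        root = roots[0]
        if set(edge_label) != set(parent):
            raise TreeError("edge_label keys must be exactly the non-root vertices")
        for v, lab in edge_label.items():
            _check_label(lab)

        raw_children: dict[int, list[int]] = {v: [] for v in verts}
        for c, p in parent.items():
            raw_children[p].append(c)
        if child_order is not None:
            for v, seq in child_order.items():
                if sorted(seq) != sorted(raw_children.get(v, [])):
                    raise TreeError(f"child_order for vertex {v} does not match parent map")
                raw_children[v] = list(seq)
        else:
            for v in raw_children:
                raw_children[v].sort()

        # preorder renumbering, root -> 1; also detects cycles/disconnection
        order: list[int] = []
        stack = [root]
        seen: set[int] = set()
        while stack:
            v = stack.pop()
            if v in seen:
                raise TreeError("cycle detected in parent map")
            seen.add(v)
            order.append(v)
            stack.extend(reversed(raw_children[v]))
        if len(order) != len(verts):
            raise TreeError("disconnected vertices in parent map")
        renum = {old: i + 1 for i, old in enumerate(order)}

        self.tree_id = str(tree_id)
        self.ordered = bool(ordered)
        self.parent = {renum[c]: renum[p] for c, p in parent.items()}
        self.children = {renum[v]: tuple(renum[c] for c in raw_children[v])
                         for v in verts}
        self.edge_label = {renum[c]: edge_label[c] for c in parent}

        anc: dict[int, frozenset[int]] = {1: frozenset()}
        for v in range(2, len(verts) + 1):
            anc[v] = anc[self.parent[v]] | {self.parent[v]}
        self._anc = anc
        sub: dict[int, int] = {}
        for v in reversed(range(1, len(verts) + 1)):
            sub[v] = sum(sub[c] + 1 for c in self.children[v])
        self._subtree_edges = sub
        self._pre = tuple(range(1, len(verts) + 1))

    # -- indexing -----------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.children)

    @property
    def n_edges(self) -> int:
        return len(self.parent)

    @property
    def vertices(self) -> tuple[int, ...]:
        return self._pre

    def ch(self, v: int) -> tuple[int, ...]:
        return self.children[v]

    def lch(self, v: int) -> int:
        return self.children[v][0]

    def rch(self, v: int) -> int:
        return self.children[v][-1]

    def anc(self, v: int) -> frozenset[int]:
        """Proper ancestors of v (root has none; v is never its own ancestor)."""
        return self._anc[v]

    def subtree_edges(self, v: int) -> int:
        """Number of edges strictly below v (== number of proper descendants)."""
        return self._subtree_edges[v]

    def is_internal(self, v: int) -> bool:
        """Internal = has at least one child (leaf otherwise)."""
        return bool(self.children[v])

    def child_position(self, v: int) -> int:
        """1-based sibling position of non-root vertex v."""
        return self.children[self.parent[v]].index(v) + 1

    # -- equality is by shape: same ordered Euler string --------------------

    def whole_ref(self, alpha: int = 0, mode: str | None = None) -> "SubtreeRef":
        """The occurrence covering the entire tree (root's full child range
        or child set, depending on ``mode``; defaults to the tree's flavor)."""
        if mode is None:
            mode = "ordered" if self.ordered else "unordered"
        if mode == "ordered":
            sel: Union[tuple[int, int], frozenset[int]] = (1, len(self.children[1]))
        else:
            sel = frozenset(self.children[1])
        return SubtreeRef(alpha=alpha, i=1, tag=None, sel=sel)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "ordered" if self.ordered else "unordered"
        return f"<LabeledTree {self.tree_id!r} {kind} {self.n_edges} edges>"


@dataclass(frozen=True)
class SubtreeRef:
    """A (possibly tagged) subtree occurrence.

    ``alpha`` indexes the tree in the input list; ``i`` is the root vertex of
    the occurrence; ``sel`` selects children of ``i`` — a 1-based inclusive
    sibling-position range ``(h, k)`` for ordered trees, a nonempty frozenset
    of child vertices for unordered trees.  The occurrence consists of ``i``,
    the selected children and all their descendants.  If ``tag`` is a vertex,
    everything strictly below it is removed and the vertex is marked as the
    attachment point of a vertical bisection.
    """

    alpha: int
    i: int
    tag: int | None
    sel: Union[tuple[int, int], frozenset[int]]

    @property
    def is_ordered_sel(self) -> bool:
        return isinstance(self.sel, tuple)

    def sort_key(self) -> tuple:
        if isinstance(self.sel, tuple):
            s: tuple = self.sel
        else:
            s = tuple(sorted(self.sel))
        return (self.alpha, self.i, s, -1 if self.tag is None else self.tag)


def _validate_ref(tree: LabeledTree, ref: SubtreeRef) -> None:
    deg = len(tree.ch(ref.i))
    if deg == 0:
        raise TreeError(f"vertex {ref.i} has no children; not a subtree root")
    if isinstance(ref.sel, tuple):
        h, k = ref.sel
        if not (1 <= h <= k <= deg):
            raise TreeError(f"invalid sibling range {ref.sel} at vertex {ref.i}")
    else:
        if not ref.sel or not ref.sel <= set(tree.ch(ref.i)):
            raise TreeError(f"invalid child subset {set(ref.sel)} at vertex {ref.i}")
    if ref.tag is not None:
        if ref.tag not in _internal_of_untagged(tree, ref.i, ref.sel):
            raise TreeError(
                f"tag {ref.tag} is not an internal vertex of the untagged subtree")


def selected_children(tree: LabeledTree, ref: SubtreeRef) -> tuple[int, ...]:
    if isinstance(ref.sel, tuple):
        h, k = ref.sel
        return tree.ch(ref.i)[h - 1:k]
    return tuple(sorted(ref.sel))


def _internal_of_untagged(tree: LabeledTree, i: int,
                          sel: Union[tuple[int, int], frozenset[int]]) -> set[int]:
    """Internal vertices of the untagged occurrence: in it, below i, with children."""
    out: set[int] = set()
    stack = list(selected_children(tree, SubtreeRef(0, i, None, sel)))
    while stack:
        v = stack.pop()
        if tree.is_internal(v):
            out.add(v)
            stack.extend(tree.ch(v))
    return out


def ref_edge_count(tree: LabeledTree, ref: SubtreeRef) -> int:
    total = sum(tree.subtree_edges(c) + 1 for c in selected_children(tree, ref))
    if ref.tag is not None:
        total -= tree.subtree_edges(ref.tag)
    return total


def ref_is_base(tree: LabeledTree, ref: SubtreeRef) -> bool:
    """Base occurrences are single (possibly tagged) edges, generated by RNC."""
    return ref_edge_count(tree, ref) == 1


# ---------------------------------------------------------------------------
# Euler strings
# ---------------------------------------------------------------------------

def _emit(tree: LabeledTree, v: int, tag: int | None, out: list[str],
          sort_children: bool) -> None:
    lab = tree.edge_label[v]
    out.append(open_token(lab))
    if v == tag:
        out.append(TAG_TOKEN)
    else:
        _body(tree, v, tree.ch(v), tag, out, sort_children)
    out.append(close_token(lab))


def _token_rank(tok: str) -> tuple:
    # frozen total order for canonical sorting: the tag symbol precedes every
    # label-derived token; remaining tokens compare lexicographically
    return (0,) if tok == TAG_TOKEN else (1, tok)


def _body(tree: LabeledTree, v: int, kids: Sequence[int], tag: int | None,
          out: list[str], sort_children: bool) -> None:
    if not sort_children:
        for c in kids:
            _emit(tree, c, tag, out, sort_children)
        return
    pieces: list[list[str]] = []
    for c in kids:
        buf: list[str] = []
        _emit(tree, c, tag, buf, sort_children)
        pieces.append(buf)
    pieces.sort(key=lambda p: [_token_rank(t) for t in p])
    for p in pieces:
        out.extend(p)


def euler_string(tree: LabeledTree, ref: SubtreeRef) -> tuple[str, ...]:
    """Euler string of an occurrence: open label on descent, close on ascent.

    The tagged edge emits ``label τ /label`` with no descent below the tag.
    Sibling order is the tree's order; equality of Euler strings is ordered
    isomorphism of (tagged) occurrences.
    """
    _validate_ref(tree, ref)
    out: list[str] = []
    for c in selected_children(tree, ref):
        _emit(tree, c, ref.tag, out, sort_children=False)
    return tuple(out)


def canonical_string_unordered(tree: LabeledTree, ref: SubtreeRef) -> tuple[str, ...]:
    """Canonical Euler string: children sorted recursively by their strings.

    Invariant under any permutation of children at any vertex, so equality is
    unordered isomorphism of (tagged) occurrences.  The tag symbol sorts
    before every label token (frozen tie-break).
    """
    _validate_ref(tree, ref)
    out: list[str] = []
    _body(tree, ref.i, selected_children(tree, ref), ref.tag, out,
          sort_children=True)
    return tuple(out)


def string_key(tokens: Iterable[str]) -> str:
    """Serialize a token sequence to a hashable class key (space-joined;
    labels may be multi-character, so tokens are never concatenated)."""
    return " ".join(tokens)


def key_edge_count(key: str) -> int:
    toks = key.split()
    return sum(1 for t in toks if not t.startswith("/") and t != TAG_TOKEN)


def key_is_tagged(key: str) -> bool:
    return TAG_TOKEN in key.split()


# ---------------------------------------------------------------------------
# transformation from vertex-labeled trees
# ---------------------------------------------------------------------------

def edge_labels_from_vertices(
    tree_id: str,
    parent: Mapping[int, int],
    vertex_label: Mapping[int, str],
    ordered: bool = False,
    child_order: Mapping[int, Sequence[int]] | None = None,
) -> LabeledTree:
    """Turn a vertex-labeled rooted tree into an edge-labeled one.

    Each edge takes the label of its lower (child-side) vertex; the root's
    own label is discarded.  This is the standard transformation for glycans,
    where every vertex is a monosaccharide and the bond inherits the name of
    the sugar it attaches.
    """
    if not parent:
        raise TreeError("vertex-labeled tree must have at least 2 vertices "
                        "(the root label alone cannot survive the transformation)")
    edge_label = {}
    for child in parent:
        if child not in vertex_label:
            raise TreeError(f"vertex {child} has no label")
        edge_label[child] = vertex_label[child]
    return LabeledTree(tree_id, parent, edge_label, ordered=ordered,
                       child_order=child_order)


# ---------------------------------------------------------------------------
# occurrence and split enumeration
# ---------------------------------------------------------------------------

def enumerate_refs(tree: LabeledTree, alpha: int = 0, mode: str | None = None,
                   degree_cap: int = DEFAULT_DEGREE_CAP) -> list[SubtreeRef]:
    """All subtree occurrences of a tree, untagged and tagged, in a
    deterministic order.

    Ordered mode: every contiguous sibling range at every vertex.  Unordered
    mode: every nonempty child subset at every vertex (vertices whose degree
    exceeds ``degree_cap`` raise :class:`DegreeCapError`).  Each untagged
    occurrence additionally yields one tagged occurrence per internal vertex.
    """
    if mode is None:
        mode = "ordered" if tree.ordered else "unordered"
    if mode not in ("ordered", "unordered"):
        raise ValueError(f"unknown mode {mode!r}")
    refs: list[SubtreeRef] = []
    for i in tree.vertices:
        kids = tree.ch(i)
        if not kids:
            continue
        sels: list[Union[tuple[int, int], frozenset[int]]] = []
        if mode == "ordered":
            d = len(kids)
            for h in range(1, d + 1):
                for k in range(h, d + 1):
                    sels.append((h, k))
        else:
            d = len(kids)
            if d > degree_cap:
                raise DegreeCapError(
                    f"vertex {i} of tree {tree.tree_id!r} has degree {d} > cap "
                    f"{degree_cap}: unordered subset enumeration would create "
                    f"2^{d}-1 references (exponential blow-up)")
            ordered_kids = sorted(kids)
            for mask in range(1, 1 << d):
                subset = frozenset(ordered_kids[b] for b in range(d)
                                   if mask >> b & 1)
                sels.append(subset)
            sels.sort(key=lambda s: (len(s), tuple(sorted(s))))  # type: ignore[arg-type]
        for sel in sels:
            refs.append(SubtreeRef(alpha, i, None, sel))
            for t in sorted(_internal_of_untagged(tree, i, sel)):
                refs.append(SubtreeRef(alpha, i, t, sel))
    return refs


@dataclass(frozen=True)
class Split:
    """One bisection of an occurrence into two smaller occurrences.

    ``kind`` is ``"H"`` (horizontal: the root's selected children are split
    in two) or ``"V"`` (vertical: the occurrence is cut at internal vertex
    ``t``; the upper part is tagged at ``t`` and the lower part is the full
    subtree hanging below ``t``).  For tagged horizontal splits the part
    carrying the tag is whichever of ``first``/``second`` has a tag.
    """

    kind: str
    first: SubtreeRef
    second: SubtreeRef
    at: Union[int, frozenset[int]]  # H: split position l / untagged subset; V: vertex t


def _position_of_ancestor_child(tree: LabeledTree, i: int, t: int) -> int:
    """The child of i on the path from i down to t."""
    v = t
    while tree.parent[v] != i:
        v = tree.parent[v]
    return v


def enumerate_splits(tree: LabeledTree, ref: SubtreeRef) -> list[Split]:
    """All bisections of a non-base occurrence.

    These are exactly the right-hand-side candidates of RHB/RVB rules and the
    index domains of the y (horizontal) and z (vertical) IP variables.
    """
    if ref_is_base(tree, ref):
        return []
    out: list[Split] = []
    a, i, tag = ref.alpha, ref.i, ref.tag
    if isinstance(ref.sel, tuple):
        h, k = ref.sel
        tag_child = (_position_of_ancestor_child(tree, i, tag)
                     if tag is not None else None)
        tag_pos = (tree.child_position(tag_child) if tag_child is not None else None)
        for l in range(h, k):
            if tag is None:
                out.append(Split("H", SubtreeRef(a, i, None, (h, l)),
                                 SubtreeRef(a, i, None, (l + 1, k)), l))
            elif tag_pos is not None and tag_pos >= l + 1:
                out.append(Split("H", SubtreeRef(a, i, None, (h, l)),
                                 SubtreeRef(a, i, tag, (l + 1, k)), l))
            else:
                out.append(Split("H", SubtreeRef(a, i, tag, (h, l)),
                                 SubtreeRef(a, i, None, (l + 1, k)), l))
        if tag is None:
            for t in sorted(_internal_of_untagged(tree, i, ref.sel)):
                out.append(Split(
                    "V", SubtreeRef(a, i, t, ref.sel),
                    SubtreeRef(a, t, None, (1, len(tree.ch(t)))), t))
        else:
            cands = sorted(tree.anc(tag) & _internal_of_untagged(tree, i, ref.sel))
            for t in cands:
                out.append(Split(
                    "V", SubtreeRef(a, i, t, ref.sel),
                    SubtreeRef(a, t, tag, (1, len(tree.ch(t)))), t))
    else:
        C = ref.sel
        kids = sorted(C)
        d = len(kids)
        pivot = kids[0]  # dedup: the part containing the smallest child is 'first'
        tag_child = (_position_of_ancestor_child(tree, i, tag)
                     if tag is not None else None)
        for mask in range(0, 1 << (d - 1)):
            first = frozenset([pivot] + [kids[b + 1] for b in range(d - 1)
                                         if mask >> b & 1])
            if len(first) == d:
                continue
            second = C - first
            if tag is None:
                out.append(Split("H", SubtreeRef(a, i, None, first),
                                 SubtreeRef(a, i, None, second), first))
            else:
                # single orientation: the untagged side is recorded in `at`
                if tag_child in first:
                    out.append(Split("H", SubtreeRef(a, i, tag, first),
                                     SubtreeRef(a, i, None, second), second))
                else:
                    out.append(Split("H", SubtreeRef(a, i, None, first),
                                     SubtreeRef(a, i, tag, second), first))
        if tag is None:
            for t in sorted(_internal_of_untagged(tree, i, C)):
                out.append(Split(
                    "V", SubtreeRef(a, i, t, C),
                    SubtreeRef(a, t, None, frozenset(tree.ch(t))), t))
        else:
            for t in sorted(tree.anc(tag) & _internal_of_untagged(tree, i, C)):
                out.append(Split(
                    "V", SubtreeRef(a, i, t, C),
                    SubtreeRef(a, t, tag, frozenset(tree.ch(t))), t))
    return out


# ---------------------------------------------------------------------------
# isomorphism-class table
# ---------------------------------------------------------------------------

class IsoClassTable:
    """The set U of Euler-string classes over all occurrences of all trees.

    ``key_of`` maps every occurrence to its class key; ``occurrences`` maps
    each class key to its occurrence list; ``keys`` is the deterministic
    class order (by edge count, then key) used for IP variable naming.
    """

    def __init__(self, trees: Sequence[LabeledTree], mode: str,
                 degree_cap: int = DEFAULT_DEGREE_CAP) -> None:
        if not trees:
            raise TreeError("empty tree set")
        if mode not in ("ordered", "unordered"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.trees = list(trees)
        self.key_of: dict[SubtreeRef, str] = {}
        self.occurrences: dict[str, list[SubtreeRef]] = {}
        canon = euler_string if mode == "ordered" else canonical_string_unordered
        for alpha, tree in enumerate(trees):
            for ref in enumerate_refs(tree, alpha, mode, degree_cap):
                key = string_key(canon(tree, ref))
                self.key_of[ref] = key
                self.occurrences.setdefault(key, []).append(ref)
        self.keys: list[str] = sorted(self.occurrences,
                                      key=lambda k: (key_edge_count(k), k))
        self.index: dict[str, int] = {k: n for n, k in enumerate(self.keys)}

    def __len__(self) -> int:
        return len(self.keys)

    def tree_of(self, ref: SubtreeRef) -> LabeledTree:
        return self.trees[ref.alpha]

    def edge_count(self, key: str) -> int:
        return key_edge_count(key)

    def whole_tree_keys(self) -> list[str]:
        return [self.key_of[t.whole_ref(a, self.mode)]
                for a, t in enumerate(self.trees)]


def build_class_table(trees: Sequence[LabeledTree], mode: str,
                      degree_cap: int = DEFAULT_DEGREE_CAP) -> IsoClassTable:
    """Build the class set U for a tree collection (see :class:`IsoClassTable`)."""
    return IsoClassTable(trees, mode, degree_cap)
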