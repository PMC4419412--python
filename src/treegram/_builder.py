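"""Shared constraint-generation core for the ordered and unordered IPs.

Both formulations have the same skeleton, differing only in how child
selections and horizontal splits are indexed (contiguous sibling ranges vs
child subsets):

* base equalities — every leaf edge (untagged) and every edge into an
  internal child (tagged at that child) is always constructed, by an RNC
  rule; every whole tree must be constructed;
* support constraints — a constructed occurrence with >= 2 edges must be
  produced by at least one active horizontal (y) or vertical (z) bisection;
* bisection bounds — y or z may be active only if both source occurrences
  are constructed (coefficient 1/2 form, as is conventional for and-linking
  of binaries);
* class linkage — s_u is the mean of the construction indicators over the
  occurrences of class u, and p_u = 1 exactly when s_u > 0.  The strict
  inequality is linearized as s_u <= p_u together with p_u <= sum of the
  occurrence indicators, which preserves the iff semantics for any solver.

The objective minimizes the number of classes used, i.e. the number of
distinct nonterminal symbols of the decoded grammar.
"""

from __future__ import annotations

from typing import Sequence, Union

from .ipmodel import IPModel
from .tree_core import (
    DEFAULT_DEGREE_CAP,
    IsoClassTable,
    LabeledTree,
    Split,
    SubtreeRef,
    TreeError,
    enumerate_splits,
    ref_is_base,
)

__all__ = ["build_model"]


def _sel_tag(sel: Union[tuple[int, int], frozenset[int]]) -> str:
    if isinstance(sel, tuple):
        return f"h{sel[0]}_k{sel[1]}"
    return "c" + "-".join(str(v) for v in sorted(sel))


def _xname(ref: SubtreeRef) -> str:
    t = "eps" if ref.tag is None else str(ref.tag)
    return f"x_a{ref.alpha}_i{ref.i}_t{t}_{_sel_tag(ref.sel)}"


def _yname(ref: SubtreeRef, sp: Split) -> str:
    t = "eps" if ref.tag is None else str(ref.tag)
    if isinstance(ref.sel, tuple):
        at = f"l{sp.at}"
    else:
        at = "s" + "-".join(str(v) for v in sorted(sp.at))  # type: ignore[arg-type]
    return f"y_a{ref.alpha}_i{ref.i}_t{t}_{_sel_tag(ref.sel)}_{at}"


def _zname(ref: SubtreeRef, sp: Split) -> str:
    t = "eps" if ref.tag is None else str(ref.tag)
    return f"z_a{ref.alpha}_i{ref.i}_t{t}_{_sel_tag(ref.sel)}_v{sp.at}"


def build_model(
    trees: Sequence[LabeledTree],
    mode: str,
    keep_s: bool = True,
    degree_cap: int = DEFAULT_DEGREE_CAP,
) -> IPModel:
    """Construct the minimum-grammar IP for a tree collection.

    Parameters
    ----------
    trees:
        Nonempty collection of trees, each with at least one edge.
    mode:
        ``"ordered"`` (sibling ranges, Euler-string classes) or
        ``"unordered"`` (child subsets, canonical-string classes).
    keep_s:
        Keep the continuous class-mean variables s_u explicit (the printed
        form of the formulation).  With ``False`` they are substituted away,
        yielding an equivalent, slightly smaller model.
    degree_cap:
        Refuse unordered vertices with more children than this.
    """
    if not trees:
        raise TreeError("empty tree set")
    for t in trees:
        if t.n_edges < 1:  # unreachable through LabeledTree, kept as a contract
            raise TreeError(f"tree {t.tree_id!r} has no edges")
    table = IsoClassTable(trees, mode, degree_cap)
    model = IPModel(mode=mode)

    x_of: dict[SubtreeRef, int] = {}
    for ref in table.key_of:
        x_of[ref] = model.add_var(_xname(ref), "x", meta=ref)

    # base equalities: RNC-constructed single edges, and the whole trees
    for alpha, tree in enumerate(trees):
        for i in tree.vertices:
            for j in tree.ch(i):
                if mode == "ordered":
                    sel: Union[tuple[int, int], frozenset[int]] = (
                        tree.child_position(j), tree.child_position(j))
                else:
                    sel = frozenset([j])
                if tree.is_internal(j):
                    ref = SubtreeRef(alpha, i, j, sel)
                    fam = "eq2"
                else:
                    ref = SubtreeRef(alpha, i, None, sel)
                    fam = "eq1"
                model.add_constr(f"{fam}_{_xname(ref)}", fam,
                                 [(1.0, x_of[ref])], "=", 1.0)
        whole = tree.whole_ref(alpha, mode)
        model.add_constr(f"eq3_a{alpha}", "eq3", [(1.0, x_of[whole])], "=", 1.0)

    # support constraints and bisection bounds
    supports: dict[SubtreeRef, list[tuple[Split, int]]] = {}
    for ref in table.key_of:
        tree = trees[ref.alpha]
        if ref_is_base(tree, ref):
            continue
        terms = [(1.0, x_of[ref])]
        entries: list[tuple[Split, int]] = []
        for sp in enumerate_splits(tree, ref):
            if sp.kind == "H":
                v = model.add_var(_yname(ref, sp), "y", meta=(ref, sp))
                if ref.tag is None:
                    fam = "eq5"
                elif mode == "unordered":
                    fam = "eq8"  # single orientation stands for both tagged variants
                else:
                    fam = "eq8" if sp.second.tag is not None else "eq9"
            else:
                v = model.add_var(_zname(ref, sp), "z", meta=(ref, sp))
                fam = "eq6" if ref.tag is None else "eq10"
            model.add_constr(f"{fam}_{model.variables[v].name}", fam,
                             [(1.0, v), (-0.5, x_of[sp.first]),
                              (-0.5, x_of[sp.second])], "<=", 0.0)
            terms.append((-1.0, v))
            entries.append((sp, v))
        supports[ref] = entries
        fam = "eq4" if ref.tag is None else "eq7"
        model.add_constr(f"{fam}_{_xname(ref)}", fam, terms, "<=", 0.0)

    # class linkage and objective
    p_of: dict[str, int] = {}
    for n, key in enumerate(table.keys):
        p = model.add_var(f"p_u{n}", "p", meta=key)
        p_of[key] = p
        occ = table.occurrences[key]
        m = len(occ)
        if keep_s:
            s = model.add_var(f"s_u{n}", "s", integer=False, meta=key)
            model.add_constr(f"eq12_u{n}", "eq12",
                             [(1.0, s)] + [(-1.0 / m, x_of[r]) for r in occ],
                             "=", 0.0)
            model.add_constr(f"eq11a_u{n}", "eq11a",
                             [(1.0, s), (-1.0, p)], "<=", 0.0)
        else:
            model.add_constr(f"eq11a_u{n}", "eq11a",
                             [(-1.0, p)] + [(1.0 / m, x_of[r]) for r in occ],
                             "<=", 0.0)
        model.add_constr(f"eq11b_u{n}", "eq11b",
                         [(1.0, p)] + [(-1.0, x_of[r]) for r in occ],
                         "<=", 0.0)
    model.set_objective([(1.0, p_of[k]) for k in table.keys])

    model.meta.update(class_table=table, x_of=x_of, p_of=p_of,
                      supports=supports, keep_s=keep_s, trees=list(trees))
    return model
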