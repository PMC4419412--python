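"""MinSEUTGMul: the minimum-grammar integer program for unordered trees.

The unordered analogue of the ordered formulation replaces contiguous
sibling ranges with child subsets C ⊆ ch(α,i): base equalities range over
singletons {j}, the whole-tree equality over ch(α,1), and horizontal splits
over unordered partitions {C', C−C'} of each subset.  Because the trees are
unordered, the two tagged orientations of a horizontal split describe the
same production rule, so a single y variable is generated per partition,
its untagged side recorded in the variable name.  Isomorphism classes are
keyed by the canonical (child-sorted) Euler string instead of the plain one.

Subset enumeration is exponential in vertex degree; vertices above the
configured degree cap are refused with an explicit error.
"""

from __future__ import annotations

from typing import Sequence

from ._builder import build_model
from .ipmodel import IPModel
from .solve_decode import solve
from .tree_core import DEFAULT_DEGREE_CAP, LabeledTree

__all__ = ["build_minseutgmul", "compare_modes"]


def build_minseutgmul(trees: Sequence[LabeledTree], keep_s: bool = True,
                      degree_cap: int = DEFAULT_DEGREE_CAP) -> IPModel:
    """Build the unordered-tree minimum-grammar IP for one or more trees."""
    return build_model(trees, "unordered", keep_s=keep_s, degree_cap=degree_cap)


def compare_modes(trees: Sequence[LabeledTree], backend: str = "scipy-highs",
                  ) -> tuple[int, int]:
    """Solve the same trees as ordered and as unordered; return both optima.

    Treating the trees as unordered can only merge isomorphism classes and
    enlarge the set of admissible splits, so the unordered optimum never
    exceeds the ordered one.
    """
    from .ip_ordered import build_minseotgmul

    ordered_opt = solve(build_minseotgmul(trees), backend=backend).objective
    unordered_opt = solve(build_minseutgmul(trees), backend=backend).objective
    return ordered_opt, unordered_opt
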