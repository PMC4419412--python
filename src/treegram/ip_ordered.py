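"""MinSEOTGMul: the minimum-grammar integer program for ordered trees.

Variables (all binary except the continuous class means s):

* ``x[α,i,t,h,k]`` — the occurrence rooted at vertex i of tree α with
  sibling range [h,k] and optional tag t is constructed;
* ``y[α,i,t,h,l,k]`` — it is built by a horizontal bisection at split
  position l (RHB rule);
* ``z[α,i,t,h,k,w]`` — it is built by a vertical bisection at internal
  vertex w (RVB rule);
* ``s_u``, ``p_u`` — class u has a positive construction mean / appears as a
  nonterminal of the grammar.

The objective minimizes Σ p_u, the number of distinct nonterminal symbols.
Support constraints are emitted only for occurrences with at least two
edges; single (possibly tagged) edges are fixed to 1 and realized by RNC
rules, so they need no bisection.
"""

from __future__ import annotations

from typing import Sequence

from ._builder import build_model
from .ipmodel import IPModel
from .tree_core import LabeledTree

__all__ = ["build_minseotgmul", "model_stats"]


def build_minseotgmul(trees: Sequence[LabeledTree], keep_s: bool = True) -> IPModel:
    """Build the ordered-tree minimum-grammar IP for one or more trees.

    Returns an :class:`~treegram.ipmodel.IPModel` whose ``meta`` carries the
    class table and the variable-to-occurrence dictionaries needed to decode
    a solved model into an explicit grammar.
    """
    return build_model(trees, "ordered", keep_s=keep_s)


def model_stats(model: IPModel) -> dict[str, dict[str, int]]:
    """Exact variable counts by kind and constraint counts by family."""
    return model.stats()
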