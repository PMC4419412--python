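# Methods

## Problem

Given N edge-labeled rooted trees — glycans (each edge labeled with the
monosaccharide at its lower end) or RNA base-pair trees (each edge labeled
with a base pair, siblings ordered 5'→3') — find the *minimum* bisection-type
tree grammar generating all of them: a Simple Elementary Ordered Tree Grammar
(SEOTG) for ordered trees, a Simple Elementary Unordered Tree Grammar (SEUTG)
for unordered ones.  Rules come in three kinds: **RNC** (a nonterminal
rewrites to a single terminal edge, possibly tag-marked), **RHB** (horizontal
bisection: two parts share the root), and **RVB** (vertical bisection: the
second part's root attaches at the first part's tag vertex).  Because every
nonterminal has exactly one rule, minimizing the number of distinct
nonterminal symbols is the same as minimizing the number of rules; grammar
*size* (total right-hand-side symbols) is then #RNC + 2·(#RHB + #RVB).

The minimum is found exactly by integer programming, which is appropriate
because the underlying smallest-grammar problems are NP-hard and exact
optima are the quantity of scientific interest (shared rules between trees).

## The integer programs

A *subtree occurrence* is a root vertex i, a selection of its children
(a contiguous sibling range [h,k] for ordered trees, a nonempty subset C for
unordered ones), all their descendants, and optionally a *tag* vertex below
which the occurrence is truncated.  Occurrences are grouped into isomorphism
classes keyed by Euler strings — edge labels emitted on descent, barred on
ascent; a tagged edge emits `label τ /label`.  For unordered trees the class
key is the canonical string obtained by recursively sorting children by
their strings (any frozen total order works; here the tag symbol sorts
before every label token).

Binary variables: x (occurrence constructed), y (constructed by a horizontal
split at position l / partition {C', C−C'}), z (constructed by a vertical
cut at internal vertex t), p (class used).  Continuous s ∈ [0,1] is the mean
of x over a class's occurrences.  Constraints:

* every leaf edge is constructed untagged, every edge into an internal child
  is constructed tagged at that child (these are the RNC-realized base
  occurrences), and every whole tree is constructed;
* each constructed occurrence with ≥ 2 edges needs at least one active y/z;
* y ≤ ½(x_first + x_second) and z ≤ ½(x_upper + x_lower) — a bisection is
  available only if both sources are constructed;
* s_u ≤ p_u and p_u ≤ Σ x over the class's occurrences.  The intended
  semantics is "p_u = 1 iff any occurrence of u is constructed"; this pair
  expresses it exactly in MILP form without relying on the objective
  direction (the textbook strict inequality p_u < 1 + s_u is not
  MILP-expressible as written).

The objective minimizes Σ p_u.  Two deliberate domain restrictions:

* **Support constraints apply only to occurrences with ≥ 2 edges.**  Taking
  the quantifier domains literally would force `x ≤ 0` for single-edge
  occurrences (the split sums are empty) and contradict the base
  equalities — every instance, even a single edge, would be infeasible.
  Single edges are RNC-constructed and need no bisection.
* **Unordered tagged horizontal splits are generated once per partition.**
  The two tagged orientations of {C', C−C'} describe the same unordered
  rule; emitting both would only add a symmetric duplicate binary.

With `keep_s=False` the s variables are substituted away
((1/m)·Σx ≤ p), an equivalent and slightly smaller model; the explicit form
is the default for fidelity to the published system and auditability of the
LP/MPS exports.

## Solving and decoding

The backend contract is any MILP solver that proves optimality; the default
is HiGHS through `scipy.optimize.milp` (single-threaded, hence
deterministic; it exposes no RNG seed, so the package's seeds govern only
the synthetic generators).  Read-back of binaries uses a frozen 0.5
threshold.

Decoding emits one rule per used class: base classes become RNC rules;
every other class picks, among the *active* y/z of its constructed
occurrences, the bisection whose source classes have the smallest total
edge count, ties broken lexicographically on the pair of class keys.
Minimum grammars are generally not unique (the three-leaf `a,a,a` star
already has two, differing in the first rule), so tests and the verifier
assert the objective value and regeneration, never rule identity.  An
active occurrence with no active bisection is reported as an integrity
error rather than silently patched.

The verifier re-derives every tree from its start symbol using only the
rule list (independent of the IP and of the tree indexing): RNC yields a
(possibly tagged) edge, RHB concatenates two child lists under a shared
root, RVB substitutes the lower part at the upper part's tag.  The derived
Euler string (canonical string in unordered mode) must equal the input's.

## Brute-force oracle

`oracle_min_nonterminals` restates the optimization combinatorially: the
smallest class set U' containing all forced classes such that every forced
occurrence is constructible, where constructibility of an occurrence
recurses through bisections whose part classes lie in U'.  Subsets are
enumerated by increasing cardinality, so the first feasible set is the
exact minimum.  It is exponential and guarded (default 10 total edges,
relaxed explicitly in tests to 14); it certifies the IP on hundreds of
random instances and is never used as the production path.

## Input transformations

* **KCF glycans** (unordered): the first endpoint of an EDGE line is the
  child (nonreducing side); the root is the node never appearing on the
  child side, with maximal x coordinate as tie-break (KCF draws the
  reducing end rightmost).  Vertex labels are monosaccharide names; each
  edge takes its lower vertex's label; the root label and all linkage
  annotations (anomer, position) are discarded.
* **Dot-bracket RNA** (ordered): base pairs nest into a tree (parent = the
  innermost enclosing pair); a virtual root is *always* added above the
  outermost pairs so that every pair survives as an edge — without it the
  edge-labeling transformation would silently drop the outermost pair.
  Edge labels are the two paired bases, 5' base first (`GC`, never `CG`);
  children are ordered by 5' position; unpaired bases vanish.  Only the
  plain `().` alphabet is accepted; extended brackets are rejected as
  pseudoknots.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `degree_cap` | 8 | refuse unordered subset enumeration above this vertex degree (2^d − 1 occurrences per vertex) |
| `keep_s` | `True` | keep the continuous class-mean variables explicit |
| `time_limit` | none | solver wall-clock limit, seconds; hitting it flags the result non-optimal and decoding refuses it |
| oracle `guard` | 10 | maximum total edges for the exhaustive search |
| generator `n_trees`, `n_vertices`, `max_degree`, `labels` | 3, 6, 3, `(a,b)` | synthetic instance shape |

The generator defaults are meant to emulate small glycan-like trees: a few
vertices, modest branching, and a two-letter alphabet so that subtree
classes genuinely repeat within and across trees (with large alphabets
almost every class is unique and the minimum grammar degenerates to the
forced classes).  Uniform-attachment sampling produces both paths and
bushy shapes.  What the generator does *not* emulate: realistic
monosaccharide frequencies, linkage chemistry, RNA stem-length statistics,
or any correlation between edge labels and topology.  Passing the property
suite therefore certifies the *combinatorics and the optimization* — on any
tree shape within the tested size range — but says nothing about
biological interpretation of the extracted rules.

`sample_related_trees` instead samples a random acyclic rule set and
derives several trees from it, so the trees share structure by
construction; the sampled grammar's reachable rule count is a certified
upper bound on the optimum, and comparing the combined optimum with the
sum of single-tree optima exhibits the compression gain the multi-tree
formulation exists for.

## Problem sizes and determinism

The shipped fixture set is desk-scale (3–4 edges per tree) and solves in
milliseconds.  The randomized property suite uses 200 instances of 1–2
trees with up to 6 edges each for the IP-vs-oracle equality, and 100
instances for the ordered/unordered comparison; the whole default test run
finishes in well under a minute on one CPU.  Every random draw is
seed-derived, and model construction iterates containers in frozen
deterministic orders, so identical inputs yield byte-identical grammar
JSON.

## Known limitations

* The unordered formulation is exponential in vertex degree (subsets) and
  the ordered one cubic-ish in degree (ranges × splits); very wide vertices
  are refused rather than attempted.
* Tree shapes for the two bundled worked examples exist in the source
  material only as drawings; the shipped JSON fixtures are transcriptions
  validated against the printed optima (7 nonterminals / size 11; 3
  nonterminals) and labeled as such in the files.
* The objective counts nonterminal symbols, not grammar size; the two
  coincide in ranking only because every rule contributes 1 or 2 RHS
  symbols and the RNC set is forced.  True size minimization would need a
  weighted objective and is out of scope.
* Checks against the published glycan optima (13/17/16 single, 31 combined)
  require KEGG KCF downloads and run only when those files are provided
  locally; they are not part of the default suite.
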