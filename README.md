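# treegram

Minimum bisection-type tree grammars for biomolecular trees, by integer
programming.

Glycans and pseudoknot-free RNA secondary structures are rooted trees: a
glycan's monosaccharides become edge labels, an RNA's base pairs become
edges labeled `GC`, `AU`, … ordered 5'→3'.  A *simple elementary tree
grammar* (SEOTG for ordered trees, SEUTG for unordered ones) builds such
trees from at most two symbols per rule: name-change rules (RNC, a
nonterminal becomes a terminal edge), horizontal bisections (RHB, two parts
share a root) and vertical bisections (RVB, one part attaches at the
other's tag vertex).  The *minimum* grammar generating a whole collection
of trees — the one with the fewest distinct nonterminal symbols, which
equals the fewest rules — exposes construction rules shared between the
trees, e.g. subtrees built by the same glycosyltransferase.  `treegram`
builds and solves the exact integer programs for this minimum (MinSEOTGMul
for ordered, MinSEUTGMul for unordered inputs), decodes an optimal grammar,
and verifies that it regenerates every input tree.

Minimize Σ_{u∈U} p_u over binary x (subtree occurrence constructed),
y/z (constructed by a horizontal/vertical bisection), p (isomorphism class
used), where U is the set of Euler-string classes of all subtree
occurrences; each constructed multi-edge occurrence must have an active
bisection whose two sources are constructed, and p_u switches on exactly
when some occurrence of class u is constructed.  A brute-force oracle
certifies the optimum on small instances, and every decoded grammar is
re-derived rule by rule and compared against the inputs.

## Worked example

```python
from treegram import (build_minseotgmul, solve, decode_grammar,
                      derive_and_verify, load_fixture_trees, grammar_to_text)

trees = load_fixture_trees("fig5")      # three small ordered trees
model = build_minseotgmul(trees)
solution = solve(model)                  # proven optimum via HiGHS
grammar = decode_grammar(solution, model)
print(solution.objective, grammar.size())
print(grammar_to_text(grammar))
print(derive_and_verify(grammar, trees)["all_ok"])
```

prints

```
7 11
# start symbols: T1 -> S1, T2 -> S2, T3 -> S3
# terminals: a, b
# size: 11
A1 -> edge(a)
A2 -> edge(a) [tagged]
A3 -> edge(b)
U1 -> RHB(A1, A3)
S3 -> RHB(A1, U1)
S1 -> RVB(A2, U1)
S2 -> RHB(S1, A1)
True
```

Seven nonterminals suffice for all three trees together (their single-tree
minima are 5, 6 and 4): the star `U1` and the whole of T1 are reused inside
T2 and T3, which is exactly the kind of shared construction rule the method
is after.  The grammar size 11 counts right-hand-side symbols: three RNC
rules contribute one each, four bisections two each.

The same from the shell:

```
treegram compress --format kcf --mode unordered --out grammar.json G02677.kcf G03661.kcf
treegram compress --format dotbracket structure.db
treegram oracle-check small_trees.json      # IP vs brute force
treegram simulate --seed 7 --related        # trees sharing a random grammar
```

Exit codes: 0 proven optimum and verified, 1 input error, 2 time limit.

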