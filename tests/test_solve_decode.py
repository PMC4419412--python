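"""Solver contract, grammar decoding, size accounting, derivation checks."""

from __future__ import annotations

import pytest

from treegram import (
    Grammar,
    IntegrityError,
    Rule,
    SolveError,
    build_minseotgmul,
    build_minseutgmul,
    decode_grammar,
    derive_and_verify,
    grammar_size,
    register_backend,
    solve,
)
from treegram.tree_core import TAG_TOKEN

from conftest import path_tree, random_instance, star_tree


class TestSolve:
    def test_single_edge_objective(self):
        sol = solve(build_minseotgmul([path_tree(["a"])]))
        assert sol.optimal and sol.objective == 1 and sol.status == "optimal"

    def test_two_edge_path_objective(self):
        assert solve(build_minseotgmul([path_tree(["a", "b"])])).objective == 3

    def test_unknown_backend(self):
        with pytest.raises(SolveError, match="unknown backend"):
            solve(build_minseotgmul([path_tree(["a"])]), backend="gurobi")

    def test_backend_registry(self):
        calls = []

        def fake(model, time_limit):
            calls.append(time_limit)
            return solve(model)  # delegate to the default backend

        register_backend("fake-for-test", fake)
        sol = solve(build_minseotgmul([path_tree(["a"])]),
                    backend="fake-for-test", time_limit=7.0)
        assert sol.objective == 1 and calls == [7.0]

    def test_objective_backend_invariant_under_s_substitution(self):
        for seed in (0, 1, 2):
            trees, mode = random_instance(seed)
            build = build_minseotgmul if mode == "ordered" else build_minseutgmul
            assert solve(build(trees, keep_s=True)).objective == \
                solve(build(trees, keep_s=False)).objective


class TestGrammarSize:
    def test_cfg_examples(self):
        assert grammar_size([("S", "aSb"), ("S", "ab")]) == 5
        assert grammar_size([("S", "aXb"), ("X", "aYb"), ("Y", "ab")]) == 8

    def test_empty_rule_set(self):
        assert grammar_size([]) == 0

    def test_decoded_grammar_counts_rnc_one_bisection_two(self):
        model = build_minseotgmul([path_tree(["a", "b"])])
        g = decode_grammar(solve(model), model)
        n_rnc = sum(r.kind == "RNC" for r in g.rules.values())
        n_bis = sum(r.kind != "RNC" for r in g.rules.values())
        assert g.size() == n_rnc + 2 * n_bis == 4  # RVB + two RNC


class TestDecode:
    def test_single_edge_grammar(self):
        model = build_minseotgmul([path_tree(["a"], "T")])
        g = decode_grammar(solve(model), model)
        assert len(g.rules) == 1 and g.size() == 1
        (rule,) = g.rules.values()
        assert rule.kind == "RNC" and rule.label == "a" and not rule.tagged_lhs
        assert g.names[g.start["T"]] == "S1"

    def test_two_edge_path_rules(self):
        model = build_minseotgmul([path_tree(["a", "b"], "T")])
        g = decode_grammar(solve(model), model)
        kinds = sorted(r.kind for r in g.rules.values())
        assert kinds == ["RNC", "RNC", "RVB"]
        rvb = next(r for r in g.rules.values() if r.kind == "RVB")
        assert rvb.rhs_keys[0] == f"a {TAG_TOKEN} /a"
        assert rvb.rhs_keys[1] == "b /b"
        assert g.size() == 4

    def test_rules_equal_nonterminals_equal_objective(self):
        for seed in range(12):
            trees, mode = random_instance(seed)
            build = build_minseotgmul if mode == "ordered" else build_minseutgmul
            model = build(trees)
            sol = solve(model)
            g = decode_grammar(sol, model)
            assert len(g.rules) == len(g.nonterminals) == sol.objective

    def test_refuses_nonoptimal_solution(self):
        model = build_minseotgmul([path_tree(["a"])])
        sol = solve(model)
        sol.optimal = False
        with pytest.raises(SolveError, match="non-optimal"):
            decode_grammar(sol, model)

    def test_annotations_cover_constructed_occurrences(self, fig5_trees):
        model = build_minseotgmul(fig5_trees)
        g = decode_grammar(solve(model), model)
        for key, occs in g.annotations.items():
            assert key in g.rules
            assert occs, f"used class {key!r} without any occurrence"
            for occ in occs:
                assert occ["tree_id"] in {t.tree_id for t in fig5_trees}
                assert len(occ["edge_vertices"]) >= 1


class TestDeriveAndVerify:
    def test_every_solve_verifies(self):
        for seed in range(12):
            trees, mode = random_instance(seed)
            build = build_minseotgmul if mode == "ordered" else build_minseutgmul
            model = build(trees)
            g = decode_grammar(solve(model), model)
            report = derive_and_verify(g, trees)
            assert report["all_ok"], (seed, report)

    def test_corrupted_rnc_label_fails_naming_tree(self):
        trees = [path_tree(["a", "b"], "T")]
        model = build_minseotgmul(trees)
        g = decode_grammar(solve(model), model)
        key = next(k for k, r in g.rules.items()
                   if r.kind == "RNC" and r.label == "b")
        g.rules[key] = Rule(key, "RNC", (), "zz", False)
        report = derive_and_verify(g, trees)
        assert not report["all_ok"]
        assert not report["per_tree"]["T"]["ok"]
        assert report["per_tree"]["T"]["expected"] != \
            report["per_tree"]["T"]["derived"]

    def test_cyclic_rules_raise_integrity_error(self):
        k1, k2 = "a a /a /a", "a a a /a /a /a"
        g = Grammar(mode="ordered", terminals=frozenset("a"),
                    rules={k1: Rule(k1, "RHB", (k2, k2)),
                           k2: Rule(k2, "RHB", (k1, k1))},
                    start={"T": k1}, names={k1: "S1", k2: "U1"})
        with pytest.raises(IntegrityError, match="cyclic"):
            derive_and_verify(g, [path_tree(["a", "a"], "T")])

    def test_rvb_attaches_at_tag(self):
        # whole = tagged-edge 'a' with 'b'-edge substituted at the tag
        trees = [path_tree(["a", "b"], "T")]
        model = build_minseotgmul(trees)
        g = decode_grammar(solve(model), model)
        report = derive_and_verify(g, trees)
        assert report["per_tree"]["T"]["derived"] == "a b /b /a"

    def test_unordered_verification_uses_canonical_form(self):
        trees = [star_tree(["b", "a"], "M", ordered=False)]
        model = build_minseutgmul(trees)
        g = decode_grammar(solve(model), model)
        report = derive_and_verify(g, trees)
        assert report["all_ok"]
        assert report["per_tree"]["M"]["derived"] == "a /a b /b"
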