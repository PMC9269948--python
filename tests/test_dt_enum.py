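from fractions import Fraction
from itertools import product

import pytest

from topomod.dt_enum import (
    ResourceError,
    SignPattern,
    dfs_count,
    enumerate_feasible,
    fva_infeasibility_oracle,
    generate_patterns,
    heuristic_patterns,
    loop_patterns,
    mass_balance_patterns,
    merged_metabolite_patterns,
    model_dof,
    module_census,
)
from topomod.model import from_reaction_table
from topomod.validation import brute_force_census

from conftest import iter_module_subnets, open_exchanges


class TestMassBalancePatterns:
    def test_irreversible_producer_leaves_one_pattern(self):
        # one irreversible producer of M: only "all reversible neighbours
        # producing" (no consumer) is infeasible
        model = from_reaction_table(
            [
                ("feed", {"x[e]": -1, "M[c]": 1}, 0, 10),
                ("r1", {"M[c]": -1, "P[c]": 1}, -10, 10),
                ("r2", {"M[c]": -1, "Q[c]": 1}, -10, 10),
            ]
            + open_exchanges("P[c]", "p")
            + open_exchanges("Q[c]", "q")
        )
        pats = [p for p in mass_balance_patterns(model) if p.witness == "M[c]"]
        assert len(pats) == 1
        assert pats[0].as_dict() == {"r1": -1, "r2": -1}  # both toward M

    def test_producer_and_consumer_guarantee_balance(self):
        model = from_reaction_table(
            [
                ("feed", {"x[e]": -1, "M[c]": 1}, 0, 10),
                ("drain", {"M[c]": -1, "y[e]": 1}, 0, 10),
                ("r1", {"M[c]": -1, "P[c]": 1}, -10, 10),
            ]
            + open_exchanges("P[c]", "p")
        )
        assert [p for p in mass_balance_patterns(model) if p.witness == "M[c]"] == []

    def test_two_reversible_neighbours_give_two_patterns(self):
        model = from_reaction_table(
            [
                ("r1", {"A[c]": -1, "M[c]": 1}, -10, 10),
                ("r2", {"M[c]": -1, "B[c]": 1}, -10, 10),
            ]
            + open_exchanges("A[c]", "a")
            + open_exchanges("B[c]", "b")
        )
        pats = [p for p in mass_balance_patterns(model) if p.witness == "M[c]"]
        assert len(pats) == 2
        # oracle: enumerate all four orientations against the single-row balance
        infeasible = set()
        for s1, s2 in product((1, -1), repeat=2):
            produced = {s1 * 1, s2 * -1}  # sign of flux into M per reaction
            if produced == {1} or produced == {-1}:
                infeasible.add((s1, s2))
        matched = {
            (d["r1"], d["r2"])
            for p in pats
            for d in [p.as_dict()]
        }
        assert matched == infeasible


class TestMergedPatterns:
    def test_no_interconversion_no_patterns(self):
        # a condensation A + B <-> C conserves no two-metabolite pool
        model = from_reaction_table(
            [("r", {"A[c]": -1, "B[c]": -1, "C[c]": 1}, -10, 10)]
            + open_exchanges("A[c]", "a")
            + open_exchanges("B[c]", "b")
            + open_exchanges("C[c]", "c")
        )
        assert merged_metabolite_patterns(model) == []

    def test_pool_patterns_on_diamond_are_sound(self, diamond):
        # every 1:1 branch conserves its endpoint pool, so pooled patterns
        # exist; they must only ever reject truly infeasible orientations
        pats = merged_metabolite_patterns(diamond)
        assert pats  # each branch edge induces a pooled balance
        from topomod.dt_enum import loop_patterns
        from topomod.validation import dt_feasibility

        law, _ = loop_patterns(diamond)
        rev = ["r1", "r2", "r3", "r4"]
        for combo in product((1, -1), repeat=4):
            assignment = dict(zip(rev, combo))
            if any(p.matches(assignment) for p in pats):
                assert not dt_feasibility(diamond, assignment, law=law).feasible

    def test_pool_rule_required_for_exact_census(self, mixed_pair):
        patterns, _ = generate_patterns(mixed_pair)
        full = dfs_count(mixed_pair, patterns)
        without = dfs_count(
            mixed_pair,
            [p for p in patterns if p.rule_type != "merged_mass_balance"],
        )
        bf = brute_force_census(mixed_pair)
        assert full.n_feasible == bf.n_feasible == 6
        assert without.n_feasible == 10  # pool violations invisible locally

    def test_pool_balance_against_brute_force(self, mixed_pair):
        """Every pooled-pattern match violates the two-metabolite balance."""
        pats = merged_metabolite_patterns(mixed_pair)
        assert pats, "pooled patterns expected"
        law, _ = loop_patterns(mixed_pair)
        from topomod.validation import dt_feasibility

        rev = [r for j, r in enumerate(mixed_pair.reaction_ids) if mixed_pair.reversible[j]]
        for combo in product((1, -1), repeat=len(rev)):
            assignment = dict(zip(rev, combo))
            if any(p.matches(assignment) for p in pats):
                assert not dt_feasibility(mixed_pair, assignment, law=law).feasible


class TestLoopPatterns:
    def test_triangle_has_two_orientations(self, triangle):
        law, pats = loop_patterns(triangle)
        assert len(law.vectors) == 1
        assert len(pats) == 2
        signs = {tuple(sorted(p.as_dict().values())) for p in pats}
        assert signs == {(1, 1, 1), (-1, -1, -1)}

    def test_exactness(self, triangle):
        law, _ = loop_patterns(triangle)
        # S_int @ v == 0 in exact rational arithmetic
        idx = triangle.rxn_index()
        for vec in law.vectors:
            for i, met in enumerate(triangle.metabolite_ids):
                total = Fraction(0)
                for r, x in zip(law.internal_reactions, vec):
                    total += Fraction(float(triangle.S[i, idx[r]])) * x
                assert total == 0

    def test_acyclic_tree_has_no_loops(self, single_module):
        law, pats = loop_patterns(single_module)
        assert law.vectors == [] and pats == []

    def test_irreversible_member_removes_one_orientation(self):
        # a cycle with one irreversible member can only run one way, so a
        # single loop pattern remains (the orientation the member allows)
        model = from_reaction_table(
            [
                ("r1", {"A[c]": -1, "B[c]": 1}, -10, 10),
                ("r2", {"B[c]": -1, "C[c]": 1}, -10, 10),
                ("irr", {"C[c]": -1, "A[c]": 1}, 0, 10),
            ]
        )
        _, pats = loop_patterns(model)
        assert len(pats) == 1
        assert pats[0].as_dict() == {"r1": 1, "r2": 1}


class TestDfsCount:
    def test_trivial_censuses(self, single_module, triangle, diamond):
        c, _, _ = module_census(single_module)
        assert (c.n_feasible, c.dof) == (2, 1.0)
        c, _, _ = module_census(triangle)
        assert c.n_feasible == 0 and c.dof == float("-inf")
        c, _, _ = module_census(diamond)
        assert (c.n_feasible, c.dof) == (1, 0.0)

    def test_matches_brute_force_on_generated_modules(self):
        checked = 0
        for seed, mid, sub in iter_module_subnets(range(3)):
            census, _, _ = module_census(sub, module_id=mid)
            bf = brute_force_census(sub, module_id=mid)
            assert census.n_feasible == bf.n_feasible, (seed, mid)
            checked += 1
        assert checked >= 20

    def test_pattern_monotonicity(self, mixed_pair):
        patterns, _ = generate_patterns(mixed_pair)
        full = dfs_count(mixed_pair, patterns).n_feasible
        for i in range(len(patterns)):
            dropped = patterns[:i] + patterns[i + 1 :]
            assert dfs_count(mixed_pair, dropped).n_feasible >= full

    def test_free_reaction_divisibility(self):
        for seed, mid, sub in iter_module_subnets([4]):
            census, _, _ = module_census(sub, module_id=mid)
            assert census.n_feasible % (1 << len(census.free_reactions)) == 0

    def test_deterministic(self, mixed_pair):
        patterns, _ = generate_patterns(mixed_pair)
        a = dfs_count(mixed_pair, patterns)
        b = dfs_count(mixed_pair, patterns)
        assert a.n_feasible == b.n_feasible and a.rejections == b.rejections

    def test_resource_cap(self, mixed_pair):
        patterns, _ = generate_patterns(mixed_pair)
        with pytest.raises(ResourceError, match="cap"):
            dfs_count(mixed_pair, patterns, max_n=1)

    def test_enumerate_matches_count(self, mixed_pair):
        patterns, _ = generate_patterns(mixed_pair)
        dts = list(enumerate_feasible(mixed_pair, patterns))
        assert len(dts) == dfs_count(mixed_pair, patterns).n_feasible
        assert len({tuple(sorted(d.items())) for d in dts}) == len(dts)


class TestHeuristics:
    def test_empty_existing_gives_empty(self, mixed_pair):
        oracle = fva_infeasibility_oracle(mixed_pair)
        assert heuristic_patterns([], oracle, ["rA", "rB"]) == []

    def test_recovers_missing_pool_pattern(self):
        """Feeding only the single-metabolite patterns of one metabolite,
        constraint relocation rediscovers a pooled-balance pattern."""
        model = from_reaction_table(
            [
                ("r1", {"A[c]": -1, "B[c]": 1, "atp[c]": -1, "adp[c]": 1}, -1000, 1000),
                ("r2", {"A[c]": -1, "B[c]": 1, "nadh[c]": -1, "nad[c]": 1}, -1000, 1000),
                ("rA1", {"A[c]": -1, "X[c]": 1}, -1000, 1000),
                ("rA2", {"A[c]": -1, "W[c]": 1}, -1000, 1000),
                ("rB", {"B[c]": -1, "Y[c]": 1}, -1000, 1000),
            ]
            + open_exchanges("X[c]", "x")
            + open_exchanges("W[c]", "w")
            + open_exchanges("Y[c]", "y"),
            boundary_metabolites={"atp[c]", "adp[c]", "nadh[c]", "nad[c]"},
        )
        # the all-inward pattern around A alone (size 4), rB unconstrained
        existing = [
            SignPattern.make(
                {"r1": -1, "r2": -1, "rA1": -1, "rA2": -1}, "mass_balance", "A[c]"
            )
        ]
        found = heuristic_patterns(
            existing, fva_infeasibility_oracle(model), ["r1", "r2", "rA1", "rA2", "rB"]
        )
        assert found, "expected a relocated sound pattern"
        # soundness: every match of every found pattern is truly infeasible
        from topomod.validation import dt_feasibility

        law, _ = loop_patterns(model)
        rev = ["r1", "r2", "rA1", "rA2", "rB"]
        for p in found:
            for combo in product((1, -1), repeat=len(rev)):
                assignment = dict(zip(rev, combo))
                if p.matches(assignment):
                    assert not dt_feasibility(model, assignment, law=law).feasible

    def test_no_gain_when_rules_complete(self, mixed_pair):
        base, _, _ = module_census(mixed_pair)
        with_h, _, _ = module_census(mixed_pair, use_heuristic=True)
        assert with_h.n_feasible == base.n_feasible


class TestModelDof:
    def test_two_free_modules(self):
        from topomod.dt_enum import DTCensus

        censuses = [DTCensus(1, 1, 2), DTCensus(2, 1, 2)]
        assert model_dof(censuses) == 2.0

    def test_infeasible_module_flags_minus_inf(self):
        from topomod.dt_enum import DTCensus

        censuses = [DTCensus(1, 1, 2), DTCensus(2, 3, 0)]
        assert model_dof(censuses) == float("-inf")

    def test_missing_module_raises(self):
        from topomod.dt_enum import DTCensus

        with pytest.raises(ValueError, match="2"):
            model_dof([DTCensus(1, 1, 2)], expected_modules={1, 2})
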