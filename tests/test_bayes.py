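"""Contingency tables, conditional probabilities, and state subsets.

The conditional/optimal state-subset selections are checked against
independent brute-force oracles that loop over cells and states directly.
"""

import numpy as np
import pytest

from islevi import (
    AlignmentError,
    ContingencyTable,
    RegionMask,
    StateSubset,
    build_probability_graph,
    conditional_probability,
    conditional_state_subset,
    joint_counts,
    match_subset,
    optimal_state_subset,
)

from conftest import full_mask, make_cat, make_grid


# --- independent oracles -----------------------------------------------------


def oracle_counts(a_levels, b_levels, m_a, m_b):
    counts = np.zeros((m_a, m_b), dtype=int)
    for x, y in zip(a_levels, b_levels):
        counts[x - 1, y - 1] += 1
    return counts


def oracle_css(levels_by_var, result_levels, result_level):
    out = {}
    for var, levels in levels_by_var.items():
        tallies = {}
        for x, r in zip(levels, result_levels):
            if r == result_level:
                tallies[x] = tallies.get(x, 0) + 1
        best = max(sorted(tallies), key=lambda s: (tallies[s], -s))
        out[var] = best
    return out


def oracle_optimal(levels_by_var, result_levels, target, n_states):
    out = {}
    for var, levels in levels_by_var.items():
        best_state, best_p = None, -1.0
        for s in range(1, n_states + 1):
            hits = sum(1 for x, r in zip(levels, result_levels) if x == s and r == target)
            total = sum(1 for x in levels if x == s)
            if total == 0:
                continue
            p = hits / total
            if p > best_p + 1e-12:
                best_state, best_p = s, p
        out[var] = best_state
    return out


def random_stack(rng, n_vars=5, n_cells=120, n_states=3, max_level=None):
    grid = make_grid(1, n_cells, cell=30.0)
    stack = {}
    hi = (max_level or n_states) + 1
    for i in range(n_vars):
        levels = rng.integers(1, hi, size=(1, n_cells))
        stack[f"x{i}"] = make_cat(levels, n_states, grid)
    stack["result"] = make_cat(rng.integers(1, hi, size=(1, n_cells)), n_states, grid)
    return grid, stack


# --- joint counts ------------------------------------------------------------


class TestJointCounts:
    def test_identical_layers_give_diagonal(self):
        grid = make_grid(10)
        levels = np.ones((10, 10), int)
        levels[5:] = 2
        a = make_cat(levels, 2, grid)
        t = joint_counts(a, a, full_mask(grid))
        np.testing.assert_array_equal(t.counts, [[50, 0], [0, 50]])

    def test_independent_checkerboards_uniform(self):
        # Row-parity vs column-parity layers are exactly independent.
        grid = make_grid(8)
        rows = (np.add.outer(np.arange(8), np.zeros(8, int)) % 2 + 1).astype(int)
        cols = (np.add.outer(np.zeros(8, int), np.arange(8)) % 2 + 1).astype(int)
        t = joint_counts(make_cat(rows, 2, grid), make_cat(cols, 2, grid), full_mask(grid))
        np.testing.assert_array_equal(t.counts, np.full((2, 2), 16))

    def test_total_conserved_and_matches_oracle(self):
        rng = np.random.default_rng(0)
        grid, stack = random_stack(rng, n_vars=2, n_cells=200)
        t = joint_counts(stack["x0"], stack["x1"], full_mask(grid))
        assert t.total == 200
        np.testing.assert_array_equal(
            t.counts, oracle_counts(stack["x0"].levels.ravel(), stack["x1"].levels.ravel(), 3, 3)
        )

    def test_unaligned_rejected(self):
        a = make_cat(np.ones((4, 4), int), 2)
        b = make_cat(np.ones((4, 4), int), 2, make_grid(4, cell=10.0))
        with pytest.raises(AlignmentError):
            joint_counts(a, b, full_mask(a.grid))

    def test_empty_overlap_rejected(self):
        grid = make_grid(4)
        a = make_cat(np.ones((4, 4), int), 2, grid)
        with pytest.raises(ValueError):
            joint_counts(a, a, RegionMask(grid, np.zeros((4, 4), bool)))


class TestConditionalProbability:
    def test_column_normalization(self):
        cpt = conditional_probability(ContingencyTable("A", "B", [[30, 10], [10, 30]]))
        assert cpt.probs[0, 0] == pytest.approx(0.75)
        assert cpt.probs[1, 1] == pytest.approx(0.75)
        np.testing.assert_allclose(cpt.probs.sum(axis=0), 1.0)

    def test_diagonal_counts_give_identity(self):
        cpt = conditional_probability(ContingencyTable("A", "B", [[40, 0], [0, 60]]))
        np.testing.assert_array_equal(cpt.probs, np.eye(2))

    def test_zero_support_column_undefined(self):
        cpt = conditional_probability(ContingencyTable("A", "B", [[10, 0], [5, 0]]))
        assert np.isnan(cpt.probs[:, 1]).all()
        np.testing.assert_allclose(cpt.probs[:, 0], [2 / 3, 1 / 3])
        np.testing.assert_array_equal(cpt.defined, [True, False])


class TestProbabilityGraph:
    def test_pair_count(self):
        rng = np.random.default_rng(1)
        grid, stack = random_stack(rng, n_vars=1)
        g = build_probability_graph(
            {"x0": stack["x0"], "result": stack["result"]}, "result", full_mask(grid)
        )
        assert len(g.all_cpts()) == 2
        grid, stack = random_stack(rng, n_vars=5)
        g6 = build_probability_graph(stack, "result", full_mask(grid))
        assert len(g6.all_cpts()) == 30

    def test_bayes_identity_and_marginal_consistency(self):
        rng = np.random.default_rng(2)
        grid, stack = random_stack(rng, n_vars=4, n_cells=300)
        g = build_probability_graph(stack, "result", full_mask(grid))
        for (a, b), cpt in g.all_cpts().items():
            pa, pb = g.marginals[a], g.marginals[b]
            rev = g.cpt(b, a)
            for i in range(len(pa)):
                for j in range(len(pb)):
                    lhs = (cpt.probs[i, j] if cpt.defined[j] else 0.0) * pb[j]
                    rhs = (rev.probs[j, i] if rev.defined[i] else 0.0) * pa[i]
                    assert abs(lhs - rhs) < 1e-9
            # marginal consistency: P(A=i) = sum_j P(A=i|B=j) P(B=j)
            recon = np.nansum(cpt.probs * pb[None, :], axis=1)
            np.testing.assert_allclose(recon, pa, atol=1e-9)

    def test_single_variable_rejected(self):
        grid = make_grid(4)
        r = make_cat(np.ones((4, 4), int), 2, grid)
        with pytest.raises(ValueError):
            build_probability_graph({"result": r}, "result", full_mask(grid))


class TestStateSubsets:
    def test_deterministic_dependence_recovers_result_state(self):
        rng = np.random.default_rng(3)
        grid = make_grid(1, 90)
        result = rng.integers(1, 4, size=(1, 90))
        stack = {f"x{i}": make_cat(result, 3, grid) for i in range(3)}
        stack["result"] = make_cat(result, 3, grid)
        g = build_probability_graph(stack, "result", full_mask(grid))
        for level in (1, 2, 3):
            css = conditional_state_subset(g, level)
            assert all(s == frozenset({level}) for s in css.assignments.values())

    @pytest.mark.parametrize("seed", range(25))
    def test_css_and_optimal_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        grid, stack = random_stack(rng, n_vars=5, n_cells=90)
        g = build_probability_graph(stack, "result", full_mask(grid))
        levels_by_var = {v: stack[v].levels.ravel() for v in stack if v != "result"}
        result_levels = stack["result"].levels.ravel()
        for level in (1, 2, 3):
            if g.marginals["result"][level - 1] == 0:
                continue
            css = conditional_state_subset(g, level)
            expect = oracle_css(levels_by_var, result_levels, level)
            assert {v: min(s) for v, s in css.assignments.items()} == expect
        opt = optimal_state_subset(g, 1)
        expect = oracle_optimal(levels_by_var, result_levels, 1, 3)
        assert {v: min(s) for v, s in opt.assignments.items()} == expect

    def test_tie_broken_toward_lowest_state_and_recorded(self):
        # Two states equally likely given result=1: states 1 and 2 both occur
        # twice among result-1 cells.
        grid = make_grid(1, 8)
        x = make_cat(np.array([[1, 1, 2, 2, 3, 3, 3, 3]]), 3, grid)
        result = make_cat(np.array([[1, 1, 1, 1, 2, 2, 2, 2]]), 3, grid)
        g = build_probability_graph({"x": x, "result": result}, "result", full_mask(grid))
        css = conditional_state_subset(g, 1)
        assert css.assignments["x"] == frozenset({1})
        assert css.ties["x"] == (1, 2)

    def test_independence_gives_tie_flag_in_optimal(self):
        grid = make_grid(8)
        rows = (np.add.outer(np.arange(8), np.zeros(8, int)) % 2 + 1).astype(int)
        cols = (np.add.outer(np.zeros(8, int), np.arange(8)) % 2 + 1).astype(int)
        g = build_probability_graph(
            {"x": make_cat(cols, 2, grid), "result": make_cat(rows, 2, grid)},
            "result",
            full_mask(grid),
        )
        opt = optimal_state_subset(g, 1)
        assert opt.assignments["x"] == frozenset({1})
        assert opt.ties["x"] == (1, 2)

    def test_zero_support_result_level_rejected(self):
        grid = make_grid(1, 10)
        x = make_cat(np.full((1, 10), 1), 3, grid)
        result = make_cat(np.full((1, 10), 2), 3, grid)
        g = build_probability_graph({"x": x, "result": result}, "result", full_mask(grid))
        with pytest.raises(ValueError):
            conditional_state_subset(g, 3)


class TestMatchSubset:
    def test_empty_assignment_matches_whole_domain(self, grid10, domain10):
        out = match_subset({}, StateSubset({}), domain10)
        np.testing.assert_array_equal(out.member, domain10.member)

    def test_absent_state_matches_nothing(self, grid10, domain10):
        stack = {"x": make_cat(np.ones((10, 10), int), 3, grid10)}
        out = match_subset(stack, StateSubset({"x": {3}}), domain10)
        assert out.n_member == 0

    def test_single_variable_count(self, grid10, domain10):
        levels = np.ones((10, 10), int)
        levels[:4] = 2  # 40 cells at state 2
        stack = {"x": make_cat(levels, 3, grid10)}
        out = match_subset(stack, StateSubset({"x": {2}}), domain10)
        assert out.n_member == 40

    def test_conjunction_equals_intersection(self, grid10, domain10):
        rng = np.random.default_rng(6)
        stack = {
            "a": make_cat(rng.integers(1, 4, (10, 10)), 3, grid10),
            "b": make_cat(rng.integers(1, 4, (10, 10)), 3, grid10),
        }
        joint = match_subset(stack, StateSubset({"a": {1, 2}, "b": {3}}), domain10)
        a_only = match_subset(stack, StateSubset({"a": {1, 2}}), domain10)
        b_only = match_subset(stack, StateSubset({"b": {3}}), domain10)
        np.testing.assert_array_equal(joint.member, a_only.member & b_only.member)

    def test_missing_variable_rejected(self, grid10, domain10):
        with pytest.raises(KeyError):
            match_subset({}, StateSubset({"ghost": {1}}), domain10)
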