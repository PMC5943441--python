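"""Exact tour/tree solvers, oracles, flow formulation, counting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pathproxy import (
    CorrelationNetwork,
    DataValidationError,
    brute_force_tsp,
    build_flow_formulation,
    canonical_tour,
    check_selection_feasibility,
    check_tour_feasibility,
    count_solutions,
    enumerate_spanning_trees_max,
    solve_mst_max,
    solve_tsp_max,
    tree_exchange_optimal,
)
from pathproxy.netopt import tour_from_order

from tests.conftest import random_network


def net_from_weights(w):
    w = np.asarray(w, dtype=float)
    return CorrelationNetwork([f"g{i:02d}" for i in range(len(w))], w)


class TestCanonicalTour:
    def test_rotations_and_reflections_collapse(self):
        base = ["a", "b", "c", "d"]
        variants = [
            ["c", "d", "a", "b"],
            ["d", "c", "b", "a"],
            ["b", "a", "d", "c"],
        ]
        canon = canonical_tour(base)
        for v in variants:
            assert canonical_tour(v) == canon

    def test_second_element_rule(self):
        assert canonical_tour(["b", "a", "c"]) == ["a", "b", "c"]
        assert canonical_tour(["a", "c", "b"]) == ["a", "b", "c"]

    @given(st.permutations(["a", "b", "c", "d", "e"]), st.integers(0, 4), st.booleans())
    def test_idempotent_and_invariant(self, order, rot, flip):
        order = list(order)
        moved = order[rot:] + order[:rot]
        if flip:
            moved = moved[::-1]
        assert canonical_tour(moved) == canonical_tour(order)
        assert canonical_tour(canonical_tour(order)) == canonical_tour(order)

    def test_repeated_gene_rejected(self):
        with pytest.raises(DataValidationError):
            canonical_tour(["a", "b", "a"])


class TestSolveTspMax:
    def test_n3_unique_cycle(self, rng):
        net = random_network(rng, 3)
        tour = solve_tsp_max(net)
        assert tour.total_weight == pytest.approx(
            net.weights[0, 1] + net.weights[1, 2] + net.weights[0, 2]
        )

    def test_heavy_edge_is_used(self):
        w = np.zeros((5, 5))
        w[1, 3] = w[3, 1] = 1.0
        tour = solve_tsp_max(net_from_weights(w))
        assert tour.total_weight == pytest.approx(1.0)
        edges = {(a, b) for a, b, _ in tour.edges.edges}
        assert ("g01", "g03") in edges

    def test_size_limits(self, rng):
        with pytest.raises(DataValidationError):
            solve_tsp_max(random_network(rng, 2) if False else net_from_weights(np.zeros((2, 2))))
        with pytest.raises(DataValidationError, match="exact-solver limit"):
            solve_tsp_max(random_network(rng, 9), exact_limit=8)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8, 9])
    def test_agrees_with_brute_force_random_instances(self, n):
        for seed in range(3):
            net = random_network(np.random.default_rng(1000 * n + seed), n)
            dp = solve_tsp_max(net)
            bf, count = brute_force_tsp(net)
            assert count == math.factorial(n - 1) // 2
            assert dp.total_weight == pytest.approx(bf.total_weight, abs=1e-9)
            assert dp.order == bf.order

    def test_tie_break_all_equal_weights_is_lexicographic(self):
        w = np.full((6, 6), 0.5)
        np.fill_diagonal(w, 0.0)
        net = net_from_weights(w)
        dp = solve_tsp_max(net)
        bf, _ = brute_force_tsp(net)
        assert dp.order == bf.order == sorted(net.gene_ids)

    def test_monotonic_shift_preserves_optimal_edges(self, rng):
        net = random_network(rng, 7)
        eps = 0.003
        shifted = CorrelationNetwork(
            net.gene_ids,
            np.where(np.eye(7, dtype=bool), 0.0, net.weights + eps),
        )
        t1, t2 = solve_tsp_max(net), solve_tsp_max(shifted)
        assert t1.order == t2.order
        assert t2.total_weight == pytest.approx(t1.total_weight + 7 * eps, abs=1e-9)


class TestBruteForce:
    def test_enumeration_counts(self, rng):
        _, c5 = brute_force_tsp(random_network(rng, 5))
        assert c5 == 12  # 24 directed cycles, 12 undirected
        _, c3 = brute_force_tsp(random_network(rng, 3))
        assert c3 == 1

    def test_out_of_range_rejected(self, rng):
        with pytest.raises(DataValidationError):
            brute_force_tsp(random_network(rng, 12), limit=11)


class TestSolveMstMax:
    def test_n2_single_edge(self):
        net = CorrelationNetwork(["a", "b"], np.array([[0, 0.4], [0.4, 0]]))
        tree = solve_mst_max(net)
        assert tree.edges.edges == [("a", "b", 0.4)]

    def test_n5_matches_prufer_enumeration(self):
        for seed in range(3):
            net = random_network(np.random.default_rng(seed), 5)
            greedy = solve_mst_max(net)
            best, count = enumerate_spanning_trees_max(net)
            assert count == 125  # Cayley: 5^3
            assert greedy.total_weight == pytest.approx(best.total_weight, abs=1e-9)
            assert greedy.edges.edges == best.edges.edges

    @pytest.mark.parametrize("n", [6, 7])
    def test_matches_enumeration_larger(self, n):
        net = random_network(np.random.default_rng(77 + n), n)
        greedy = solve_mst_max(net)
        best, count = enumerate_spanning_trees_max(net)
        assert count == n ** (n - 2)
        assert greedy.total_weight == pytest.approx(best.total_weight, abs=1e-9)

    def test_geometric_chain_weights_give_path(self):
        # w(i,j) = phi^|i-j|: adjacent edges strictly dominate, tree is the path
        phi = 0.8
        n = 6
        w = phi ** np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        np.fill_diagonal(w, 0.0)
        net = net_from_weights(w)
        tree = solve_mst_max(net)
        expected = [(f"g{i:02d}", f"g{i+1:02d}") for i in range(n - 1)]
        assert [(a, b) for a, b, _ in tree.edges.edges] == expected
        best, _ = enumerate_spanning_trees_max(net)
        assert best.edges.edges == tree.edges.edges

    def test_agrees_with_networkx_maximum_spanning_tree_weight(self, rng):
        import networkx as nx

        net = random_network(rng, 9)
        g = nx.Graph()
        for a, b, w in net.edge_list().edges:
            g.add_edge(a, b, weight=w)
        nx_total = sum(d["weight"] for _, _, d in nx.maximum_spanning_tree(g).edges(data=True))
        assert solve_mst_max(net).total_weight == pytest.approx(nx_total, abs=1e-9)

    def test_exchange_property_certifies_optimality(self, rng):
        net = random_network(rng, 8)
        tree = solve_mst_max(net)
        assert tree_exchange_optimal(net, tree)

    def test_exchange_check_rejects_suboptimal_tree(self):
        from pathproxy import EdgeList, TreeSolution

        w = np.array(
            [[0, 0.9, 0.1, 0.1], [0.9, 0, 0.8, 0.1], [0.1, 0.8, 0, 0.7], [0.1, 0.1, 0.7, 0]]
        )
        net = net_from_weights(w)
        bad = EdgeList([("g00", "g02", 0.1), ("g00", "g01", 0.9), ("g02", "g03", 0.7)])
        assert not tree_exchange_optimal(net, TreeSolution(edges=bad, total_weight=bad.total_weight))

    def test_deterministic_tie_break(self):
        w = np.full((4, 4), 0.5)
        np.fill_diagonal(w, 0.0)
        tree = solve_mst_max(net_from_weights(w))
        assert [(a, b) for a, b, _ in tree.edges.edges] == [
            ("g00", "g01"), ("g00", "g02"), ("g00", "g03")
        ]


class TestFlowFormulation:
    def test_shapes_and_sums_n4(self, rng):
        model = build_flow_formulation(random_network(rng, 4))
        assert model.incidence.shape == (4, 12)
        np.testing.assert_array_equal(model.supply, [3, -1, -1, -1])
        np.testing.assert_array_equal(model.incidence.sum(axis=0), np.zeros(12))
        assert model.supply.sum() == 0
        for k in range(model.m):
            col = model.incidence[:, k]
            assert (col == 1).sum() == 1 and (col == -1).sum() == 1

    def test_costs_are_negated_weights(self, rng):
        net = random_network(rng, 4)
        model = build_flow_formulation(net)
        for k, (i, j) in enumerate(model.arcs):
            assert model.costs[k] == -net.weight(model.gene_ids[i], model.gene_ids[j])

    def test_solver_tour_satisfies_all_constraints(self, rng):
        net = random_network(rng, 5)
        model = build_flow_formulation(net)
        report = check_tour_feasibility(model, solve_tsp_max(net))
        assert report.feasible
        assert report.total_cost == pytest.approx(-solve_tsp_max(net).total_weight)

    def test_two_subtours_flagged_infeasible(self, rng):
        # degree constraints hold, but flow cannot reach the detached subtour
        net = random_network(rng, 5)
        model = build_flow_formulation(net)
        g = model.gene_ids
        arcs = [(g[0], g[1]), (g[1], g[0]), (g[2], g[3]), (g[3], g[4]), (g[4], g[2])]
        report = check_selection_feasibility(model, arcs)
        assert report.degree_out_ok and report.degree_in_ok
        assert not report.flow_balance_ok
        assert not report.feasible

    def test_degree_violation_detected(self, rng):
        net = random_network(rng, 4)
        model = build_flow_formulation(net)
        g = model.gene_ids
        # node g0 has out-degree 2, g2 out-degree 0
        arcs = [(g[0], g[1]), (g[0], g[2]), (g[1], g[3]), (g[3], g[0])]
        report = check_selection_feasibility(model, arcs)
        assert not report.degree_out_ok

    def test_full_tour_selection_is_feasible_by_lp(self, rng):
        net = random_network(rng, 5)
        model = build_flow_formulation(net)
        tour = solve_tsp_max(net)
        seq = tour.order
        arcs = list(zip(seq, seq[1:] + seq[:1]))
        assert check_selection_feasibility(model, arcs).feasible


class TestCountSolutions:
    @pytest.mark.parametrize(
        "n,tours,trees",
        [(2, 1, 1), (3, 2, 3), (5, 24, 125), (11, 3628800, 11**9)],
    )
    def test_exact_counts(self, n, tours, trees):
        report = count_solutions(n)
        assert (report.tour_count, report.tree_count) == (tours, trees)

    def test_exact_integer_arithmetic_n30(self):
        report = count_solutions(30)
        assert report.tree_count == 30**28  # exact int, no float overflow
        assert report.tour_count == math.factorial(29)

    def test_n_below_2_rejected(self):
        with pytest.raises(ValueError):
            count_solutions(1)


class TestTourSolutionInvariants:
    def test_total_weight_consistency_enforced(self, rng):
        net = random_network(rng, 5)
        tour = solve_tsp_max(net)
        recomputed = sum(net.weight(a, b) for a, b in zip(tour.order, tour.order[1:] + tour.order[:1]))
        assert tour.total_weight == pytest.approx(recomputed, abs=1e-9)

    def test_tour_from_order_canonicalizes(self, rng):
        net = random_network(rng, 5)
        genes = sorted(net.gene_ids)
        t1 = tour_from_order(net, genes)
        t2 = tour_from_order(net, genes[2:] + genes[:2])  # rotated input
        assert t1.order == t2.order
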