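"""Exact maximum-correlation tours and spanning trees over a gene network.

The two pathway-proxy models are:

* the maximum-correlation Hamiltonian cycle (a TSP with edge gains
  ``|rho|`` instead of costs), solved exactly by Held-Karp dynamic
  programming over vertex subsets -- the cyclic structure models feedback;
* the maximum-correlation spanning tree, solved by Kruskal's greedy with a
  deterministic tie-break -- the open structure models coordinated groups
  without feedback.

Both solvers are exact: the returned structure is a global optimum, and no
heuristic fallback exists.  Instances beyond the exact-solver limit raise
instead of silently degrading, because the whole point of the method is the
optimality guarantee.

Tours are undirected objects: rotations and reflections of a cycle are the
same solution.  The canonical representative starts at the lexicographically
smallest gene and, of the two directions, stores the one whose second gene
is lexicographically smaller.  All tie-breaks are lexicographic on gene id,
so every output is reproducible bit-for-bit.

The single-commodity flow MILP formulation of the tour problem (degree
constraints, flow balance ``Nx = b`` from a source holding ``n-1`` units,
and forcing constraints ``x_ij <= (n-1) y_ij``) is represented explicitly
as matrices plus a feasibility checker.  It is not used to solve anything
-- the DP is the solver of record -- but it makes the subtour-elimination
argument checkable: an arc selection made of disjoint subtours passes the
degree constraints yet admits no feasible flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations, product

import numpy as np

from .exprdata import CorrelationNetwork, DataValidationError, EdgeList

__all__ = [
    "TourSolution",
    "TreeSolution",
    "FlowTspModel",
    "FeasibilityReport",
    "CountReport",
    "canonical_tour",
    "tour_from_order",
    "solve_tsp_max",
    "brute_force_tsp",
    "solve_mst_max",
    "enumerate_spanning_trees_max",
    "tree_exchange_optimal",
    "build_flow_formulation",
    "check_tour_feasibility",
    "check_selection_feasibility",
    "count_solutions",
]

WEIGHT_TOL = 1e-9


def canonical_tour(order: list[str]) -> list[str]:
    """Rotation/reflection-invariant representative of a cyclic gene sequence."""
    if len(order) != len(set(order)):
        raise DataValidationError("tour visits a gene more than once")
    if len(order) < 3:
        raise DataValidationError("a tour needs at least 3 genes")
    k = order.index(min(order))
    fwd = order[k:] + order[:k]
    rev = [fwd[0]] + fwd[1:][::-1]
    return fwd if fwd[1] < rev[1] else rev


@dataclass
class TourSolution:
    """Canonical Hamiltonian cycle with its total absolute-correlation weight."""

    order: list[str]
    total_weight: float
    edges: EdgeList

    def __post_init__(self) -> None:
        if self.order != canonical_tour(self.order):
            raise DataValidationError("tour order is not canonical")
        recomputed = self.edges.total_weight
        if abs(recomputed - self.total_weight) > WEIGHT_TOL:
            raise DataValidationError(
                f"total_weight {self.total_weight} inconsistent with edges ({recomputed})"
            )

    def edge_list(self) -> EdgeList:
        return self.edges


@dataclass
class TreeSolution:
    """Spanning tree (n-1 edges) with its total absolute-correlation weight."""

    edges: EdgeList
    total_weight: float

    def __post_init__(self) -> None:
        nodes = self.edges.nodes()
        if len(self.edges.edges) != len(nodes) - 1:
            raise DataValidationError("a spanning tree on n nodes must have n-1 edges")
        # connectivity (and hence acyclicity, given the edge count)
        adj: dict[str, list[str]] = {v: [] for v in nodes}
        for a, b, _ in self.edges.edges:
            adj[a].append(b)
            adj[b].append(a)
        seen = {nodes[0]}
        stack = [nodes[0]]
        while stack:
            for u in adj[stack.pop()]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        if len(seen) != len(nodes):
            raise DataValidationError("tree edges do not span all genes")
        if abs(self.edges.total_weight - self.total_weight) > WEIGHT_TOL:
            raise DataValidationError("total_weight inconsistent with edges")

    def edge_list(self) -> EdgeList:
        return self.edges


def _sorted_net(net: CorrelationNetwork) -> tuple[list[str], np.ndarray]:
    """Network genes in lexicographic order with the reindexed weight matrix."""
    genes = sorted(net.gene_ids)
    idx = [net.gene_ids.index(g) for g in genes]
    return genes, net.weights[np.ix_(idx, idx)]


def tour_from_order(net: CorrelationNetwork, order: list[str]) -> TourSolution:
    """Assemble a :class:`TourSolution` (canonicalized) from a visiting order."""
    if set(order) != set(net.gene_ids):
        raise DataValidationError("tour must visit exactly the network's genes")
    canon = canonical_tour(list(order))
    edges = []
    total = 0.0
    for a, b in zip(canon, canon[1:] + canon[:1]):
        w = net.weight(a, b)
        total += w
        edges.append((a, b, w))
    return TourSolution(order=canon, total_weight=total, edges=EdgeList(edges))


def solve_tsp_max(net: CorrelationNetwork, exact_limit: int = 20) -> TourSolution:
    """Globally maximum-weight Hamiltonian cycle by Held-Karp subset DP.

    Runs in O(2^n n^2) time; ``exact_limit`` caps n because the method's
    guarantee is exact optimality -- for larger gene lists, select fewer
    genes rather than accepting a heuristic.  Among co-optimal tours the
    lexicographically smallest canonical order is returned.
    """
    n = net.n
    if n < 3:
        raise DataValidationError("TSP needs at least 3 genes")
    if n > exact_limit:
        raise DataValidationError(
            f"{n} genes exceeds the exact-solver limit ({exact_limit}); "
            "select a smaller gene list (e.g. fewer Pareto layers)"
        )
    genes, w = _sorted_net(net)
    m = n - 1  # non-start nodes 1..n-1 -> bits 0..m-1
    full = (1 << m) - 1
    # h[mask][cur]: best weight of a path cur -> (nodes not in mask) -> start,
    # where mask is the set of already-visited non-start nodes (cur included).
    h = np.full((full + 1, m), -np.inf)
    h[full, :] = w[1:, 0]
    nonstart = np.arange(1, n)
    for mask in range(full - 1, 0, -1):
        members = [c for c in range(m) if mask >> c & 1]
        rest = np.array([c for c in range(m) if not mask >> c & 1])
        nxt_masks = mask | (1 << rest)
        for cur in members:
            h[mask, cur] = np.max(w[cur + 1, rest + 1] + h[nxt_masks, rest])
    first_vals = w[0, 1:] + h[1 << np.arange(m), np.arange(m)]
    total = float(np.max(first_vals))
    # greedy lexicographic reconstruction among optimal completions
    order_idx = [0]
    mask = 0
    cur = 0  # start node
    need = total
    for _ in range(m):
        for c in range(m):
            if mask >> c & 1:
                continue
            if w[cur, c + 1] + h[mask | (1 << c), c] >= need - WEIGHT_TOL:
                order_idx.append(c + 1)
                need -= w[cur, c + 1]
                mask |= 1 << c
                cur = c + 1
                break
        else:  # pragma: no cover - DP bookkeeping guarantees a choice
            raise AssertionError("tour reconstruction failed")
    return tour_from_order(net, [genes[i] for i in order_idx])


def brute_force_tsp(net: CorrelationNetwork, limit: int = 11) -> tuple[TourSolution, int]:
    """Exhaustive tour enumeration oracle.

    Enumerates all (n-1)!/2 undirected Hamiltonian cycles (each undirected
    cycle visited once, in its canonical direction), returns the maximum
    with the same lexicographic tie-break as :func:`solve_tsp_max`, plus
    the number of tours enumerated.
    """
    n = net.n
    if not 3 <= n <= limit:
        raise DataValidationError(f"brute force supports 3 <= n <= {limit}, got {n}")
    genes, w = _sorted_net(net)
    rows = w.tolist()
    best = -1.0
    best_perm: tuple[int, ...] | None = None
    count = 0
    r0 = rows[0]
    for p in permutations(range(1, n)):
        if p[0] > p[-1]:
            continue  # the mirror direction of an already-seen cycle
        count += 1
        prev = p[0]
        total = r0[prev]
        for x in p[1:]:
            total += rows[prev][x]
            prev = x
        total += rows[prev][0]
        if total > best:  # permutations arrive in lex order: first max is lex-min
            best = total
            best_perm = p
    assert best_perm is not None
    tour = tour_from_order(net, [genes[0]] + [genes[i] for i in best_perm])
    return tour, count


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def solve_mst_max(net: CorrelationNetwork) -> TreeSolution:
    """Maximum-weight spanning tree by greedy (Kruskal) edge insertion.

    Equivalent to a minimum spanning tree under cost ``1 - |rho|``.  Edges
    are considered by descending weight, ties broken by lexicographic
    endpoint pair, so the result is deterministic even on tied weights.
    """
    if net.n < 2:
        raise DataValidationError("MST needs at least 2 genes")
    candidates = sorted(net.edge_list().edges, key=lambda e: (-e[2], e[0], e[1]))
    uf = _UnionFind(net.gene_ids)
    chosen = []
    for a, b, w in candidates:
        if uf.union(a, b):
            chosen.append((a, b, w))
            if len(chosen) == net.n - 1:
                break
    el = EdgeList(chosen)
    return TreeSolution(edges=el, total_weight=el.total_weight)


def enumerate_spanning_trees_max(net: CorrelationNetwork) -> tuple[TreeSolution, int]:
    """Exhaustive spanning-tree oracle via Prufer sequences.

    Visits all n^(n-2) labeled trees (Cayley's count) and returns the
    maximum-weight one; ties resolved toward the lexicographically smallest
    sorted edge list.  Practical for n <= ~8.
    """
    import networkx as nx

    n = net.n
    genes, w = _sorted_net(net)
    if n == 2:
        el = EdgeList([(genes[0], genes[1], float(w[0, 1]))])
        return TreeSolution(edges=el, total_weight=el.total_weight), 1
    best_w = -1.0
    best_edges: list[tuple[int, int]] | None = None
    count = 0
    for seq in product(range(n), repeat=n - 2):
        count += 1
        tree = nx.from_prufer_sequence(list(seq))
        edges = sorted(tuple(sorted(e)) for e in tree.edges())
        total = float(sum(w[i, j] for i, j in edges))
        if total > best_w + WEIGHT_TOL or (
            abs(total - best_w) <= WEIGHT_TOL and (best_edges is None or edges < best_edges)
        ):
            best_w = total
            best_edges = edges
    assert best_edges is not None
    el = EdgeList([(genes[i], genes[j], float(w[i, j])) for i, j in best_edges])
    return TreeSolution(edges=el, total_weight=el.total_weight), count


def tree_exchange_optimal(net: CorrelationNetwork, tree: TreeSolution, tol: float = WEIGHT_TOL) -> bool:
    """Cut-exchange optimality certificate for a spanning tree.

    For every tree edge, removing it splits the genes into two components;
    the tree is maximum iff no non-tree edge across that cut is heavier than
    the removed edge.  This certifies global optimality without enumeration.
    """
    nodes = net.gene_ids
    adj: dict[str, list[tuple[str, float]]] = {v: [] for v in nodes}
    for a, b, w in tree.edges.edges:
        adj[a].append((b, w))
        adj[b].append((a, w))
    for a, b, w in tree.edges.edges:
        # component containing `a` after removing edge (a, b)
        comp = {a}
        stack = [a]
        while stack:
            u = stack.pop()
            for v, _ in adj[u]:
                if v not in comp and not (u == a and v == b) and not (u == b and v == a):
                    comp.add(v)
                    stack.append(v)
        for u in comp:
            for v in nodes:
                if v not in comp and net.weight(u, v) > w + tol:
                    return False
    return True


@dataclass
class FlowTspModel:
    """Single-commodity flow MILP data for the tour problem.

    Arcs are all ordered pairs (i, j), i != j, of the lexicographically
    sorted gene list; costs are the *negated* absolute correlations, so
    that minimizing total cost maximizes total correlation.  ``incidence``
    has +1 at the tail row and -1 at the head row of each arc; ``supply``
    puts n-1 units at the source (first gene) and a demand of 1 everywhere
    else.
    """

    gene_ids: list[str]  # sorted; gene_ids[0] is the flow source
    arcs: list[tuple[int, int]]
    costs: np.ndarray  # length m, c_ij = -|rho_ij|
    incidence: np.ndarray  # n x m, columns sum to zero
    supply: np.ndarray  # length n, sums to zero

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    @property
    def m(self) -> int:
        return len(self.arcs)

    def arc_index(self, tail: str, head: str) -> int:
        i = self.gene_ids.index(tail)
        j = self.gene_ids.index(head)
        return self.arcs.index((i, j))


def build_flow_formulation(net: CorrelationNetwork) -> FlowTspModel:
    if net.n < 3:
        raise DataValidationError("flow formulation needs at least 3 genes")
    genes, w = _sorted_net(net)
    n = len(genes)
    arcs = [(i, j) for i in range(n) for j in range(n) if i != j]
    m = len(arcs)
    costs = np.array([-w[i, j] for i, j in arcs])
    incidence = np.zeros((n, m))
    for k, (i, j) in enumerate(arcs):
        incidence[i, k] = 1.0  # tail: flow leaves i
        incidence[j, k] = -1.0  # head: flow arrives at j
    supply = np.full(n, -1.0)
    supply[0] = n - 1.0
    return FlowTspModel(genes, arcs, costs, incidence, supply)


@dataclass
class FeasibilityReport:
    """Per-constraint-family verdicts for an arc selection of the flow model."""

    degree_out_ok: bool  # one arc leaves every node
    degree_in_ok: bool  # one arc enters every node
    flow_balance_ok: bool  # Nx = b admits / holds
    forcing_ok: bool  # x_ij <= (n-1) y_ij
    nonnegative_ok: bool  # x >= 0
    binary_ok: bool  # y in {0, 1}
    total_cost: float | None = None

    @property
    def feasible(self) -> bool:
        return (
            self.degree_out_ok
            and self.degree_in_ok
            and self.flow_balance_ok
            and self.forcing_ok
            and self.nonnegative_ok
            and self.binary_ok
        )


def _degree_checks(model: FlowTspModel, y: np.ndarray) -> tuple[bool, bool, bool]:
    n = model.n
    out_deg = np.zeros(n)
    in_deg = np.zeros(n)
    for k, (i, j) in enumerate(model.arcs):
        out_deg[i] += y[k]
        in_deg[j] += y[k]
    binary_ok = bool(np.all((y == 0) | (y == 1)))
    return bool(np.all(out_deg == 1)), bool(np.all(in_deg == 1)), binary_ok


def check_tour_feasibility(model: FlowTspModel, tour: TourSolution) -> FeasibilityReport:
    """Verify that a tour satisfies every constraint family of the flow model.

    The arc selection follows the tour's canonical direction from the
    source; flows carry n-1, n-2, ..., 1 units along successive tour arcs
    (the closing arc carries none).  All checks are exact.
    """
    if set(tour.order) != set(model.gene_ids):
        raise DataValidationError("tour genes differ from model genes")
    n = model.n
    # rotate the canonical cycle so it starts at the model's source gene
    k = tour.order.index(model.gene_ids[0])
    seq = tour.order[k:] + tour.order[:k]
    y = np.zeros(model.m)
    x = np.zeros(model.m)
    for step, (a, b) in enumerate(zip(seq, seq[1:] + seq[:1])):
        idx = model.arc_index(a, b)
        y[idx] = 1.0
        x[idx] = float(n - 1 - step)  # n-1, n-2, ..., 1, then 0 on the closing arc
    out_ok, in_ok, binary_ok = _degree_checks(model, y)
    balance_ok = bool(np.array_equal(model.incidence @ x, model.supply))
    forcing_ok = bool(np.all(x <= (n - 1) * y))
    nonneg_ok = bool(np.all(x >= 0))
    cost = float(model.costs @ y)
    return FeasibilityReport(out_ok, in_ok, balance_ok, forcing_ok, nonneg_ok, binary_ok, cost)


def check_selection_feasibility(
    model: FlowTspModel, selected_arcs: list[tuple[str, str]]
) -> FeasibilityReport:
    """Check an arbitrary directed arc selection against the flow model.

    Degree and binarity constraints are checked directly; the flow system
    (balance, forcing, nonnegativity) is decided by a linear-programming
    feasibility problem: does any x >= 0 with Nx = b and
    x_a <= (n-1) y_a exist?  A selection made of disjoint subtours passes
    the degree checks but the flow system is infeasible -- the
    subtour-elimination argument in executable form.
    """
    from scipy.optimize import linprog

    y = np.zeros(model.m)
    for a, b in selected_arcs:
        y[model.arc_index(a, b)] = 1.0
    out_ok, in_ok, binary_ok = _degree_checks(model, y)
    n = model.n
    bounds = [(0.0, (n - 1) * float(yk)) for yk in y]
    res = linprog(
        c=np.zeros(model.m),
        A_eq=model.incidence,
        b_eq=model.supply,
        bounds=bounds,
        method="highs",
    )
    flow_ok = bool(res.status == 0)
    cost = float(model.costs @ y)
    # when the system is infeasible, balance and forcing jointly fail
    return FeasibilityReport(
        degree_out_ok=out_ok,
        degree_in_ok=in_ok,
        flow_balance_ok=flow_ok,
        forcing_ok=flow_ok,
        nonnegative_ok=True,
        binary_ok=binary_ok,
        total_cost=cost,
    )


@dataclass(frozen=True)
class CountReport:
    """Exact solution-space sizes: (n-1)! directed tours, n^(n-2) labeled trees."""

    n: int
    tour_count: int
    tree_count: int


def count_solutions(n: int) -> CountReport:
    if not isinstance(n, (int, np.integer)) or n < 2:
        raise ValueError("count_solutions needs an integer n >= 2")
    n = int(n)
    return CountReport(n=n, tour_count=math.factorial(n - 1), tree_count=n ** (n - 2))
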