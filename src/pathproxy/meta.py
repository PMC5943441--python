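"""Pairwise-comparison pipeline runs and conserved-relation reporting.

For every pair of condition groups the full chain is executed -- Pareto
preselection, difference-correlation network, exact tour and tree -- and
the resulting solutions are compared across condition pairs: which
undirected gene-gene edges recur in several comparisons' tours, trees, or
both, and which *blocks* (maximal chains of jointly recurring edges) they
form.  Recurring blocks are the meta-analysis output: gene relations that a
single comparison might produce by chance but several independent
comparisons are unlikely to.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .diffcorr import correlation_network, difference_vectors
from .exprdata import CorrelationNetwork, DataValidationError, ExpressionMatrix, GroupDesign
from .mco import ParetoSelection, select_biomarkers
from .netopt import TourSolution, TreeSolution, solve_mst_max, solve_tsp_max

__all__ = [
    "ComparisonResult",
    "SharedRelationReport",
    "run_comparison",
    "run_all_comparisons",
    "shared_relations",
]


@dataclass
class ComparisonResult:
    """One condition pair's selected genes, network, tour and tree."""

    label: str
    group_a: str
    group_b: str
    selection: ParetoSelection
    network: CorrelationNetwork
    tour: TourSolution
    tree: TreeSolution

    def __post_init__(self) -> None:
        genes = set(self.network.gene_ids)
        if set(self.tour.order) != genes or set(self.tree.edges.nodes()) != genes:
            raise DataValidationError("solutions must cover exactly the selected genes")


def run_comparison(
    expr: ExpressionMatrix,
    design: GroupDesign,
    group_a: str,
    group_b: str,
    n_layers: int = 1,
    pairing: str = "all_pairs",
    exact_limit: int = 20,
) -> ComparisonResult:
    """select -> correlate -> tour + tree for one pair of groups.

    ``group_a`` plays the control role in the difference construction.  A
    selection larger than the exact-solver limit raises with advice to
    reduce ``n_layers`` rather than silently truncating.
    """
    selection = select_biomarkers(expr, design, group_a, group_b, n_layers=n_layers)
    genes = sorted(selection.selected)
    if len(genes) < 3:
        raise DataValidationError(
            f"{group_a} vs {group_b}: only {len(genes)} genes selected; "
            "a tour needs at least 3 (increase n_layers)"
        )
    if len(genes) > exact_limit:
        raise DataValidationError(
            f"{group_a} vs {group_b}: {len(genes)} genes selected, beyond the "
            f"exact-solver limit ({exact_limit}); lower n_layers for a finer selection"
        )
    sub = expr.subset_genes(genes)
    diffs = difference_vectors(sub, design, group_a, group_b, pairing=pairing)
    net = correlation_network(diffs)
    return ComparisonResult(
        label=f"{group_a}_vs_{group_b}",
        group_a=group_a,
        group_b=group_b,
        selection=selection,
        network=net,
        tour=solve_tsp_max(net, exact_limit=exact_limit),
        tree=solve_mst_max(net),
    )


def run_all_comparisons(
    expr: ExpressionMatrix,
    design: GroupDesign,
    n_layers: int = 1,
    pairing: str = "all_pairs",
    exact_limit: int = 20,
) -> list[ComparisonResult]:
    """Every unordered pair of groups, in sorted label order.

    Four conditions yield the six pairwise analyses of the meta-analysis
    design.
    """
    groups = design.groups
    return [
        run_comparison(expr, design, a, b, n_layers=n_layers, pairing=pairing, exact_limit=exact_limit)
        for a, b in combinations(groups, 2)
    ]


Edge = tuple[str, str]


@dataclass
class SharedRelationReport:
    """Edge-recurrence tallies and maximal shared blocks across comparisons.

    ``tour_support``/``tree_support``/``both_support`` map each undirected
    edge to the ordered set of comparison labels whose tour / tree / both
    contain it.  ``blocks`` maps each category to maximal chains of edges
    that recur in the *same* set of comparisons (at least ``min_support``
    of them).
    """

    comparisons: list[str]
    tour_support: dict[Edge, list[str]]
    tree_support: dict[Edge, list[str]]
    both_support: dict[Edge, list[str]]
    blocks: dict[str, list[tuple[list[str], list[str]]]]  # category -> [(gene chain, comparisons)]
    min_support: int


def _edge_key(a: str, b: str) -> Edge:
    return (a, b) if a < b else (b, a)


def _tally(edge_sets: dict[str, set[Edge]]) -> dict[Edge, list[str]]:
    support: dict[Edge, list[str]] = {}
    for label in sorted(edge_sets):
        for e in edge_sets[label]:
            support.setdefault(e, []).append(label)
    return dict(sorted(support.items()))


def _maximal_chains(edges: list[Edge]) -> list[list[str]]:
    """Decompose an edge set into maximal simple paths (degree-<=2 chains).

    Nodes of degree != 2 are chain endpoints; a component where every node
    has degree 2 is a cycle and is reported as a closed chain starting at
    its lexicographically smallest gene.
    """
    adj: dict[str, list[str]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    for v in adj:
        adj[v].sort()
    unused = set(edges)
    chains: list[list[str]] = []

    def walk(start: str, nxt: str) -> list[str]:
        chain = [start, nxt]
        unused.discard(_edge_key(start, nxt))
        while len(adj[chain[-1]]) == 2:
            a, b = adj[chain[-1]]
            step = b if a == chain[-2] else a
            if _edge_key(chain[-1], step) not in unused:
                break
            unused.discard(_edge_key(chain[-1], step))
            chain.append(step)
        return chain

    endpoints = sorted(v for v in adj if len(adj[v]) != 2)
    for v in endpoints:
        for u in adj[v]:
            if _edge_key(v, u) in unused:
                chains.append(walk(v, u))
    while unused:  # leftover components are cycles
        a, b = min(unused)
        chains.append(walk(a, b))
    chains.sort()
    return chains


def shared_relations(results: list[ComparisonResult], min_support: int = 2) -> SharedRelationReport:
    """Tally edge recurrence across comparisons and extract shared blocks.

    Blocks are computed per category (tour, tree, both): edges meeting
    ``min_support`` are grouped by their exact comparison-support set, and
    each group is decomposed into maximal simple chains.
    """
    if len(results) < 2:
        raise DataValidationError("shared_relations needs at least two comparisons")
    if min_support < 2:
        raise ValueError("min_support must be >= 2")
    labels = [r.label for r in results]
    if len(set(labels)) != len(labels):
        raise DataValidationError("comparison labels must be unique")

    tour_sets = {
        r.label: {_edge_key(a, b) for a, b, _ in r.tour.edges.edges} for r in results
    }
    tree_sets = {
        r.label: {_edge_key(a, b) for a, b, _ in r.tree.edges.edges} for r in results
    }
    both_sets = {lbl: tour_sets[lbl] & tree_sets[lbl] for lbl in tour_sets}

    supports = {
        "tour": _tally(tour_sets),
        "tree": _tally(tree_sets),
        "both": _tally(both_sets),
    }
    blocks: dict[str, list[tuple[list[str], list[str]]]] = {}
    for category, support in supports.items():
        by_comp_set: dict[tuple[str, ...], list[Edge]] = {}
        for e, comps in support.items():
            if len(comps) >= min_support:
                by_comp_set.setdefault(tuple(comps), []).append(e)
        cat_blocks: list[tuple[list[str], list[str]]] = []
        for comps, edges in sorted(by_comp_set.items()):
            for chain in _maximal_chains(edges):
                cat_blocks.append((chain, list(comps)))
        cat_blocks.sort()
        blocks[category] = cat_blocks

    return SharedRelationReport(
        comparisons=sorted(labels),
        tour_support=supports["tour"],
        tree_support=supports["tree"],
        both_support=supports["both"],
        blocks=blocks,
        min_support=min_support,
    )
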