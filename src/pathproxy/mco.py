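"""Multiple-criteria (Pareto) preselection of candidate biomarker genes.

Each gene is scored by two conflicting criteria computed between two sample
groups: the absolute difference of group means and the absolute difference
of group medians, both in the (unitless) expression scale of the input
matrix.  A gene *dominates* another if it is >= on both criteria and > on
at least one (maximize-maximize).  The first Pareto front is the set of
non-dominated genes; "peeling" removes a front and recomputes the next,
yielding an ordered layering of the gene list.

No distributional assumptions and no significance thresholds are involved:
the selection is fully deterministic given the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exprdata import DataValidationError, ExpressionMatrix, GroupDesign

__all__ = [
    "CriterionScores",
    "ParetoSelection",
    "compute_criteria",
    "pareto_front",
    "select_biomarkers",
]


@dataclass(frozen=True)
class CriterionScores:
    """Per-gene criterion pair: (|mean_B - mean_A|, |median_B - median_A|)."""

    gene_id: str
    mean_abs_diff: float
    median_abs_diff: float

    def __post_init__(self) -> None:
        for v in (self.mean_abs_diff, self.median_abs_diff):
            if not np.isfinite(v) or v < 0:
                raise DataValidationError(
                    f"invalid criterion score for {self.gene_id!r}: {v}"
                )


@dataclass
class ParetoSelection:
    """Layered Pareto selection: ``layers[0]`` is the first front."""

    layers: list[set[str]]
    criteria: list[CriterionScores]
    exhausted: bool  # True when peeling ran out of genes before n_layers

    @property
    def selected(self) -> set[str]:
        out: set[str] = set()
        for layer in self.layers:
            out |= layer
        return out

    def layer_of(self, gene_id: str) -> int:
        """1-based layer index of a selected gene."""
        for k, layer in enumerate(self.layers, start=1):
            if gene_id in layer:
                return k
        raise KeyError(f"gene {gene_id!r} not in selection")


def compute_criteria(
    expr: ExpressionMatrix,
    design: GroupDesign,
    group_a: str,
    group_b: str,
) -> list[CriterionScores]:
    """Score every gene by |Δmean| and |Δmedian| between two groups.

    Means and medians are computed within each group on the stored values
    as-is; the direction of the difference is irrelevant because absolute
    values are taken.
    """
    a_cols = expr.sample_columns(design.samples_for(group_a))
    b_cols = expr.sample_columns(design.samples_for(group_b))
    d_mean = np.abs(b_cols.mean(axis=1) - a_cols.mean(axis=1))
    d_median = np.abs(np.median(b_cols, axis=1) - np.median(a_cols, axis=1))
    return [
        CriterionScores(g, float(m), float(md))
        for g, m, md in zip(expr.gene_ids, d_mean, d_median)
    ]


def pareto_front(scores: list[CriterionScores]) -> set[str]:
    """Non-dominated gene set under maximize-maximize dominance.

    Genes with identical score pairs are all retained.  Runs in
    O(n log n) via a sort-and-sweep skyline; an O(n^2) pairwise check is
    used as an independent oracle in the test suite.
    """
    if not scores:
        raise DataValidationError("pareto_front needs at least one score")
    order = sorted(scores, key=lambda s: (-s.mean_abs_diff, -s.median_abs_diff))
    front: set[str] = set()
    best_b_prev = -np.inf  # max median_abs_diff over strictly larger mean_abs_diff
    i = 0
    n = len(order)
    while i < n:
        j = i
        while j < n and order[j].mean_abs_diff == order[i].mean_abs_diff:
            j += 1
        group = order[i:j]
        group_max = max(s.median_abs_diff for s in group)
        if group_max > best_b_prev:
            front.update(s.gene_id for s in group if s.median_abs_diff == group_max)
        best_b_prev = max(best_b_prev, group_max)
        i = j
    return front


def select_biomarkers(
    expr: ExpressionMatrix,
    design: GroupDesign,
    group_a: str,
    group_b: str,
    n_layers: int = 1,
) -> ParetoSelection:
    """Iteratively peel ``n_layers`` Pareto fronts off the criteria cloud.

    If the gene list is exhausted before ``n_layers`` fronts were peeled the
    selection is returned with ``exhausted=True`` rather than raising:
    asking for more layers than exist is a soft condition.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    criteria = compute_criteria(expr, design, group_a, group_b)
    remaining = {s.gene_id: s for s in criteria}
    layers: list[set[str]] = []
    while remaining and len(layers) < n_layers:
        front = pareto_front(list(remaining.values()))
        layers.append(front)
        for g in front:
            del remaining[g]
    exhausted = not remaining and len(layers) < n_layers
    return ParetoSelection(layers=layers, criteria=criteria, exhausted=exhausted)
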