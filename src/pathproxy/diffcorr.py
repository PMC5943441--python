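"""Expression-difference vectors and the absolute Pearson correlation network.

For every gene the control and case samples are turned into a vector of
case-minus-control expression differences over a *common* pair ordering.
With ``all_pairs`` pairing every control sample is differenced against every
case sample (n_control x n_case values per gene, ordered lexicographically
by control position then case position); ``matched`` pairing uses an
explicit or positional one-to-one match.  Because every gene shares the
pair ordering, the Pearson correlation between two genes' difference
vectors is well defined; its absolute value is the edge weight of the
network handed to the optimizers.

All-pairs difference vectors reuse each sample many times, so their entries
are statistically dependent; the correlations are descriptive weights, and
no inferential claim (p-value, CI) is attached to them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exprdata import (
    CorrelationNetwork,
    DataValidationError,
    ExpressionMatrix,
    GroupDesign,
)

__all__ = ["PairedDifferenceSet", "difference_vectors", "pearson", "correlation_network"]


@dataclass
class PairedDifferenceSet:
    """Per-gene case-minus-control differences over one shared pair ordering."""

    gene_ids: list[str]
    pair_index: list[tuple[str, str]]  # (control_sample_id, case_sample_id)
    diffs: np.ndarray  # genes x pairs

    def __post_init__(self) -> None:
        self.diffs = np.asarray(self.diffs, dtype=float)
        if self.diffs.shape != (len(self.gene_ids), len(self.pair_index)):
            raise DataValidationError(
                f"diff grid shape {self.diffs.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.pair_index)} pairs"
            )
        if not np.all(np.isfinite(self.diffs)):
            raise DataValidationError("non-finite difference value")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_index)


def difference_vectors(
    expr: ExpressionMatrix,
    design: GroupDesign,
    control_label: str,
    case_label: str,
    pairing: str = "all_pairs",
    matches: Sequence[tuple[str, str]] | None = None,
) -> PairedDifferenceSet:
    """Build the shared-ordering difference vectors for every gene.

    Sign convention is case - control; the downstream absolute correlations
    are provably invariant to the consistent alternative.
    """
    controls = design.samples_for(control_label)
    cases = design.samples_for(case_label)
    ctrl = expr.sample_columns(controls)  # genes x n_control
    case = expr.sample_columns(cases)  # genes x n_case

    if pairing == "all_pairs":
        # lexicographic by (control position, case position)
        pair_index = [(c, a) for c in controls for a in cases]
        diffs = (case[:, None, :] - ctrl[:, :, None]).reshape(expr.n_genes, -1)
    elif pairing == "matched":
        if matches is not None:
            pair_index = [(str(c), str(a)) for c, a in matches]
            ci = {s: i for i, s in enumerate(controls)}
            ai = {s: i for i, s in enumerate(cases)}
            try:
                c_idx = [ci[c] for c, _ in pair_index]
                a_idx = [ai[a] for _, a in pair_index]
            except KeyError as exc:
                raise DataValidationError(f"match references unknown sample: {exc}") from exc
        elif len(controls) == len(cases):
            pair_index = list(zip(controls, cases))
            c_idx = list(range(len(controls)))
            a_idx = list(range(len(cases)))
        else:
            raise DataValidationError(
                "matched pairing needs an explicit match list or equal group sizes "
                f"(got {len(controls)} controls vs {len(cases)} cases)"
            )
        if not pair_index:
            raise DataValidationError("matched pairing resolved to zero pairs")
        diffs = case[:, a_idx] - ctrl[:, c_idx]
    else:
        raise ValueError(f"unknown pairing {pairing!r}; choose all_pairs or matched")

    return PairedDifferenceSet(list(expr.gene_ids), pair_index, diffs)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation (n-1 normalization), in [-1, 1].

    A zero-variance input has no defined correlation and raises rather than
    silently returning 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson needs two equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("pearson needs n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataValidationError("correlation undefined for a zero-variance vector")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) > 1.0 + 1e-12:
        raise AssertionError(f"|rho| exceeded 1 beyond tolerance: {r}")
    return float(np.clip(r, -1.0, 1.0))


def correlation_network(d: PairedDifferenceSet) -> CorrelationNetwork:
    """Absolute Pearson correlations between all gene difference vectors.

    weights[i][j] = |rho(diffs[i], diffs[j])| for i != j, diagonal 0.  A
    constant difference vector is rejected with the offending gene named.
    """
    if len(d.gene_ids) < 2:
        raise DataValidationError("need at least 2 genes to build a network")
    spans = np.ptp(d.diffs, axis=1)
    flat = np.nonzero(spans == 0)[0]
    if flat.size:
        raise DataValidationError(
            f"constant difference vector for gene {d.gene_ids[int(flat[0])]!r}; "
            "its correlation is undefined"
        )
    r = np.corrcoef(d.diffs)
    w = np.abs(r)
    if np.any(w > 1.0 + 1e-12):
        raise AssertionError("|rho| exceeded 1 beyond tolerance")
    w = np.minimum(w, 1.0)
    w = (w + w.T) / 2.0  # exact symmetry against float asymmetries
    np.fill_diagonal(w, 0.0)
    return CorrelationNetwork(list(d.gene_ids), w)
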