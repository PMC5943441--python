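"""Synthetic expression data with planted ground truth.

The generator emulates the statistical structure the pipeline is built to
exploit, without imitating any particular platform's noise: background
genes are i.i.d. Normal(mu, sigma^2) in every group, while *planted* genes
receive, in case samples only, a mean shift of ``delta_g * sigma`` plus a
coordinated per-sample latent chain effect.  The chain is a stationary
AR(1) across the planted genes: for case sample s,

    e[0, s] ~ N(0, 1),   e[j, s] = phi * e[j-1, s] + sqrt(1 - phi^2) * xi,

so the latent correlation between planted genes j and j' is
``phi**|j - j'|`` -- a correlation *chain* whose maximum-correlation
spanning tree is the path 0-1-...-b-1.  The chain enters the expression
values with amplitude ``lambda = chain_to_shift_ratio * delta * sigma``,
coupling coordination strength to differential-expression strength (a gene
that does not move between groups carries no coordinated signal either, so
``delta = 0`` collapses planted genes to exact background behavior).

Because the chain lives in the case samples, it surfaces exactly where the
pipeline computes correlations: in case-minus-control difference vectors.
There it is attenuated by the independent noise of both samples; for equal
shifts the difference-correlation between planted genes j and j' is

    rho(j, j') = phi**|j - j'| * lambda^2 / (lambda^2 + 2 * sigma^2)

under matched pairing (and the same value in the all-pairs population),
which :func:`expected_chain_correlation` computes for tests.

Randomness is organized as deterministic substreams keyed by
(seed, group label, gene), so regenerating one condition or gene never
perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exprdata import ExpressionMatrix, GroupDesign

__all__ = [
    "SyntheticSpec",
    "ConditionSpec",
    "expected_chain_correlation",
    "generate",
    "generate_four_condition",
]

_CHAIN_STREAM = 7
_BG_STREAM = 1000
_PL_STREAM = 2000


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-design parameters of the two-group generator.

    delta is the case-group mean shift of each planted gene in units of
    sigma (scalar, or one value per planted gene); phi is the AR(1)
    coefficient of the planted correlation chain; chain_to_shift_ratio
    converts shift size into coordinated-signal amplitude.
    """

    seed: int
    n_background: int = 100
    n_planted: int = 8
    n_control: int = 30
    n_case: int = 30
    mu: float = 8.0
    sigma: float = 1.0
    delta: float | Sequence[float] = 5.0
    phi: float = 0.8
    chain_to_shift_ratio: float = 0.6
    control_label: str = "control"
    case_label: str = "cancer"

    def __post_init__(self) -> None:
        if min(self.n_background, self.n_planted, self.n_control, self.n_case) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if np.any(np.asarray(self.deltas) < 0):
            raise ValueError("delta must be non-negative")

    @property
    def deltas(self) -> np.ndarray:
        d = np.asarray(self.delta, dtype=float)
        if d.ndim == 0:
            return np.full(self.n_planted, float(d))
        if d.shape != (self.n_planted,):
            raise ValueError(f"delta must be scalar or length {self.n_planted}")
        return d


def expected_chain_correlation(spec: SyntheticSpec, lag: int = 1) -> float:
    """Population |rho| between planted difference vectors at chain distance ``lag``.

    Valid for equal per-gene shifts; derived from the generator's variance
    bookkeeping (chain amplitude lambda vs. 2 sigma^2 of independent
    control+case noise in each difference).
    """
    lam = spec.chain_to_shift_ratio * float(np.mean(spec.deltas)) * spec.sigma
    s2 = spec.sigma**2
    return spec.phi**lag * lam**2 / (lam**2 + 2.0 * s2)


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(list(key))


def _label_key(label: str) -> int:
    return zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF


def _condition_block(
    seed: int,
    label: str,
    n_samples: int,
    n_background: int,
    n_planted: int,
    mu: float,
    sigma: float,
    shifts: np.ndarray,  # per planted gene, sigma units (0 for control-like)
    phi: float,
    chain_amplitudes: np.ndarray,  # per planted gene, sigma units
) -> np.ndarray:
    """One condition's (background+planted) x n_samples block."""
    lk = _label_key(label)
    block = np.empty((n_background + n_planted, n_samples))
    for g in range(n_background):
        block[g] = _rng(seed, lk, _BG_STREAM + g).normal(mu, sigma, n_samples)
    if np.any(chain_amplitudes > 0):
        crng = _rng(seed, lk, _CHAIN_STREAM)
        e = np.empty((n_planted, n_samples))
        e[0] = crng.normal(0.0, 1.0, n_samples)
        for j in range(1, n_planted):
            e[j] = phi * e[j - 1] + np.sqrt(1.0 - phi**2) * crng.normal(0.0, 1.0, n_samples)
    else:
        e = np.zeros((n_planted, n_samples))
    for j in range(n_planted):
        base = _rng(seed, lk, _PL_STREAM + j).normal(mu, sigma, n_samples)
        block[n_background + j] = base + shifts[j] * sigma + chain_amplitudes[j] * sigma * e[j]
    return block


def _gene_ids(n_background: int, n_planted: int) -> list[str]:
    bg = [f"BG{g:04d}" for g in range(n_background)]
    pl = [f"PL{j:02d}" for j in range(n_planted)]
    return bg + pl


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroupDesign, dict]:
    """Two-group matrix with planted differential expression and chain.

    Returns the expression matrix, the control/case design, and a truth
    record listing the planted gene ids in chain order, the background ids,
    and the generating parameters.
    """
    deltas = spec.deltas
    lam = spec.chain_to_shift_ratio * deltas  # sigma units, per gene
    genes = _gene_ids(spec.n_background, spec.n_planted)
    ctrl = _condition_block(
        spec.seed,
        spec.control_label,
        spec.n_control,
        spec.n_background,
        spec.n_planted,
        spec.mu,
        spec.sigma,
        shifts=np.zeros(spec.n_planted),
        phi=spec.phi,
        chain_amplitudes=np.zeros(spec.n_planted),
    )
    case = _condition_block(
        spec.seed,
        spec.case_label,
        spec.n_case,
        spec.n_background,
        spec.n_planted,
        spec.mu,
        spec.sigma,
        shifts=deltas,
        phi=spec.phi,
        chain_amplitudes=lam,
    )
    ctrl_ids = [f"{spec.control_label}_{i:03d}" for i in range(spec.n_control)]
    case_ids = [f"{spec.case_label}_{i:03d}" for i in range(spec.n_case)]
    expr = ExpressionMatrix(genes, ctrl_ids + case_ids, np.hstack([ctrl, case]))
    design = GroupDesign(
        {**{s: spec.control_label for s in ctrl_ids}, **{s: spec.case_label for s in case_ids}}
    )
    truth = {
        "planted": genes[spec.n_background :],
        "background": genes[: spec.n_background],
        "chain_order": genes[spec.n_background :],
        "delta": deltas.tolist(),
        "phi": spec.phi,
        "chain_to_shift_ratio": spec.chain_to_shift_ratio,
        "expected_adjacent_correlation": expected_chain_correlation(spec, 1),
        "seed": spec.seed,
    }
    return expr, design, truth


@dataclass(frozen=True)
class ConditionSpec:
    """One condition of a multi-group design.

    ``delta`` and ``chain`` describe how this condition's planted genes
    deviate from baseline; conditions with identical delta/chain settings
    but different seeds are exchangeable replicates.
    """

    label: str
    n_samples: int
    seed: int
    delta: float | Sequence[float] = 0.0
    chain: bool = False


def default_four_conditions(seed: int, delta: float = 5.0) -> list[ConditionSpec]:
    """Healthy/cancer x never/current-smoker layout (sizes 15/16/16/24)."""
    return [
        ConditionSpec("HNS", 15, seed, delta=0.0, chain=False),
        ConditionSpec("HCS", 16, seed, delta=0.0, chain=False),
        ConditionSpec("CNS", 16, seed, delta=delta, chain=True),
        ConditionSpec("CCS", 24, seed, delta=delta, chain=True),
    ]


def generate_four_condition(
    base: SyntheticSpec,
    conditions: Sequence[ConditionSpec] | None = None,
) -> tuple[ExpressionMatrix, GroupDesign, dict]:
    """One matrix holding several condition groups over a shared gene space.

    The default layout emulates a four-condition lung study (healthy/cancer
    crossed with smoking status) and supports all six pairwise comparisons.
    Every condition draws from its own substream, so changing one
    condition's seed leaves the other conditions' submatrices untouched.
    """
    if conditions is None:
        conditions = default_four_conditions(base.seed)
    labels = [c.label for c in conditions]
    if len(set(labels)) != len(labels):
        raise ValueError("condition labels must be unique")
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    genes = _gene_ids(base.n_background, base.n_planted)
    blocks = []
    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    for cond in conditions:
        d = np.asarray(cond.delta, dtype=float)
        deltas = np.full(base.n_planted, float(d)) if d.ndim == 0 else d
        if deltas.shape != (base.n_planted,):
            raise ValueError(f"condition {cond.label!r}: delta length mismatch")
        lam = base.chain_to_shift_ratio * deltas if cond.chain else np.zeros(base.n_planted)
        blocks.append(
            _condition_block(
                cond.seed,
                cond.label,
                cond.n_samples,
                base.n_background,
                base.n_planted,
                base.mu,
                base.sigma,
                shifts=deltas,
                phi=base.phi,
                chain_amplitudes=lam,
            )
        )
        ids = [f"{cond.label}_{i:03d}" for i in range(cond.n_samples)]
        sample_ids.extend(ids)
        assignments.update({s: cond.label for s in ids})
    expr = ExpressionMatrix(genes, sample_ids, np.hstack(blocks))
    design = GroupDesign(assignments)
    truth = {
        "planted": genes[base.n_background :],
        "background": genes[: base.n_background],
        "conditions": {
            c.label: {"n_samples": c.n_samples, "seed": c.seed, "chain": c.chain}
            for c in conditions
        },
        "phi": base.phi,
    }
    return expr, design, truth
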