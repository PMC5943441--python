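"""Domain containers and TSV/GraphML/DOT input-output.

The pipeline works on three tabular objects: a genes x samples expression
matrix of relative (unitless) expression values, a sample -> group design
table, and a symmetric matrix of absolute pairwise gene correlations with a
zero diagonal.  All files are plain TSV (UTF-8, ``.`` decimal separator, no
quoting); the first header cell of a matrix file may be empty.

Missing or non-numeric cells are hard errors by default: downstream
correlations require a complete common pair ordering, so silent imputation
is never performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataValidationError",
    "ExpressionMatrix",
    "GroupDesign",
    "CorrelationNetwork",
    "EdgeList",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_group_design",
    "write_group_design",
    "read_correlation_matrix_tsv",
    "write_correlation_matrix_tsv",
    "read_edge_tsv",
    "write_network",
]

ASYMMETRY_POLICIES = ("error", "upper", "lower", "mean", "max")


class DataValidationError(ValueError):
    """An input violates a container invariant (duplicate id, missing cell, ...)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DataValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes x samples grid of relative expression values.

    Invariants: unique gene and sample ids, dimensions matching the id
    lists, every value finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataValidationError(
                f"non-finite expression value for gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene_id!r}") from None

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(gene_ids)
        rows = [self.gene_index(g) for g in ids]
        return ExpressionMatrix(ids, list(self.sample_ids), self.values[rows, :])

    def sample_columns(self, sample_ids: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return self.values[:, cols]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class GroupDesign:
    """Mapping sample id -> condition label with a deterministic group order."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        self.assignments = {str(k): str(v) for k, v in self.assignments.items()}
        if not self.assignments:
            raise DataValidationError("empty group design")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def samples_for(self, label: str) -> list[str]:
        """Samples carrying ``label``, in assignment (file) order."""
        out = [s for s, g in self.assignments.items() if g == label]
        if not out:
            raise DataValidationError(f"unknown or empty group label: {label!r}")
        return out

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.assignments.values():
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [s for s in expr.sample_ids if s not in self.assignments]
        if missing:
            raise DataValidationError(f"samples missing from design: {missing[:5]}")
        extra = [s for s in self.assignments if s not in set(expr.sample_ids)]
        if extra:
            raise DataValidationError(f"design samples absent from matrix: {extra[:5]}")
        if len(self.groups) < 2:
            raise DataValidationError("design must contain at least two groups")


@dataclass
class CorrelationNetwork:
    """Symmetric absolute-correlation matrix over selected genes.

    Diagonal is exactly zero (the printed-matrix convention, which also
    keeps self-loops out of the optimizers); off-diagonal weights lie in
    [0, 1].
    """

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        _check_unique(self.gene_ids, "gene")
        n = len(self.gene_ids)
        if n < 2:
            raise DataValidationError("correlation network needs at least 2 genes")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n, n):
            raise DataValidationError(
                f"weight grid shape {self.weights.shape} does not match {n} genes"
            )
        if not np.all(np.isfinite(self.weights)):
            raise DataValidationError("non-finite correlation weight")
        if not np.array_equal(self.weights, self.weights.T):
            raise DataValidationError("correlation matrix is not symmetric")
        if np.any(np.diag(self.weights) != 0.0):
            raise DataValidationError("correlation matrix diagonal must be 0")
        off = self.weights[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < 0.0 or off.max() > 1.0):
            raise DataValidationError("correlation weights must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def weight(self, a: str, b: str) -> float:
        ia = self.gene_ids.index(a)
        ib = self.gene_ids.index(b)
        return float(self.weights[ia, ib])

    def edge_list(self) -> "EdgeList":
        edges = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                a, b = sorted((self.gene_ids[i], self.gene_ids[j]))
                edges.append((a, b, float(self.weights[i, j])))
        edges.sort(key=lambda e: (e[0], e[1]))
        return EdgeList(edges)

    def subset(self, gene_ids: Sequence[str]) -> "CorrelationNetwork":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return CorrelationNetwork(list(gene_ids), self.weights[np.ix_(idx, idx)])


@dataclass
class EdgeList:
    """Undirected weighted edges, canonically ordered (gene_a < gene_b, sorted)."""

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        canon = []
        seen: set[tuple[str, str]] = set()
        for a, b, w in self.edges:
            a, b = str(a), str(b)
            if a == b:
                raise DataValidationError(f"self-loop on {a!r}")
            if a > b:
                a, b = b, a
            if (a, b) in seen:
                raise DataValidationError(f"duplicate edge {a!r}-{b!r}")
            seen.add((a, b))
            w = float(w)
            if not (0.0 <= w <= 1.0):
                raise DataValidationError(f"edge weight out of [0,1]: {a}-{b} {w}")
            canon.append((a, b, w))
        canon.sort(key=lambda e: (e[0], e[1]))
        self.edges = canon

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def nodes(self) -> list[str]:
        ns: set[str] = set()
        for a, b, _ in self.edges:
            ns.add(a)
            ns.add(b)
        return sorted(ns)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise DataValidationError(f"cannot parse TSV {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataValidationError(f"empty table: {path}")
    return df


def _to_float_grid(df: pd.DataFrame, path, require_complete: bool) -> np.ndarray:
    grid = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        bad = converted.isna() & ~raw_na
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise DataValidationError(
                f"non-numeric cell in {path} at gene {gene!r}, column {col!r}"
            )
        if require_complete and raw_na.any():
            gene = df.index[raw_na.to_numpy().nonzero()[0][0]]
            raise DataValidationError(
                f"missing cell in {path} at gene {gene!r}, column {col!r}"
            )
        grid[:, j] = converted.to_numpy(dtype=float)
    return grid


def read_expression_tsv(path, require_complete: bool = True) -> ExpressionMatrix:
    """Read a genes x samples expression TSV (header row of sample ids,
    first column gene ids). Row and column order are preserved."""
    df = _read_table(path)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DataValidationError(f"duplicate gene id: {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise DataValidationError(f"duplicate sample id: {dup!r} in {path}")
    grid = _to_float_grid(df, path, require_complete)
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), grid)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.to_csv(path, sep="\t", index_label="")


def read_group_design(path) -> GroupDesign:
    """Read a two-column TSV ``sample_id<TAB>group_label`` (with header)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise DataValidationError(f"design file {path} needs two columns")
    if df.shape[0] == 0:
        raise DataValidationError(f"empty design file: {path}")
    samples = df.iloc[:, 0].astype(str)
    labels = df.iloc[:, 1].astype(str)
    if samples.duplicated().any():
        dup = samples[samples.duplicated()].iloc[0]
        raise DataValidationError(f"sample listed twice in design: {dup!r}")
    return GroupDesign(dict(zip(samples, labels)))


def write_group_design(design: GroupDesign, path) -> None:
    df = pd.DataFrame(
        {"sample_id": list(design.assignments), "group": list(design.assignments.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def read_correlation_matrix_tsv(path, asymmetry_policy: str = "error") -> CorrelationNetwork:
    """Read a square labeled correlation TSV into a :class:`CorrelationNetwork`.

    ``asymmetry_policy`` resolves disagreeing mirror cells: ``error`` (default)
    rejects them; ``upper``/``lower`` take the corresponding triangle as
    authoritative; ``mean``/``max`` combine the two.  The diagonal is forced
    to 0.  Out-of-range entries are always an error, never clamped.
    """
    if asymmetry_policy not in ASYMMETRY_POLICIES:
        raise ValueError(
            f"unknown asymmetry policy {asymmetry_policy!r}; choose from {ASYMMETRY_POLICIES}"
        )
    df = _read_table(path)
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if len(rows) != len(cols):
        raise DataValidationError(f"correlation matrix in {path} is not square")
    if rows != cols:
        raise DataValidationError(
            f"row/column label mismatch in {path}: rows {rows[:3]}..., cols {cols[:3]}..."
        )
    grid = _to_float_grid(df, path, require_complete=True)
    n = len(rows)
    off = grid[~np.eye(n, dtype=bool)]
    if off.size and (off.min() < 0.0 or off.max() > 1.0):
        raise DataValidationError(f"correlation entry outside [0,1] in {path}")
    sym = grid.copy()
    iu = np.triu_indices(n, k=1)
    upper = grid[iu]
    lower = grid.T[iu]
    if asymmetry_policy == "error":
        if not np.array_equal(upper, lower):
            k = int(np.nonzero(upper != lower)[0][0])
            a, b = rows[iu[0][k]], rows[iu[1][k]]
            raise DataValidationError(
                f"asymmetric cell ({a}, {b}): {upper[k]} vs {lower[k]} "
                f"(use an explicit asymmetry policy to resolve)"
            )
        resolved = upper
    elif asymmetry_policy == "upper":
        resolved = upper
    elif asymmetry_policy == "lower":
        resolved = lower
    elif asymmetry_policy == "mean":
        resolved = (upper + lower) / 2.0
    else:  # max
        resolved = np.maximum(upper, lower)
    sym[iu] = resolved
    sym.T[iu] = resolved
    np.fill_diagonal(sym, 0.0)
    return CorrelationNetwork(rows, sym)


def write_correlation_matrix_tsv(net: CorrelationNetwork, path) -> None:
    df = pd.DataFrame(net.weights, index=net.gene_ids, columns=net.gene_ids)
    df.to_csv(path, sep="\t", index_label="")


def read_edge_tsv(path) -> EdgeList:
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str, 1: str}, float_precision="round_trip")
    if df.shape[1] < 3:
        raise DataValidationError(f"edge TSV {path} needs three columns")
    edges = [
        (str(r.iloc[0]), str(r.iloc[1]), float(r.iloc[2])) for _, r in df.iterrows()
    ]
    return EdgeList(edges)


def _as_edge_list(obj) -> EdgeList:
    if isinstance(obj, EdgeList):
        return obj
    if isinstance(obj, CorrelationNetwork):
        return obj.edge_list()
    edges = getattr(obj, "edges", None)
    if isinstance(edges, EdgeList):
        return edges
    # TourSolution-like: cyclic order plus weights via a .edge_list() method
    fn = getattr(obj, "edge_list", None)
    if callable(fn):
        out = fn()
        if isinstance(out, EdgeList):
            return out
    raise TypeError(f"cannot derive an edge list from {type(obj).__name__}")


def write_network(obj, path, format: str = "edge_tsv") -> None:
    """Serialize a network, tour or tree as an edge-list TSV, GraphML or DOT.

    Edges are emitted in lexicographic order, so repeated runs are
    byte-identical.
    """
    el = _as_edge_list(obj)
    if format == "edge_tsv":
        df = pd.DataFrame(el.edges, columns=["gene_a", "gene_b", "weight"])
        df.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(el.nodes())
        for a, b, w in el.edges:
            g.add_edge(a, b, weight=w)
        nx.write_graphml(g, path)
    elif format == "dot":
        lines = ["graph pathproxy {"]
        for node in el.nodes():
            lines.append(f'  "{node}";')
        for a, b, w in el.edges:
            lines.append(f'  "{a}" -- "{b}" [weight={w!r}, label="{w:.3f}"];')
        lines.append("}")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; choose edge_tsv, graphml or dot")
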