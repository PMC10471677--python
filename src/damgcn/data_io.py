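"""Feature tables, labeled patient graphs and normalized convolution operators.

A domain is an attributed graph: one row of numeric features per patient,
a binary (or small-C categorical) outcome label per patient, and an
undirected similarity graph. When no edge list is given the graph is built
by connecting each patient to its k nearest neighbours in feature space
(default k=6) and symmetrizing by union, so every graph is undirected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger("damgcn")

DEFAULT_K = 6  # KNN edges per node


class InputFormatError(ValueError):
    """A data file failed to parse; the message names the offending cell."""


@dataclass
class FeatureTable:
    """N x d real-valued node feature matrix with ordered node identifiers."""

    values: np.ndarray
    node_ids: list[str] = field(default_factory=list)
    columns: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("feature table must be 2-D with at least one column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite entries")
        if not self.node_ids:
            self.node_ids = [str(i) for i in range(self.values.shape[0])]
        if len(self.node_ids) != self.values.shape[0]:
            raise ValueError("node_ids length does not match number of rows")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class LabeledGraph:
    """One domain: symmetric zero-diagonal adjacency, features X, labels Y."""

    adjacency: np.ndarray
    features: FeatureTable
    labels: np.ndarray
    domain_tag: str = "source"

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.intp)
        n = self.features.n_nodes
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match feature rows")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(self.adjacency < 0):
            raise ValueError("adjacency must be non-negative")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero (self-loops are added at normalization)")
        if self.labels.shape != (n,):
            raise ValueError("labels length must equal the number of nodes")
        if self.domain_tag not in ("source", "target"):
            raise ValueError("domain_tag must be 'source' or 'target'")

    @property
    def n_nodes(self) -> int:
        return self.features.n_nodes

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class NormalizedOperator:
    """Dense N x N propagation operator ready for graph convolution."""

    matrix: np.ndarray
    flavor: str  # "adjacency" | "ppmi"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("operator contains non-finite entries")
        if self.flavor not in ("adjacency", "ppmi"):
            raise ValueError("flavor must be 'adjacency' or 'ppmi'")


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def load_feature_table(path: str | Path, delimiter: str = ",") -> FeatureTable:
    """Load a delimited numeric table, one node per row.

    A non-numeric first row is treated as a column header; a fully
    non-numeric first column supplies node identifiers. Any other
    non-numeric cell raises :class:`InputFormatError` naming its
    0-based row and column in the data block.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep=delimiter, header=None, dtype=str,
                          skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise InputFormatError(f"{path}: empty input file") from None
    if raw.empty:
        raise InputFormatError(f"{path}: empty input file")
    raw = raw.map(lambda s: s.strip() if isinstance(s, str) else s)

    columns: list[str] | None = None
    first_row = raw.iloc[0]
    if first_row.map(_is_number).sum() < len(first_row):
        columns = [str(c) for c in first_row.tolist()]
        raw = raw.iloc[1:].reset_index(drop=True)
        if raw.empty:
            raise InputFormatError(f"{path}: header but no data rows")

    node_ids: list[str] = []
    first_col = raw.iloc[:, 0]
    if (columns is not None and columns[0] == "node_id") \
            or not first_col.map(_is_number).any():
        node_ids = [str(v) for v in first_col.tolist()]
        raw = raw.iloc[:, 1:]
        if columns is not None:
            columns = columns[1:]
        if raw.shape[1] == 0:
            raise InputFormatError(f"{path}: no numeric feature columns")

    values = np.empty(raw.shape, dtype=np.float64)
    for j in range(raw.shape[1]):
        col = raw.iloc[:, j].to_numpy()
        try:
            # numpy's parser is correctly rounded (unlike pandas' fast path)
            values[:, j] = col.astype(np.float64)
        except (ValueError, TypeError):
            bad = [i for i, s in enumerate(col) if not _is_number(s)]
            i = bad[0] if bad else 0
            raise InputFormatError(
                f"{path}: cell at row {i}, column {j} "
                f"({col[i]!r}) is not numeric") from None
    return FeatureTable(values=values, node_ids=node_ids, columns=columns)


def save_feature_table(table: FeatureTable, path: str | Path,
                       delimiter: str = ",") -> None:
    df = pd.DataFrame(table.values,
                      columns=table.columns or
                      [f"f{j}" for j in range(table.n_features)])
    df.insert(0, "node_id", table.node_ids)
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def load_labels(path: str | Path, delimiter: str = ",") -> np.ndarray:
    """Single-column integer class labels aligned to feature rows."""
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter, header=None, dtype=str,
                      skip_blank_lines=True)
    col = raw.iloc[:, 0].map(lambda s: s.strip() if isinstance(s, str) else s)
    if not _is_number(col.iloc[0]):  # optional header line
        col = col.iloc[1:]
    vals = pd.to_numeric(col, errors="coerce")
    bad = np.where(vals.isna().to_numpy())[0]
    if bad.size:
        raise InputFormatError(f"{path}: label at row {int(bad[0])} is not numeric")
    return vals.to_numpy().astype(np.intp)


def save_labels(labels: Sequence[int], path: str | Path) -> None:
    np.savetxt(path, np.asarray(labels, dtype=int), fmt="%d")


def load_edge_list(path: str | Path, n_nodes: int,
                   delimiter: str | None = None) -> np.ndarray:
    """Two-column 0-based undirected edge list -> binary symmetric adjacency."""
    edges = np.loadtxt(path, dtype=np.intp, delimiter=delimiter, ndmin=2)
    if edges.size == 0:
        return np.zeros((n_nodes, n_nodes))
    if edges.shape[1] != 2:
        raise InputFormatError(f"{path}: edge list must have exactly two columns")
    if edges.min() < 0 or edges.max() >= n_nodes:
        raise InputFormatError(f"{path}: edge endpoint out of range [0, {n_nodes})")
    adj = np.zeros((n_nodes, n_nodes))
    adj[edges[:, 0], edges[:, 1]] = 1.0
    adj[edges[:, 1], edges[:, 0]] = 1.0
    np.fill_diagonal(adj, 0.0)
    return adj


def save_edge_list(adjacency: np.ndarray, path: str | Path,
                   delimiter: str = "\t") -> None:
    iu, ju = np.nonzero(np.triu(adjacency, k=1))
    np.savetxt(path, np.column_stack([iu, ju]), fmt="%d", delimiter=delimiter)


def _is_number(s: object) -> bool:
    try:
        float(s)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# graph construction and normalization
# ---------------------------------------------------------------------------

def build_knn_graph(features: FeatureTable, k: int = DEFAULT_K,
                    metric: str = "euclidean",
                    standardize: bool = False) -> np.ndarray:
    """Binary union-symmetrized k-nearest-neighbour adjacency.

    Each node is linked to its k nearest neighbours (self excluded) and an
    undirected edge is kept if either endpoint selected the other. Distance
    ties are broken by lower node index (stable argsort), so the graph is
    a deterministic function of the features.
    """
    n = features.n_nodes
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of nodes ({n})")
    if k < 1:
        raise ValueError("k must be a positive integer")
    x = features.values
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    dist = cdist(x, x, metric=metric)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")
    neighbours = order[:, :k]
    adj = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    adj[rows, neighbours.ravel()] = 1.0
    adj = np.maximum(adj, adj.T)  # union symmetrization
    np.fill_diagonal(adj, 0.0)
    return adj


def normalize_adjacency(adjacency: np.ndarray) -> NormalizedOperator:
    """Symmetric GCN normalization D̃^{-1/2} (A + I) D̃^{-1/2}."""
    a = np.asarray(adjacency, dtype=np.float64)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(a < 0):
        raise ValueError("adjacency must be non-negative")
    a_tilde = a + np.eye(a.shape[0])
    d = a_tilde.sum(axis=1)  # > 0 thanks to the self-loop
    d_inv_sqrt = 1.0 / np.sqrt(d)
    mat = a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return NormalizedOperator(matrix=mat, flavor="adjacency")
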