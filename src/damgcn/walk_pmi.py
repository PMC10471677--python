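"""Random-walk PPMI operator for the global-consistency channel.

The local channel propagates features over the immediate adjacency; the
global channel instead uses a node-context similarity matrix harvested
from simple random walks. Walks are treated like sentences and nodes like
words: co-occurrences within a sliding window give a frequency matrix F,
whose positive pointwise mutual information

    PPMI_ij = max(log(p_ij / (p_i. p_.j)), 0)

keeps only node/context pairs that co-occur more often than independence
would predict. Symmetric degree normalization of the PPMI matrix then
yields a diffusion operator with the same shape contract as the
normalized adjacency, so the two channels share one convolution code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import NormalizedOperator

logger = logging.getLogger("damgcn")

__all__ = [
    "WalkConfig",
    "FrequencyMatrix",
    "PPMIMatrix",
    "transition_matrix",
    "sample_walks",
    "build_frequency_matrix",
    "compute_ppmi",
    "normalize_ppmi",
    "ppmi_operator",
]


@dataclass(frozen=True)
class WalkConfig:
    """Sampling hyperparameters for the walk corpus.

    Defaults are conventional skip-gram-scale values: 10 walks per node of
    40 steps each, with a co-occurrence window of 5.
    """

    walks_per_node: int = 10
    walk_length: int = 40
    window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walks_per_node < 1 or self.walk_length < 1 or self.window < 1:
            raise ValueError("walks_per_node, walk_length and window must be positive")
        if self.window > self.walk_length:
            raise ValueError("window must not exceed walk_length")


@dataclass
class FrequencyMatrix:
    """F_ij = number of times node i appears with context node j in a window."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("frequency matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("frequency counts must be non-negative")


@dataclass
class PPMIMatrix:
    """Positive-PMI matrix P with its degree vector D_ii = sum_j P_ij."""

    matrix: np.ndarray
    degree: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.degree = np.asarray(self.degree, dtype=np.float64)
        if np.any(self.matrix < 0) or not np.all(np.isfinite(self.matrix)):
            raise ValueError("PPMI matrix must be non-negative and finite")


def transition_matrix(adjacency: np.ndarray) -> np.ndarray:
    """Row-normalize the adjacency into one-step transition probabilities.

    Rows of isolated nodes are left all-zero; such nodes are excluded from
    walk starts and a warning is logged.
    """
    a = np.asarray(adjacency, dtype=np.float64)
    deg = a.sum(axis=1)
    isolated = deg == 0
    if isolated.any():
        logger.warning("%d isolated node(s) excluded from random walks",
                       int(isolated.sum()))
    t = np.zeros_like(a)
    nz = ~isolated
    t[nz] = a[nz] / deg[nz, None]
    return t


def sample_walks(adjacency: np.ndarray, cfg: WalkConfig) -> list[np.ndarray]:
    """Sample ``walks_per_node`` walks of ``walk_length`` steps per node.

    Each walk is an index sequence of ``walk_length + 1`` nodes starting at
    a non-isolated node; successors are drawn from the transition matrix.
    Fully reproducible from ``cfg.seed``.
    """
    t = transition_matrix(adjacency)
    starts = np.where(t.sum(axis=1) > 0)[0]
    if starts.size == 0:
        logger.warning("graph has no edges; returning an empty walk corpus")
        return []
    rng = np.random.default_rng(cfg.seed)
    cur = np.repeat(starts, cfg.walks_per_node)
    cum = np.cumsum(t, axis=1)
    path = np.empty((cur.size, cfg.walk_length + 1), dtype=np.intp)
    path[:, 0] = cur
    for step in range(1, cfg.walk_length + 1):
        u = rng.random(cur.size)
        # vectorized inverse-CDF draw from each current node's row
        cur = (u[:, None] < cum[cur]).argmax(axis=1)
        path[:, step] = cur
    return [path[i] for i in range(path.shape[0])]


def build_frequency_matrix(walks: list[np.ndarray], window: int,
                           n_nodes: int) -> FrequencyMatrix:
    """Count ordered (center, context) pairs within ``window`` positions."""
    counts = np.zeros((n_nodes, n_nodes))
    for walk in walks:
        w = np.asarray(walk, dtype=np.intp)
        if w.size and w.max() >= n_nodes:
            raise ValueError("walk contains a node index >= n_nodes")
        for off in range(1, window + 1):
            if off >= w.size:
                break
            a, b = w[:-off], w[off:]
            np.add.at(counts, (a, b), 1.0)
            np.add.at(counts, (b, a), 1.0)
    return FrequencyMatrix(counts=counts)


def compute_ppmi(freq: FrequencyMatrix) -> PPMIMatrix:
    """Positive pointwise mutual information of the co-occurrence counts.

    Joint p_ij = F_ij / sum(F); marginals p_i. and p_.j are the row and
    column sums of the joint. Entries with zero counts stay exactly zero,
    as do pairs whose joint matches the product of their marginals.
    """
    f = freq.counts
    tot = f.sum()
    if tot <= 0:
        raise ValueError("frequency matrix is all-zero; a non-empty walk corpus is required")
    joint = f / tot
    row = joint.sum(axis=1)
    col = joint.sum(axis=0)
    denom = row[:, None] * col[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(np.where(denom > 0, joint / np.where(denom > 0, denom, 1.0), 0.0))
    pmi[joint == 0] = -np.inf  # never co-occurred -> floored to 0 below
    p = np.maximum(pmi, 0.0)
    p[~np.isfinite(p)] = 0.0
    # PMI below 1e-12 nats is numerically indistinguishable from exact
    # independence (rounding residue of joint == product-of-marginals)
    p[p < 1e-12] = 0.0
    return PPMIMatrix(matrix=p, degree=p.sum(axis=1))


def normalize_ppmi(ppmi: PPMIMatrix) -> NormalizedOperator:
    """Symmetric degree normalization D^{-1/2} P D^{-1/2}.

    Rows/columns with zero PPMI degree (isolated nodes) are left zero; those
    nodes rely on the local adjacency channel alone.
    """
    p = ppmi.matrix
    d = p.sum(axis=1)
    inv = np.zeros_like(d)
    nz = d > 0
    inv[nz] = 1.0 / np.sqrt(d[nz])
    mat = p * inv[:, None] * inv[None, :]
    return NormalizedOperator(matrix=mat, flavor="ppmi")


def ppmi_operator(adjacency: np.ndarray, cfg: WalkConfig) -> NormalizedOperator:
    """Full pipeline: walks -> frequency matrix -> PPMI -> normalized operator."""
    walks = sample_walks(adjacency, cfg)
    if not walks:
        n = adjacency.shape[0]
        return NormalizedOperator(matrix=np.zeros((n, n)), flavor="ppmi")
    freq = build_frequency_matrix(walks, cfg.window, adjacency.shape[0])
    return normalize_ppmi(compute_ppmi(freq))
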