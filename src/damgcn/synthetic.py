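"""Synthetic paired-domain generator for end-to-end testing and demos.

The generator emulates the statistical shape of small clinical patient
cohorts: two domains that share label semantics (the same class-conditional
geometry) but differ in marginal feature distribution. Features are
class-conditional Gaussians in d dimensions (default d=25, two classes,
imbalanced positives); the target domain applies a rigid rotation plus a
mean translation — both scaled by a single ``shift`` knob — to the whole
cloud, producing covariate shift that degrades a source-only classifier
while leaving the classes themselves intact. KNN graphs (default k=6) are
built from the shifted features so synthetic data flows through exactly
the same pipeline as real delimited-text cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import FeatureTable, LabeledGraph, build_knn_graph
from .walk_pmi import FrequencyMatrix, PPMIMatrix, compute_ppmi, normalize_ppmi
from .data_io import normalize_adjacency

__all__ = ["SyntheticSpec", "generate_domain_pair", "worked_micro_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_source: int = 300
    n_target: int = 300
    d: int = 25
    n_classes: int = 2
    class_sep: float = 3.0
    shift: float = 1.0
    imbalance: float = 0.15  # positive-class fraction
    noise_sd: float = 1.0
    k: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ValueError("the generator currently produces binary outcomes")
        for n in (self.n_source, self.n_target):
            if n < 2 * self.k + 2:
                raise ValueError("need n >= 2k + 2 for a well-posed KNN graph")
            if self.imbalance * n < 2:
                raise ValueError("imbalance too extreme: fewer than 2 positives")
        if not 0.0 < self.imbalance < 1.0:
            raise ValueError("imbalance must lie in (0, 1)")
        if self.noise_sd <= 0 or self.class_sep < 0 or self.shift < 0:
            raise ValueError("noise_sd must be > 0; class_sep, shift must be >= 0")


def generate_domain_pair(spec: SyntheticSpec) -> tuple[LabeledGraph, LabeledGraph]:
    """Draw one source/target pair of labeled KNN patient graphs.

    Both domains share centroid geometry (class 1 sits ``class_sep`` away
    from class 0 along a seed-fixed unit direction); the target cloud is
    rotated by Givens angles of 0.15*shift radians on successive coordinate
    pairs and translated by a vector of norm ``shift``. ``shift=0`` makes
    the two domains draws from the identical distribution.
    """
    rng = np.random.default_rng(spec.seed)
    sep_dir = _unit(rng.standard_normal(spec.d))
    centroids = np.stack([np.zeros(spec.d), spec.class_sep * sep_dir])
    offset_dir = _unit(rng.standard_normal(spec.d))
    rot = _givens_rotation(spec.d, 0.15 * spec.shift)

    graphs = []
    for n, tag in ((spec.n_source, "source"), (spec.n_target, "target")):
        labels = np.zeros(n, dtype=np.intp)
        labels[: max(2, round(spec.imbalance * n))] = 1
        rng.shuffle(labels)
        x = centroids[labels] + spec.noise_sd * rng.standard_normal((n, spec.d))
        if tag == "target":
            x = x @ rot.T + spec.shift * offset_dir
        feats = FeatureTable(values=x)
        adj = build_knn_graph(feats, k=spec.k)
        graphs.append(LabeledGraph(adjacency=adj, features=feats,
                                   labels=labels, domain_tag=tag))
    return graphs[0], graphs[1]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _givens_rotation(d: int, angle: float) -> np.ndarray:
    """Block-diagonal rotation by ``angle`` on dims (0,1), (2,3), ..."""
    rot = np.eye(d)
    c, s = np.cos(angle), np.sin(angle)
    for i in range(0, d - 1, 2):
        rot[i, i] = c
        rot[i + 1, i + 1] = c
        rot[i, i + 1] = -s
        rot[i + 1, i] = s
    return rot


def worked_micro_fixture() -> dict:
    """A deterministic 6-node instance with hand-checked intermediates.

    Two triangles (0-1-2 and 3-4-5) joined by the bridge 2-3, two features
    per node, a fixed 4-walk corpus with window 2, and the frequency and
    PPMI matrices enumerated from that corpus by hand. Used in unit tests
    and documentation examples.
    """
    adjacency = np.zeros((6, 6))
    for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]:
        adjacency[i, j] = adjacency[j, i] = 1.0
    features = FeatureTable(values=np.array(
        [[0.0, 0.0], [0.1, 0.0], [0.0, 0.1],
         [1.0, 1.0], [1.1, 1.0], [1.0, 1.1]]))
    labels = np.array([0, 0, 0, 1, 1, 1], dtype=np.intp)
    walks = [np.array(w, dtype=np.intp) for w in
             ([0, 1, 2, 3], [3, 4, 5, 3], [2, 0, 1, 0], [5, 4, 3, 2])]
    window = 2
    # ordered (center, context) counts over the four walks, window 2,
    # enumerated by hand; symmetric because both directions are counted
    freq = FrequencyMatrix(counts=_MICRO_F.copy())
    ppmi = PPMIMatrix(matrix=_MICRO_P.copy(), degree=_MICRO_P.sum(axis=1))
    graph = LabeledGraph(adjacency=adjacency, features=features, labels=labels)
    return {
        "graph": graph,
        "walks": walks,
        "window": window,
        "F": freq,
        "P": ppmi,
        "op_A": normalize_adjacency(adjacency),
        "op_P": normalize_ppmi(ppmi),
    }


# Literals for the micro fixture, enumerated from the walk corpus above
# (all ordered in-window pairs) and pushed through the PPMI definition;
# kept at full double precision.
_MICRO_F = np.array([
    [2.0, 3.0, 2.0, 0.0, 0.0, 0.0],
    [3.0, 0.0, 2.0, 1.0, 0.0, 0.0],
    [2.0, 2.0, 0.0, 2.0, 1.0, 0.0],
    [0.0, 1.0, 2.0, 0.0, 3.0, 3.0],
    [0.0, 0.0, 1.0, 3.0, 0.0, 2.0],
    [0.0, 0.0, 0.0, 3.0, 2.0, 0.0],
])

_MICRO_P = np.array([
    [0.4902063365632552, 1.0498221244986776, 0.490206336563255, 0.0, 0.0, 0.0],
    [1.0498221244986776, 0.0, 0.6443570163905132, 0.0, 0.0, 0.0],
    [0.490206336563255, 0.6443570163905132, 0.0, 0.23889190828234888, 0.0, 0.0],
    [0.0, 0.0, 0.23889190828234888, 0.0, 0.7985076962177713, 0.980829253011726],
    [0.0, 0.0, 0.0, 0.7985076962177713, 0.0, 0.9808292530117262],
    [0.0, 0.0, 0.0, 0.980829253011726, 0.9808292530117262, 0.0],
])
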