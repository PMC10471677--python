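import numpy as np
import pytest

from damgcn import (
    FrequencyMatrix,
    WalkConfig,
    build_frequency_matrix,
    compute_ppmi,
    normalize_ppmi,
    ppmi_operator,
    sample_walks,
    transition_matrix,
)


def enumerate_pairs(walks, window, n):
    """Brute-force ordered in-window pair counts (independent oracle)."""
    f = np.zeros((n, n))
    for w in walks:
        for i in range(len(w)):
            for j in range(len(w)):
                if i != j and abs(i - j) <= window:
                    f[w[i], w[j]] += 1
    return f


def ppmi_oracle(f):
    """Direct evaluation of the joint/marginal/log-ratio definition."""
    joint = f / f.sum()
    row, col = joint.sum(1), joint.sum(0)
    out = np.zeros_like(joint)
    for i in range(f.shape[0]):
        for j in range(f.shape[1]):
            if joint[i, j] > 0:
                out[i, j] = max(np.log(joint[i, j] / (row[i] * col[j])), 0.0)
    return out


class TestTransitionMatrix:
    def test_two_nodes_one_edge(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.array_equal(transition_matrix(a), [[0, 1], [1, 0]])

    def test_rows_sum_to_one(self, rng):
        a = (rng.random((25, 25)) < 0.3).astype(float)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
        t = transition_matrix(a)
        connected = a.sum(1) > 0
        assert np.allclose(t[connected].sum(1), 1.0)

    def test_path_graph_middle_row(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1.0
        assert np.allclose(transition_matrix(a)[1], [0.5, 0.0, 0.5])

    def test_isolated_node_row_zero(self, caplog):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0
        t = transition_matrix(a)
        assert np.all(t[2] == 0)


class TestSampleWalks:
    def test_two_node_walks_alternate(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        walks = sample_walks(a, WalkConfig(walks_per_node=2, walk_length=5,
                                           window=2, seed=1))
        assert len(walks) == 4
        for w in walks:
            assert len(w) == 6
            assert np.all(np.abs(np.diff(w)) == 1)  # strict alternation

    def test_seeded_reproducibility(self):
        a = np.zeros((5, 5))
        for i in range(4):
            a[i, i + 1] = a[i + 1, i] = 1.0
        cfg = WalkConfig(walks_per_node=3, walk_length=10, window=2, seed=42)
        w1, w2 = sample_walks(a, cfg), sample_walks(a, cfg)
        assert all(np.array_equal(x, y) for x, y in zip(w1, w2))

    def test_edgeless_graph_gives_empty_corpus(self):
        assert sample_walks(np.zeros((4, 4)), WalkConfig(seed=0)) == []

    def test_empirical_step_frequencies_match_transition_rows(self):
        # weighted 4-node graph; compare Monte-Carlo next-node frequencies
        # against the exact transition probabilities within 3 standard errors
        a = np.array([[0, 2, 1, 0], [2, 0, 0, 1], [1, 0, 0, 3], [0, 1, 3, 0]],
                     dtype=float)
        t = transition_matrix(a)
        walks = sample_walks(a, WalkConfig(walks_per_node=80, walk_length=40,
                                           window=2, seed=5))
        trans_counts = np.zeros((4, 4))
        for w in walks:
            np.add.at(trans_counts, (w[:-1], w[1:]), 1.0)
        for i in range(4):
            n_i = trans_counts[i].sum()
            assert n_i > 1000
            for j in range(4):
                p = t[i, j]
                se = np.sqrt(max(p * (1 - p), 1e-12) / n_i)
                assert abs(trans_counts[i, j] / n_i - p) <= 3 * se + 1e-9


class TestFrequencyMatrix:
    def test_single_pair_walk(self):
        f = build_frequency_matrix([np.array([0, 1])], window=1, n_nodes=2)
        assert np.array_equal(f.counts, [[0, 1], [1, 0]])

    def test_empty_corpus_all_zero(self):
        assert np.all(build_frequency_matrix([], window=2, n_nodes=3).counts == 0)

    def test_three_node_walk_window_two_vs_enumeration(self):
        walks = [np.array([0, 1, 2])]
        f = build_frequency_matrix(walks, window=2, n_nodes=3)
        assert np.array_equal(f.counts, enumerate_pairs(walks, 2, 3))

    def test_random_walks_vs_enumeration(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 10))
            walks = [rng.integers(0, n, size=rng.integers(2, 12))
                     for _ in range(5)]
            w = int(rng.integers(1, 4))
            f = build_frequency_matrix(walks, window=w, n_nodes=n)
            assert np.array_equal(f.counts, enumerate_pairs(walks, w, n))

    def test_out_of_range_index_errors(self):
        with pytest.raises(ValueError, match="n_nodes"):
            build_frequency_matrix([np.array([0, 5])], window=1, n_nodes=3)


class TestPPMI:
    def test_uniform_counts_are_independent(self):
        p = compute_ppmi(FrequencyMatrix(counts=np.ones((2, 2))))
        assert np.all(p.matrix == 0)

    def test_outer_product_counts_give_exact_zero(self, rng):
        # joint = product of marginals for any rank-one count matrix
        u = rng.integers(1, 10, size=6).astype(float)
        v = rng.integers(1, 10, size=6).astype(float)
        p = compute_ppmi(FrequencyMatrix(counts=np.outer(u, v)))
        assert np.all(p.matrix == 0.0)

    def test_diagonal_counts_give_log_two(self):
        p = compute_ppmi(FrequencyMatrix(counts=np.array([[2.0, 0.0], [0.0, 2.0]])))
        assert np.allclose(np.diag(p.matrix), np.log(2.0))
        assert p.matrix[0, 1] == 0 and p.matrix[1, 0] == 0

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError, match="non-empty walk corpus"):
            compute_ppmi(FrequencyMatrix(counts=np.zeros((3, 3))))

    def test_nonnegative_and_zero_where_f_zero(self, rng):
        for _ in range(20):
            f = rng.integers(0, 5, size=(8, 8)).astype(float)
            if f.sum() == 0:
                continue
            p = compute_ppmi(FrequencyMatrix(counts=f))
            assert np.all(p.matrix >= 0)
            assert np.all(p.matrix[f == 0] == 0)
            assert np.allclose(p.matrix, ppmi_oracle(f), atol=1e-12)

    def test_bit_reproducible(self, rng):
        f = rng.integers(0, 6, size=(10, 10)).astype(float)
        f[0, 0] += 1
        p1 = compute_ppmi(FrequencyMatrix(counts=f.copy()))
        p2 = compute_ppmi(FrequencyMatrix(counts=f.copy()))
        assert np.array_equal(p1.matrix, p2.matrix)

    def test_symmetric_corpus_gives_symmetric_f_and_p(self, rng):
        walks = [rng.integers(0, 6, size=8) for _ in range(6)]
        walks = walks + [w[::-1] for w in walks]  # add every reversal
        f = build_frequency_matrix(walks, window=3, n_nodes=6)
        assert np.array_equal(f.counts, f.counts.T)
        p = compute_ppmi(f)
        assert np.allclose(p.matrix, p.matrix.T, atol=1e-12)


class TestNormalizePPMI:
    def test_identity_ppmi_maps_to_identity(self):
        from damgcn import PPMIMatrix
        p = PPMIMatrix(matrix=np.eye(3), degree=np.ones(3))
        assert np.array_equal(normalize_ppmi(p).matrix, np.eye(3))

    def test_two_node_swap_matrix(self):
        from damgcn import PPMIMatrix
        p = PPMIMatrix(matrix=np.array([[0.0, 2.0], [2.0, 0.0]]),
                       degree=np.array([2.0, 2.0]))
        out = normalize_ppmi(p).matrix
        assert np.allclose(out, [[0, 1], [1, 0]])

    def test_matches_dense_formula_random(self, rng):
        from damgcn import PPMIMatrix
        for _ in range(20):
            n = int(rng.integers(2, 50))
            m = rng.random((n, n)) * (rng.random((n, n)) < 0.4)
            p = PPMIMatrix(matrix=m, degree=m.sum(1))
            d = m.sum(1)
            inv = np.where(d > 0, 1 / np.sqrt(np.where(d > 0, d, 1)), 0.0)
            assert np.allclose(normalize_ppmi(p).matrix,
                               m * inv[:, None] * inv[None, :], atol=1e-12)

    def test_zero_row_stays_zero(self):
        from damgcn import PPMIMatrix
        m = np.array([[0.0, 0.0], [0.0, 3.0]])
        out = normalize_ppmi(PPMIMatrix(matrix=m, degree=m.sum(1))).matrix
        assert np.all(out[0] == 0) and np.all(out[:, 0] == 0)


def test_two_block_graph_ppmi_separates_communities():
    """Walk co-occurrence is denser within communities than across the
    bridge, so mean within-block PPMI should exceed mean between-block."""
    n = 12
    a = np.zeros((n, n))
    for block in (range(0, 6), range(6, 12)):
        for i in block:
            for j in block:
                if i < j:
                    a[i, j] = a[j, i] = 1.0
    a[5, 6] = a[6, 5] = 1.0  # sparse bridge
    op = ppmi_operator(a, WalkConfig(walks_per_node=20, walk_length=20,
                                     window=3, seed=11))
    p = op.matrix
    within = np.concatenate([p[:6, :6][~np.eye(6, dtype=bool)],
                             p[6:, 6:][~np.eye(6, dtype=bool)]])
    between = p[:6, 6:].ravel()
    assert within.mean() > between.mean()
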