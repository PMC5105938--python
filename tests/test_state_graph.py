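"""Quantization, block labeling, transition estimation, Laplacian projection."""

import warnings

import networkx as nx
import numpy as np
import pytest

from osaprog.models import train_partition
from osaprog.state_graph import (APNEIC, NON_APNEIC, BlockGraph,
                                 build_block_graph, estimate_transitions,
                                 label_blocks, laplacian_project, quantize)
from osaprog.synthetic_data import generate_markov_fixture, simulate_chain


class TestQuantize:
    def test_boundary_is_left_closed_into_upper_bin(self):
        # 0.5 sits exactly on the bin edge and belongs to the upper bin
        states = np.array([[0.0], [0.5], [1.0]])
        block_ids, assignment, _ = quantize(states, bins_per_dim=2)
        cells = [block_ids[b] for b in assignment]
        assert cells == [(0,), (1,), (1,)]

    def test_identical_states_single_block(self):
        with pytest.warns(UserWarning):
            block_ids, assignment, _ = quantize(np.ones((5, 3)), 20)
        assert len(block_ids) == 1
        assert np.all(assignment == 0)

    def test_matches_floor_oracle(self, rng):
        X = rng.uniform(-3, 5, size=(1000, 3))
        block_ids, assignment, q = quantize(X, bins_per_dim=20)
        mins, maxs = X.min(0), X.max(0)
        width = (maxs - mins) / 20
        expected = np.clip(np.floor((X - mins) / width).astype(int), 0, 19)
        got = np.array([block_ids[b] for b in assignment])
        np.testing.assert_array_equal(got, expected)

    def test_cell_centers_within_half_bin_of_states(self, rng):
        X = rng.normal(size=(200, 4))
        block_ids, assignment, q = quantize(X, bins_per_dim=20)
        half = q.widths / 2 + 1e-12
        for i, b in enumerate(assignment):
            center = q.cell_center(block_ids[b])
            assert np.all(np.abs(X[i] - center) <= half)


class TestLabelBlocks:
    def test_partition_labels_match_blob_identity(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (100, 2)),
                       rng.normal(8, 0.5, (100, 2))])
        y = np.array([False] * 100 + [True] * 100)
        part = train_partition(X, y)
        block_ids, assignment, _ = quantize(X, bins_per_dim=10)
        labels, centroids = label_blocks(block_ids, assignment, X, partition=part)
        for b, lab in enumerate(labels):
            members = assignment == b
            expected = APNEIC if y[members].mean() > 0.5 else NON_APNEIC
            assert lab == expected

    def test_majority_tie_breaks_to_non_apneic(self):
        states = np.zeros((2, 1))
        with pytest.warns(UserWarning), warnings.catch_warnings():
            warnings.simplefilter("always")
            labels, _ = label_blocks([(0,)], np.array([0, 0]), states,
                                     state_labels=["apnea", "non_apnea"],
                                     mode="majority")
        assert labels == [NON_APNEIC]


class TestEstimateTransitions:
    def test_deterministic_cycle_recovers_permutation_matrix(self):
        seq = np.tile([0, 1, 2], 100)
        P = estimate_transitions(3, seq, smoothing=0.0)
        expected = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        np.testing.assert_allclose(P, expected)

    def test_rows_sum_to_one(self, rng):
        seq = rng.integers(0, 5, size=500)
        P = estimate_transitions(5, seq)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_known_chain_recovered_within_sampling_error(self):
        # balanced chain: every row is visited ~2500 times in 10k steps
        P_true = np.array([[0.5, 0.2, 0.2, 0.1],
                           [0.1, 0.6, 0.1, 0.2],
                           [0.3, 0.1, 0.4, 0.2],
                           [0.25, 0.25, 0.25, 0.25]])
        graph = BlockGraph([(i,) for i in range(4)], [NON_APNEIC] * 4, P_true)
        seq = simulate_chain(graph, 0, 10_000, np.random.default_rng(4))
        P_hat = estimate_transitions(4, seq, smoothing=0.0)
        assert np.max(np.abs(P_hat - P_true)) < 0.02

    def test_timestamp_gaps_not_counted(self):
        seq = np.array([0, 1, 0, 1])
        ts = np.array([0, 1, 5, 6])  # the 1→0 jump spans a gap
        with pytest.warns(UserWarning):
            P = estimate_transitions(2, seq, timestamps=ts, smoothing=0.0)
        assert P[0, 1] == 1.0
        # block 1 never has a consecutive successor: self-loop fallback
        assert P[1, 1] == 1.0


class TestLaplacianProjection:
    @staticmethod
    def _triangle_pair_graph():
        P = np.zeros((6, 6))
        for a, b, c in [(0, 1, 2), (3, 4, 5)]:
            P[a, b] = P[b, c] = P[c, a] = 1.0
        return BlockGraph([(i,) for i in range(6)], [NON_APNEIC] * 6, P)

    def test_disconnected_components_constant_coordinates(self):
        g = self._triangle_pair_graph()
        with pytest.warns(UserWarning):
            proj = laplacian_project(g, n_coords=3)
        assert np.sum(proj.eigenvalues < 1e-9) == 2
        v2 = proj.coordinates[:, 0]
        assert np.ptp(v2[:3]) < 1e-9 and np.ptp(v2[3:]) < 1e-9
        assert abs(v2[0] - v2[3]) > 1e-6

    def test_path_graph_fiedler_vector_monotone(self):
        P = np.zeros((6, 6))
        for i in range(5):
            P[i, i + 1] += 0.5
            P[i + 1, i] += 0.5
        P[0, 0] = P[5, 5] = 0.5
        g = BlockGraph([(i,) for i in range(6)], [NON_APNEIC] * 6, P)
        v2 = laplacian_project(g, n_coords=1).coordinates[:, 0]
        diffs = np.diff(v2)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        g = generate_markov_fixture(30, 5, seed=13)
        proj = laplacian_project(g, n_coords=3)
        W = (g.P + g.P.T) / 2
        G = nx.from_numpy_array(W)
        L = nx.normalized_laplacian_matrix(G).toarray()
        vals, vecs = np.linalg.eigh((L + L.T) / 2)
        np.testing.assert_allclose(proj.eigenvalues[:5], vals[:5], atol=1e-8)
        for k in range(3):
            ours = proj.coordinates[:, k]
            ref = vecs[:, k + 1]
            assert (np.linalg.norm(ours - ref) < 1e-8
                    or np.linalg.norm(ours + ref) < 1e-8)

    def test_connected_blocks_projected_nearby(self):
        """Two planted communities end up separated along V2."""
        P = np.full((8, 8), 0.02)
        for grp in (range(4), range(4, 8)):
            for i in grp:
                for j in grp:
                    P[i, j] = 0.23
        P /= P.sum(axis=1, keepdims=True)
        g = BlockGraph([(i,) for i in range(8)], [NON_APNEIC] * 8, P)
        coords = laplacian_project(g, n_coords=2).coordinates
        within = np.mean([np.linalg.norm(coords[i] - coords[j])
                          for i in range(4) for j in range(4) if i != j])
        across = np.mean([np.linalg.norm(coords[i] - coords[j])
                          for i in range(4) for j in range(4, 8)])
        assert within < across


def test_block_graph_json_round_trip():
    g = generate_markov_fixture(5, 2, seed=3)
    back = BlockGraph.from_json(g.to_json())
    np.testing.assert_allclose(back.P, g.P)
    assert back.labels == g.labels
    assert back.block_ids == g.block_ids


def test_build_block_graph_end_to_end(rng):
    X = np.vstack([rng.normal(0, 0.5, (60, 2)), rng.normal(5, 0.5, (60, 2))])
    order = rng.permutation(120)
    X = X[order]
    labels = ["apnea" if x[0] > 2.5 else "non_apnea" for x in X]
    part = train_partition(X, labels)
    g = build_block_graph(X, np.arange(120), partition=part,
                          state_labels=labels, bins_per_dim=6)
    assert g.n_blocks >= 2
    np.testing.assert_allclose(g.P.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(g.r, 1.0 - g.Q.sum(axis=1), atol=1e-12)
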