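import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from tauramd.contacts import ContactParams, PairDistanceMatrix
from tauramd.errors import ConfigurationError, EmptySelectionError
from tauramd.fixtures import make_cluster_fixture
from tauramd.pathways import (
    BinaryIFPMatrix,
    ClusterConfig,
    FrameSelection,
    build_binary_matrix,
    cluster_frames,
    flow_graph,
    jaccard_matrix,
    last_contact_clusters,
    select_cluster_frames,
)
from tauramd.residence import DissociationEvent


def make_matrix(tid, n_frames, n_pairs=4, distances=None, seed=0):
    rng = np.random.default_rng(seed)
    d = (np.asarray(distances) if distances is not None
         else rng.uniform(3.0, 9.0, size=(n_frames, n_pairs)))
    pairs = [(("A", i, "X"), ("B", i, "X")) for i in range(d.shape[1])]
    return PairDistanceMatrix(
        pairs=pairs, distances=d, times=np.arange(d.shape[0]) * 10.0,
        delta_com=np.linspace(0, 20, d.shape[0]),
        com_com=np.linspace(10, 40, d.shape[0]),
        rmsd=np.zeros(d.shape[0]),
    )


def binary_from_fixture(fx):
    n = len(fx.true_labels)
    return BinaryIFPMatrix(
        matrix=fx.fingerprints,
        pairs=[(("A", j, "X"), ("B", j, "X"))
               for j in range(fx.fingerprints.shape[1])],
        trajectory_ids=fx.trajectory_ids,
        frame_indices=np.arange(n),
        times=np.arange(n) * 10.0,
        delta_com=fx.delta_com,
        com_com=fx.delta_com + 10.0,
        rmsd=np.zeros(n),
    )


class TestFrameSelection:
    def test_window_arithmetic(self):
        mats = {"t1": make_matrix("t1", 400)}
        events = {"t1": DissociationEvent("t1", "r1", 2500.0,
                                          "by_residue_first")}
        sel = select_cluster_frames(mats, events,
                                    ClusterConfig(pre_window_frames=200))
        assert sel.n_rows == 350
        assert sel.frame_indices[0] == 50
        assert sel.frame_indices[-1] == 399

    def test_window_clamped_at_zero(self):
        mats = {"t1": make_matrix("t1", 300)}
        events = {"t1": DissociationEvent("t1", "r1", 1000.0,
                                          "by_residue_first")}
        sel = select_cluster_frames(mats, events,
                                    ClusterConfig(pre_window_frames=200))
        assert sel.frame_indices[0] == 0

    def test_censored_trajectories_excluded(self):
        mats = {"t1": make_matrix("t1", 50), "t2": make_matrix("t2", 50)}
        events = {
            "t1": DissociationEvent("t1", "r1", 100.0, "by_residue_first"),
            "t2": DissociationEvent("t2", "r1", 490.0, "by_residue_first",
                                    censored=True),
        }
        sel = select_cluster_frames(mats, events)
        assert set(sel.trajectory_ids) == {"t1"}

    def test_all_censored_is_empty_selection(self):
        mats = {"t1": make_matrix("t1", 50)}
        events = {"t1": DissociationEvent("t1", "r1", 490.0,
                                          "by_residue_first",
                                          censored=True)}
        with pytest.raises(EmptySelectionError):
            select_cluster_frames(mats, events)


class TestBinaryMatrix:
    def test_binarization_threshold_and_empty_columns(self):
        d = np.asarray([[4.0, 9.0, 5.5], [5.0, 9.0, 4.0]])
        mats = {"t1": make_matrix("t1", 2, distances=d)}
        events = {"t1": DissociationEvent("t1", "r1", 0.0,
                                          "by_residue_first")}
        sel = select_cluster_frames(mats, events)
        binary = build_binary_matrix(sel, ContactParams())
        # column 1 never below 5.5 -> dropped; boundary 5.5 is not < 5.5
        assert binary.matrix.shape == (2, 2)
        assert binary.matrix[:, 0].tolist() == [True, True]
        assert binary.matrix[:, 1].tolist() == [False, True]


class TestJaccard:
    def test_identical_disjoint_and_partial(self):
        fp = np.asarray([
            [1, 1, 1, 0], [1, 1, 1, 0],  # identical
            [0, 0, 0, 1],                # disjoint from the first two
            [0, 1, 1, 1],                # {b,c,d} vs {a,b,c}
        ], dtype=bool)
        fx = make_cluster_fixture(n_per_block=2)
        binary = binary_from_fixture(fx)
        binary.matrix = fp
        D = jaccard_matrix(binary)
        assert D[0, 1] == 0.0
        assert D[0, 2] == 1.0
        assert D[0, 3] == pytest.approx(0.5)  # 1 - 2/4

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(8)
        M = rng.random((40, 10)) < 0.4
        fx = make_cluster_fixture(n_per_block=20, n_cols=10)
        binary = binary_from_fixture(fx)
        binary.matrix = M
        D = jaccard_matrix(binary)
        for i in range(len(M)):
            for j in range(len(M)):
                a = set(np.flatnonzero(M[i]))
                b = set(np.flatnonzero(M[j]))
                expect = 0.0 if not (a | b) else 1 - len(a & b) / len(a | b)
                assert D[i, j] == pytest.approx(expect)

    def test_symmetry_diagonal_and_triangle(self):
        rng = np.random.default_rng(9)
        M = rng.random((25, 8)) < 0.5
        fx = make_cluster_fixture(n_per_block=13, n_cols=8)
        binary = binary_from_fixture(fx)
        binary.matrix = M[:26]
        D = jaccard_matrix(binary)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        for _ in range(200):
            i, j, k = rng.integers(0, len(D), 3)
            assert D[i, k] <= D[i, j] + D[j, k] + 1e-12


class TestClustering:
    def test_planted_two_block_partition_recovered(self):
        fx = make_cluster_fixture(n_per_block=30, seed=2)
        binary = binary_from_fixture(fx)
        D = jaccard_matrix(binary)
        model = cluster_frames(D, binary, ClusterConfig(k=2, seed=0))
        assert adjusted_rand_score(fx.true_labels, model.labels) == 1.0

    def test_duplicates_share_labels_and_reruns_identical(self):
        fx = make_cluster_fixture(n_per_block=10, seed=3)
        binary = binary_from_fixture(fx)
        D = jaccard_matrix(binary)
        cfg = ClusterConfig(k=2, seed=4)
        m1 = cluster_frames(D, binary, cfg)
        m2 = cluster_frames(D, binary, cfg)
        assert np.array_equal(m1.labels, m2.labels)
        # rows 0 and 1 are duplicates by construction (no noise)
        assert m1.labels[0] == m1.labels[1]

    def test_labels_ordered_by_mean_delta_com(self):
        fx = make_cluster_fixture(n_per_block=20, seed=5)
        binary = binary_from_fixture(fx)
        D = jaccard_matrix(binary)
        model = cluster_frames(D, binary, ClusterConfig(k=2, seed=0))
        assert np.all(np.diff(model.mean_delta_com) >= 0)
        # block with small dCOM must be cluster 1
        assert model.labels[0] == 1

    def test_occupancy_rows_sum_to_mean_contact_count(self):
        fx = make_cluster_fixture(n_per_block=15, seed=6)
        binary = binary_from_fixture(fx)
        D = jaccard_matrix(binary)
        model = cluster_frames(D, binary, ClusterConfig(k=2, seed=0))
        for c in range(1, model.k + 1):
            rows = binary.matrix[model.labels == c]
            assert model.occupancy[c - 1].sum() == pytest.approx(
                rows.sum(axis=1).mean())

    def test_auto_k_finds_two_blocks(self):
        fx = make_cluster_fixture(n_per_block=25, seed=7)
        binary = binary_from_fixture(fx)
        D = jaccard_matrix(binary)
        model = cluster_frames(
            D, binary, ClusterConfig(k="auto", auto_k_range=(2, 5), seed=0))
        assert model.k == 2
        assert 2 in model.silhouette_by_k

    def test_more_clusters_than_rows_rejected(self):
        fx = make_cluster_fixture(n_per_block=2, seed=8)
        binary = binary_from_fixture(fx)
        D = jaccard_matrix(binary)
        with pytest.raises(ConfigurationError):
            cluster_frames(D, binary, ClusterConfig(k=5, seed=0))


class TestFlowGraph:
    def selection_for(self, labels_by_traj):
        tids, fids = [], []
        for tid, labels in labels_by_traj.items():
            tids += [tid] * len(labels)
            fids += list(range(len(labels)))
        return FrameSelection(np.asarray(tids), np.asarray(fids),
                              np.asarray(fids, dtype=float), {})

    def model_with_labels(self, labels):
        class M:
            pass

        m = M()
        m.labels = np.asarray(labels)
        return m

    def test_single_trajectory_hand_count(self):
        sel = self.selection_for({"t1": [1, 1, 2, 2, 3]})
        model = self.model_with_labels([1, 1, 2, 2, 3])
        g = flow_graph(model, sel)
        edges = {(e.source, e.target): e for e in g.edges}
        assert set(edges) == {(1, 2), (2, 3)}
        assert all(e.trajectory_count == 1 for e in g.edges)
        assert edges[(1, 2)].net_flow == 1

    def test_constant_labels_no_edges(self):
        sel = self.selection_for({"t1": [2, 2, 2], "t2": [1, 1]})
        model = self.model_with_labels([2, 2, 2, 1, 1])
        assert flow_graph(model, sel).edges == []

    def test_shared_transition_counts_trajectories(self):
        sel = self.selection_for({"t1": [1, 2], "t2": [1, 2, 1]})
        model = self.model_with_labels([1, 2, 1, 2, 1])
        g = flow_graph(model, sel)
        edges = {(e.source, e.target): e for e in g.edges}
        assert edges[(1, 2)].trajectory_count == 2
        assert edges[(1, 2)].net_flow == 1  # 2 forward, 1 backward
        assert edges[(2, 1)].frame_count == 1

    def test_no_cross_trajectory_transitions(self):
        sel = self.selection_for({"t1": [1, 1], "t2": [2, 2]})
        model = self.model_with_labels([1, 1, 2, 2])
        assert flow_graph(model, sel).edges == []

    def test_label_changes_equal_transition_contributions(self):
        rng = np.random.default_rng(10)
        labels_by_traj = {f"t{i}": rng.integers(1, 4, 20).tolist()
                          for i in range(4)}
        flat = [l for ls in labels_by_traj.values() for l in ls]
        sel = self.selection_for(labels_by_traj)
        model = self.model_with_labels(flat)
        g = flow_graph(model, sel)
        total_frame_transitions = sum(e.frame_count for e in g.edges)
        changes = sum(
            sum(1 for a, b in zip(ls, ls[1:]) if a != b)
            for ls in labels_by_traj.values()
        )
        assert total_frame_transitions == changes


class TestLastContacts:
    def test_single_shared_pattern(self):
        M = np.zeros((6, 5), dtype=bool)
        M[:, 2] = True  # every sparse frame keeps the same single contact
        fx = make_cluster_fixture(n_per_block=3, n_cols=5)
        binary = binary_from_fixture(fx)
        binary.matrix = M
        rep = last_contact_clusters(binary, None, ClusterConfig())
        assert len(rep.groups) == 1
        assert rep.groups[0].pattern == [binary.pairs[2]]
        assert rep.groups[0].n_trajectories == len(set(binary.trajectory_ids))

    def test_two_disjoint_patterns_split(self):
        M = np.zeros((8, 6), dtype=bool)
        M[:4, 0] = True
        M[4:, 5] = True
        fx = make_cluster_fixture(n_per_block=4, n_cols=6)
        binary = binary_from_fixture(fx)
        binary.matrix = M
        rep = last_contact_clusters(binary, None, ClusterConfig())
        assert len(rep.groups) == 2
        patterns = {tuple(g.pattern) for g in rep.groups}
        assert patterns == {(binary.pairs[0],), (binary.pairs[5],)}

    def test_three_contact_frames_excluded(self):
        M = np.zeros((4, 6), dtype=bool)
        M[0, :3] = True  # exactly 3 contacts: excluded (strict <3)
        M[1, 0] = True
        M[2, 0] = True
        M[3, :4] = True  # 4 contacts: excluded
        fx = make_cluster_fixture(n_per_block=2, n_cols=6)
        binary = binary_from_fixture(fx)
        binary.matrix = M
        rep = last_contact_clusters(binary, None, ClusterConfig())
        assert rep.n_frames_considered == 2

    def test_no_qualifying_frames_warns_empty(self):
        M = np.ones((4, 6), dtype=bool)
        fx = make_cluster_fixture(n_per_block=2, n_cols=6)
        binary = binary_from_fixture(fx)
        binary.matrix = M
        with pytest.warns(UserWarning):
            rep = last_contact_clusters(binary, None, ClusterConfig())
        assert rep.groups == []
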