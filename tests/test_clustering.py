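import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.cluster import AgglomerativeClustering

from fictivemotor.clustering import (
    ClusterAssignment,
    LabelThresholds,
    auto_label_clusters,
    classify_window,
    cluster_windows,
    label_windows,
    manual_label_clusters,
    mean_cluster_windows,
    window_signature,
)
from fictivemotor.features import FeatureMatrix
from fictivemotor.labels import MotorLabel

L = MotorLabel


def _features(X):
    return FeatureMatrix(np.asarray(X, dtype=float), "test")


def _traveling_bump(direction, amp=1.0, sigma=0.9):
    """9x8 window with a Gaussian bump sweeping the full segment axis."""
    seg = np.arange(9.0)
    pos = np.linspace(8, 0, 8) if direction == "fw" else np.linspace(0, 8, 8)
    return amp * np.exp(-((seg[:, None] - pos[None, :]) ** 2) / (2 * sigma**2))


def _burst(segments, amp=1.0):
    w = np.zeros((9, 8))
    w[segments[0] : segments[1] + 1, :] = amp
    return w


class TestClusterWindows:
    def test_two_separated_blobs(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (20, 4)), rng.normal(5, 0.05, (20, 4))])
        assignment = cluster_windows(_features(X), 2)
        labels = assignment.labels
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_ward_first_merges_hand_computed(self):
        # 1-D points {0, 1, 10, 11}: Ward's smallest variance increases are
        # the pairs (0,1) and (10,11)
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        assignment = cluster_windows(_features(X), 2)
        Z = assignment.linkage
        first_pairs = {frozenset(Z[0, :2].astype(int)), frozenset(Z[1, :2].astype(int))}
        assert first_pairs == {frozenset({0, 1}), frozenset({2, 3})}
        assert assignment.labels[0] == assignment.labels[1]
        assert assignment.labels[2] == assignment.labels[3]

    def test_cut_nesting(self, rng):
        # the flat cut at k is a refinement of the cut at k-1
        X = rng.random((40, 6))
        assignment = cluster_windows(_features(X), 5)
        for k in range(2, 8):
            fine = fcluster(assignment.linkage, t=k, criterion="maxclust")
            coarse = fcluster(assignment.linkage, t=k - 1, criterion="maxclust")
            mapping = {}
            for f, c in zip(fine, coarse):
                assert mapping.setdefault(f, c) == c

    def test_matches_sklearn_ward(self, rng):
        # independent cross-check of the Ward merge structure
        X = rng.random((30, 5))
        ours = cluster_windows(_features(X), 4).labels
        theirs = AgglomerativeClustering(n_clusters=4, linkage="ward").fit_predict(X)
        # same partition up to label permutation
        pairs = {(a, b) for a, b in zip(ours, theirs)}
        assert len({a for a, _ in pairs}) == len(pairs) == len({b for _, b in pairs})

    def test_partition_invariant_to_feature_rescaling(self, rng):
        X = rng.random((30, 5))
        a1 = cluster_windows(_features(X), 6).labels
        a2 = cluster_windows(_features(X * 17.0), 6).labels
        pairs = {(a, b) for a, b in zip(a1, a2)}
        assert len({a for a, _ in pairs}) == len(pairs)

    def test_invalid_k(self, rng):
        with pytest.raises(ValueError):
            cluster_windows(_features(rng.random((5, 3))), 0)
        with pytest.raises(ValueError):
            cluster_windows(_features(rng.random((5, 3))), 6)


class TestMeanClusterWindows:
    def test_means_match_loop_oracle(self, rng):
        tensors = rng.random((10, 9, 8))
        labels = np.array([0, 0, 1, 1, 1, 0, 2, 2, 0, 1])
        assignment = ClusterAssignment(labels=labels, linkage=np.empty((9, 4)), n_clusters=3)
        means = mean_cluster_windows(assignment, tensors)
        for cid in range(3):
            members = [tensors[i] for i in range(10) if labels[i] == cid]
            acc = np.zeros((9, 8))
            for m in members:
                acc += m
            np.testing.assert_allclose(means[cid], acc / len(members))

    def test_single_window_cluster(self, rng):
        tensors = rng.random((3, 9, 8))
        assignment = ClusterAssignment(
            labels=np.array([0, 1, 1]), linkage=np.empty((2, 4)), n_clusters=2
        )
        means = mean_cluster_windows(assignment, tensors)
        np.testing.assert_array_equal(means[0], tensors[0])

    def test_empty_cluster_warns(self, rng):
        tensors = rng.random((3, 9, 8))
        assignment = ClusterAssignment(
            labels=np.array([0, 0, 2]), linkage=np.empty((2, 4)), n_clusters=3
        )
        with pytest.warns(UserWarning, match="empty"):
            means = mean_cluster_windows(assignment, tensors)
        assert 1 not in means


class TestClassifyWindow:
    def test_zero_window_is_qs(self):
        assert classify_window(np.zeros((9, 8))) is L.QS

    def test_traveling_bumps_are_waves(self):
        assert classify_window(_traveling_bump("fw")) is L.FW
        assert classify_window(_traveling_bump("bw")) is L.BW

    def test_stationary_bursts(self):
        anterior = _burst((0, 6))
        posterior = _burst((6, 8))
        assert classify_window(anterior) is L.AT
        assert classify_window(posterior) is L.PT
        # verify the mass fractions the rules used, against a manual sum
        sig = window_signature(posterior)
        assert sig["posterior_fraction"] == pytest.approx(
            posterior[6:9].sum() / posterior.sum()
        )
        assert sig["anterior_fraction"] == pytest.approx(
            posterior[0:7].sum() / posterior.sum()
        )

    def test_boundary_straddling_window_labeled_by_center(self):
        # wave remnant in the first three columns, posterior burst from
        # column 3 on: the centre frame (column 4) lies in the burst
        w = np.zeros((9, 8))
        w[0:3, 0:3] = [[0.8, 0.3, 0.0], [0.5, 0.2, 0.0], [0.2, 0.0, 0.0]]
        w[6:9, 3:] = 0.5
        assert classify_window(w) is L.PT

    def test_label_invariant_to_window_rescaling(self):
        for w in (_traveling_bump("fw"), _burst((0, 6)), _burst((6, 8))):
            assert classify_window(w) is classify_window(np.clip(w * 0.5, 0, 1))


class TestAutoLabelClusters:
    def test_examples(self):
        means = {0: np.zeros((9, 8)), 1: _traveling_bump("fw"), 2: _burst((6, 8))}
        label_map = auto_label_clusters(means)
        assert label_map.labels == {0: L.QS, 1: L.FW, 2: L.PT}

    def test_manual_overrides(self):
        label_map = auto_label_clusters({0: np.zeros((9, 8)), 3: _traveling_bump("fw")})
        overridden = manual_label_clusters(label_map, {3: "BW"})
        assert overridden.labels[3] is L.BW
        assert overridden.labels[0] is L.QS
        assert manual_label_clusters(label_map, {}).labels == label_map.labels
        with pytest.raises(ValueError, match="unknown cluster"):
            manual_label_clusters(label_map, {9: "BW"})
        with pytest.raises(ValueError, match="unknown motor label"):
            manual_label_clusters(label_map, {3: "XX"})


class TestLabelWindows:
    def _assignment(self, labels):
        labels = np.asarray(labels)
        return ClusterAssignment(
            labels=labels, linkage=np.empty((len(labels) - 1, 4)),
            n_clusters=int(labels.max()) + 1,
        )

    def test_pure_cluster_vote_denoises(self, rng):
        # 5 FW windows and one noisy member in the same cluster: the vote
        # relabels the odd one out
        tensors = np.stack([_traveling_bump("fw")] * 5 + [_burst((6, 8))])
        wl, label_map = label_windows(self._assignment([0] * 6), tensors)
        assert all(l is L.FW for l in wl)
        assert label_map.labels[0] is L.FW

    def test_mixed_cluster_keeps_window_labels(self):
        tensors = np.stack([_traveling_bump("fw")] * 3 + [_burst((6, 8))] * 3)
        wl, label_map = label_windows(self._assignment([0] * 6), tensors)
        assert list(wl[:3]) == [L.FW] * 3 and list(wl[3:]) == [L.PT] * 3
        assert label_map.stats[0]["vote_fraction"] == pytest.approx(0.5)

    def test_override_forces_cluster(self):
        tensors = np.stack([_traveling_bump("fw")] * 4)
        wl, label_map = label_windows(
            self._assignment([0, 0, 1, 1]), tensors, overrides={1: "QS"}
        )
        assert list(wl) == [L.FW, L.FW, L.QS, L.QS]
        assert label_map.labels[1] is L.QS
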