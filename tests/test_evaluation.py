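"""Feature building, PCA, distances, precision-recall and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gotkit import (
    FeatureMatrix,
    build_features,
    cluster_complete_linkage,
    distance_matrix,
    generate,
    ModelSpec,
    pca_reduce,
    precision_recall,
)

from conftest import temporal


def brute_force_prc(dist: pd.DataFrame, labels, step=0.001):
    """Oracle: explicit pair loops at every threshold."""
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    total_correct = sum(labels[i] == labels[j] for i, j in pairs)
    n_steps = int(round(1 / step))
    precision, recall = [], []
    for k in range(n_steps + 1):
        eps = k * step
        grouped = [(i, j) for i, j in pairs if dist.iloc[i, j] <= eps]
        correct = sum(labels[i] == labels[j] for i, j in grouped)
        precision.append(correct / len(grouped) if grouped else 1.0)
        recall.append(correct / total_correct)
    aupr = sum(p * (r2 - r1) for p, r1, r2 in
               zip(precision[1:], recall[:-1], recall[1:]))
    return np.array(precision), np.array(recall), aupr


def _toy_networks():
    dense = [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d"), ("b", "d"), ("a", "d")]
    sparse = [("a", "b"), ("b", "c"), ("c", "d")]
    nets = []
    for i, base in enumerate([dense, sparse]):
        for rep in range(2):
            # perturb one edge per replicate to avoid exact duplicates
            edges = base if rep == 0 else base[:-1] + [("a", "e")]
            net = temporal(edges, edges, name=f"m{i}_r{rep}")
            net.meta["model"] = f"model{i}"
            nets.append(net)
    return nets


class TestBuildFeatures:
    def test_got_feature_length_is_orbit_count_squared(self, cat4):
        fm = build_features(_toy_networks(), "GoT", cat4)
        assert fm.X.shape == (4, 121)

    def test_stg_feature_length(self, cat4):
        fm = build_features(_toy_networks(), "STG", cat4)
        assert fm.X.shape[1] == 2 * 11

    def test_sg_and_sm_lengths(self, cat4):
        nets = _toy_networks()
        assert build_features(nets, "SG", cat4).X.shape[1] == 11
        assert build_features(nets, "SM", cat4, n_random=3).X.shape[1] == 6

    def test_identical_networks_identical_rows(self, cat4):
        nets = _toy_networks()[:2]
        nets[1].snapshots = list(nets[0].snapshots)
        fm = build_features(nets, "GoT", cat4)
        assert (fm.X.iloc[0] == fm.X.iloc[1]).all()

    def test_labels_come_from_meta(self, cat4):
        fm = build_features(_toy_networks(), "SG", cat4)
        assert fm.labels == ["model0", "model0", "model1", "model1"]

    def test_stg_rejects_unequal_snapshot_counts(self, cat4):
        nets = _toy_networks()
        nets[0].snapshots = nets[0].snapshots + [nets[0].snapshots[0]]
        with pytest.raises(ValueError, match="equal snapshot counts"):
            build_features(nets, "STG", cat4)

    def test_unknown_method_rejected(self, cat4):
        with pytest.raises(ValueError, match="unknown method"):
            build_features(_toy_networks(), "DG", cat4)

    def test_node_level_mode_for_got(self, cat4):
        fm = build_features(_toy_networks(), "GoT", cat4, node_level=True)
        assert fm.X.shape[1] == 121
        with pytest.raises(ValueError, match="node-level"):
            build_features(_toy_networks(), "SM", cat4, node_level=True)


class TestPCA:
    def _fm(self, X):
        return FeatureMatrix(X=pd.DataFrame(X), labels=["a"] * len(X), method="SG")

    def test_full_variance_preserves_distances(self):
        rng = np.random.default_rng(0)
        X = rng.random((6, 10))
        red = pca_reduce(self._fm(X), variance=1.0)
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(X), pdist(red.X.to_numpy()))

    def test_rank_one_data_keeps_single_component(self):
        u = np.arange(5, dtype=float)[:, None]
        X = u @ np.ones((1, 8))
        red = pca_reduce(self._fm(X), variance=0.99)
        assert red.X.shape[1] == 1

    def test_constant_matrix_collapses_to_zero(self):
        X = np.full((4, 6), 3.0)
        red = pca_reduce(self._fm(X), variance=0.99)
        assert red.X.shape[1] == 1
        assert (red.X.to_numpy() == 0).all()


class TestDistanceMatrix:
    def _fm(self, X, labels=None):
        labels = labels or [f"l{i}" for i in range(len(X))]
        return FeatureMatrix(X=pd.DataFrame(np.asarray(X, float)),
                             labels=labels, method="SG")

    def test_identical_rows_distance_zero(self):
        d = distance_matrix(self._fm([[1, 2], [1, 2], [5, 9]]))
        assert d.iloc[0, 1] == 0.0

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(1)
        d = distance_matrix(self._fm(rng.random((5, 3)))).to_numpy()
        assert np.allclose(d, d.T)
        assert d.min() >= 0 and d.max() == pytest.approx(1.0)

    def test_rescaling_preserves_order(self):
        X = [[0.0], [1.0], [3.0]]
        d = distance_matrix(self._fm(X))
        assert d.iloc[0, 1] < d.iloc[0, 2]
        assert d.iloc[1, 2] < d.iloc[0, 2]

    def test_all_identical_rows_warns(self, caplog):
        with caplog.at_level("WARNING", logger="gotkit"):
            d = distance_matrix(self._fm([[1, 1], [1, 1], [1, 1]]))
        assert (d.to_numpy() == 0).all()


class TestPrecisionRecall:
    def _dist(self, values, names):
        return pd.DataFrame(values, index=names, columns=names)

    def test_perfect_separation_gives_aupr_one(self):
        v = np.array([
            [0.0, 0.1, 0.9, 0.8],
            [0.1, 0.0, 0.95, 0.85],
            [0.9, 0.95, 0.0, 0.05],
            [0.8, 0.85, 0.05, 0.0],
        ])
        prc = precision_recall(self._dist(v, list("abcd")), ["x", "x", "y", "y"])
        assert prc.aupr == pytest.approx(1.0)

    def test_recall_is_one_at_epsilon_one(self):
        rng = np.random.default_rng(2)
        v = rng.random((5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        v /= v.max()
        prc = precision_recall(self._dist(v, list("abcde")),
                               ["x", "x", "y", "y", "x"])
        assert prc.recall[-1] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        n = 8
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        v /= v.max()
        labels = ["a", "a", "b", "b", "c", "c", "a", "b"]
        d = self._dist(v, [str(i) for i in range(n)])
        prc = precision_recall(d, labels, step=0.01)
        op, orc, oaupr = brute_force_prc(d, labels, step=0.01)
        assert np.allclose(prc.precision, op)
        assert np.allclose(prc.recall, orc)
        assert prc.aupr == pytest.approx(oaupr)

    def test_random_distances_approach_prevalence(self):
        """Label-independent distances give AUPR near the same-label pair
        prevalence."""
        rng = np.random.default_rng(4)
        n = 20
        labels = ["a"] * 10 + ["b"] * 10
        pairs = list(itertools.combinations(range(n), 2))
        prevalence = sum(labels[i] == labels[j] for i, j in pairs) / len(pairs)
        auprs = []
        for _ in range(20):
            v = rng.random((n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            v /= v.max()
            d = self._dist(v, [str(i) for i in range(n)])
            auprs.append(precision_recall(d, labels).aupr)
        assert abs(np.mean(auprs) - prevalence) < 0.05

    def test_single_class_rejected(self):
        v = np.zeros((3, 3))
        with pytest.raises(ValueError, match="classes"):
            precision_recall(self._dist(v, list("abc")), ["x", "x", "x"])


class TestClustering:
    def _sim(self, v, names, kind="OTA"):
        df = pd.DataFrame(v, index=names, columns=names)
        df.attrs["kind"] = kind
        return df

    def test_well_separated_pairs_merge_first(self):
        v = np.array([
            [1.0, 0.9, 0.1, 0.1],
            [0.9, 1.0, 0.1, 0.1],
            [0.1, 0.1, 1.0, 0.95],
            [0.1, 0.1, 0.95, 1.0],
        ])
        tree = cluster_complete_linkage(self._sim(v, list("abcd")))
        first_two = {frozenset(tree.linkage[0, :2].astype(int)),
                     frozenset(tree.linkage[1, :2].astype(int))}
        assert first_two == {frozenset({2, 3}), frozenset({0, 1})}

    def test_merge_heights_invariant_to_input_order(self):
        rng = np.random.default_rng(5)
        v = rng.random((5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        names = list("abcde")
        t1 = cluster_complete_linkage(self._sim(v, names))
        perm = [3, 1, 4, 0, 2]
        t2 = cluster_complete_linkage(
            self._sim(v[np.ix_(perm, perm)], [names[i] for i in perm]))
        assert np.allclose(sorted(t1.linkage[:, 2]), sorted(t2.linkage[:, 2]))

    def test_asymmetric_input_rejected(self):
        v = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            cluster_complete_linkage(self._sim(v, list("ab")))

    def test_distance_input_used_raw(self):
        v = np.array([[0.0, 0.2, 0.9],
                      [0.2, 0.0, 0.8],
                      [0.9, 0.8, 0.0]])
        tree = cluster_complete_linkage(self._sim(v, list("abc"), kind="euclidean-distance"))
        assert tree.linkage[0, 2] == pytest.approx(0.2)


def test_end_to_end_toy_grouping(cat4):
    """Structurally distinct model families separate perfectly on a toy set."""
    nets = []
    for i in range(3):
        d = generate(ModelSpec(model="barabasi", n0=25, seed=i))
        d.meta["model"] = "barabasi"
        nets.append(d)
    for i in range(3):
        s = generate(ModelSpec(model="strogatz", n0=25, beta=0.0, seed=i))
        s.meta["model"] = "strogatz"
        nets.append(s)
    from gotkit import grouping_experiment
    prc = grouping_experiment(nets, "GoT", cat4)
    assert prc.aupr > 0.8
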