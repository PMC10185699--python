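"""Clustering: k-means recovery and oracle equivalence, outcome-weighted
consensus clustering, burden ordering, PCA projection."""

import itertools

import numpy as np
import pytest
from sklearn.datasets import make_blobs
from sklearn.metrics import adjusted_rand_score

from petclust.clustering import (
    SupervisedClusterConfig,
    kmeans_cluster,
    order_clusters,
    pca_project,
    supervised_survival_cluster,
)


def _hazard_tier_data(seed=7, n=150, p_noise=300):
    """One 3-level feature drives the hazard; the rest is noise."""
    rng = np.random.default_rng(seed)
    tiers = rng.integers(0, 3, n)
    X = np.column_stack([tiers + rng.normal(0, 0.15, n),
                         rng.normal(size=(n, p_noise))])
    t = rng.exponential(1 / (0.01 * np.exp(0.9 * tiers)))
    e = rng.random(n) < 0.9
    return X, t, e, tiers


class TestKMeans:
    def test_well_separated_blobs_perfectly_recovered(self):
        X, y = make_blobs(n_samples=90, centers=3, cluster_std=0.05,
                          center_box=(-10, 10), random_state=0)
        labels = kmeans_cluster(X, k=3, seed=0)
        assert adjusted_rand_score(y, labels) == 1.0

    def test_n_equals_k_each_point_own_cluster(self):
        X = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        labels = kmeans_cluster(X, k=3, seed=0)
        assert len(set(labels)) == 3

    def test_deterministic_given_seed(self, rng):
        X = rng.random((40, 6))
        assert np.array_equal(kmeans_cluster(X, seed=5), kmeans_cluster(X, seed=5))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="k=3"):
            kmeans_cluster(np.zeros((2, 4)), k=3)

    def test_matches_exhaustive_assignment_on_tiny_instances(self, rng):
        """k-means inertia equals the global optimum found by enumerating
        every 2-partition of n <= 8 points."""
        for trial in range(5):
            X = rng.random((7, 3))
            Xc = X - X.mean(axis=0)
            best = np.inf
            for assignment in itertools.product([0, 1], repeat=len(Xc)):
                a = np.asarray(assignment)
                if len(set(assignment)) < 2:
                    continue
                sse = sum(
                    ((Xc[a == c] - Xc[a == c].mean(axis=0)) ** 2).sum()
                    for c in (0, 1)
                )
                best = min(best, sse)
            from sklearn.cluster import KMeans

            km = KMeans(n_clusters=2, n_init=50, random_state=trial).fit(Xc)
            assert km.inertia_ == pytest.approx(best, rel=1e-9)


class TestSupervisedClustering:
    def test_planted_hazard_tiers_recovered(self):
        X, t, e, tiers = _hazard_tier_data()
        labels = supervised_survival_cluster(X, t, e, SupervisedClusterConfig(seed=0))
        assert adjusted_rand_score(tiers, labels) >= 0.8

    def test_deterministic_given_seed(self):
        X, t, e, _ = _hazard_tier_data(seed=3, n=60, p_noise=40)
        cfg = SupervisedClusterConfig(seed=11)
        a = supervised_survival_cluster(X, t, e, cfg)
        b = supervised_survival_cluster(X, t, e, cfg)
        assert np.array_equal(a, b)

    def test_constant_feature_changes_nothing(self):
        """A constant feature has coefficient 0, weight 0, and therefore
        contributes nothing to any pairwise distance."""
        X, t, e, _ = _hazard_tier_data(seed=5, n=60, p_noise=40)
        cfg = SupervisedClusterConfig(seed=2)
        base = supervised_survival_cluster(X, t, e, cfg)
        padded = supervised_survival_cluster(
            np.column_stack([X, np.full(len(X), 3.7)]), t, e, cfg
        )
        assert np.array_equal(base, padded)

    def test_no_events_rejected(self):
        X, t, _, _ = _hazard_tier_data(seed=1, n=60, p_noise=10)
        with pytest.raises(ValueError, match="event"):
            supervised_survival_cluster(X, t, np.zeros(len(X), dtype=bool))


class TestOrderClusters:
    def test_ascending_mean_mtv(self):
        raw = np.array([0, 0, 1, 1, 2, 2])
        mtv = np.array([100.0, 100.0, 5.0, 5.0, 30.0, 30.0])
        res = order_clusters(raw, mtv)
        assert list(res.labels) == ["C", "C", "A", "A", "B", "B"]
        assert res.mean_mtv == {"A": 5.0, "B": 30.0, "C": 100.0}

    def test_ties_break_by_raw_index(self):
        raw = np.array([1, 0, 2])
        mtv = np.array([10.0, 10.0, 10.0])
        res = order_clusters(raw, mtv)
        assert list(res.labels) == ["B", "A", "C"]

    def test_membership_unchanged(self, rng):
        raw = rng.integers(0, 3, 30)
        mtv = rng.random(30) * 100
        res = order_clusters(raw, mtv)
        for c in np.unique(raw):
            names = set(res.labels[raw == c])
            assert len(names) == 1

    def test_missing_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            order_clusters(np.array([0, 0, 2]), np.array([1.0, 2.0, 3.0]), k=3)


class TestPcaProject:
    def test_projection_centered(self, rng):
        coords, _ = pca_project(rng.random((30, 8)))
        assert np.abs(coords.mean(axis=0)).max() < 1e-8

    def test_variances_nonincreasing(self, rng):
        _, var = pca_project(rng.random((40, 10)), n_components=4)
        assert all(a >= b for a, b in zip(var, var[1:]))

    def test_rank_one_data_has_negligible_second_component(self, rng):
        direction = rng.random(6)
        X = np.outer(rng.random(20), direction)
        coords, var = pca_project(X)
        assert var[1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pca_project(np.full((10, 4), 2.0))


class TestMethodAgreement:
    def test_supervised_and_unsupervised_agree_on_burden_driven_cohort(self):
        """When lesion burden drives both image appearance and hazard, the
        two clustering routes substantially agree (ARI >= 0.5)."""
        import warnings

        from petclust.autoencoder import ConvAutoencoder, TrainConfig, \
            encode_features, train_autoencoder
        from petclust.bone_voi import apply_mask, extract_bone_mask
        from petclust.mip import make_mip
        from petclust.phantom import CohortSpec, simulate_cohort

        spec = CohortSpec(
            n_subjects=45,
            burden_levels=(5.0, 60.0, 300.0),
            burden_level_probs=(0.35, 0.35, 0.3),
            burden_level_suvs=(4.0, 5.5, 7.0),
            burden_level_bg_suvs=(0.7, 1.1, 1.5),
            seed=0,
        )
        cohort = simulate_cohort(spec, volumes=False)
        mips = []
        for i in range(spec.n_subjects):
            ph = cohort.realize_phantom(i)
            mask = extract_bone_mask(ph.volumes.ct)
            mips.append(make_mip(apply_mask(ph.volumes.suv, mask)))
        model = ConvAutoencoder(seed=1)
        train_autoencoder(model, mips, TrainConfig(epochs=20, seed=1))
        feats = encode_features(model, mips)
        t = cohort.records["pfs_days"].to_numpy()
        e = cohort.records["event"].to_numpy()
        unsup = kmeans_cluster(feats, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sup = supervised_survival_cluster(
                feats, t, e, SupervisedClusterConfig(seed=3, n_rounds=5)
            )
        assert adjusted_rand_score(unsup, sup) >= 0.5
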