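"""PCA feature selection, fuzzy c-means, separability, severity assignment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans

from calfmfi.clustering import (FeatureTable, FuzzyCMeans, PCAFeatureSelector,
                                assess_separability, assign_severity,
                                choose_cluster_count, fcm_cluster,
                                select_features)


def _severity_feature_frame(rng, sizes=(45, 45, 15, 2)):
    """Feature table mimicking a planted 4-level severity cohort."""
    means = np.array([[115, 102, 40], [145, 104, 48], [193, 108, 69],
                      [290, 385, 210]], dtype=float)
    sds = np.array([[2, 1, 2], [3, 2, 3], [7, 5, 9], [10, 40, 50]], dtype=float)
    rows, classes = [], []
    for k, n in enumerate(sizes):
        rows.append(rng.normal(means[k], sds[k], size=(n, 3)))
        classes += [k] * n
    X = np.vstack(rows)
    df = pd.DataFrame(X, columns=["mean_intensity", "mode_intensity", "fwhm"])
    df["subject_id"] = [f"S{i:03d}" for i in range(len(df))]
    return df, np.array(classes)


class TestFeatureTable:
    def test_zscore_invariants(self, rng):
        df, _ = _severity_feature_frame(rng)
        table = FeatureTable.from_frame(df)
        assert np.abs(table.zscored.mean().to_numpy()).max() < 1e-10
        assert np.abs(table.zscored.std(ddof=0).to_numpy() - 1).max() < 1e-10

    def test_constant_column_rejected(self, rng):
        df, _ = _severity_feature_frame(rng)
        df["fwhm"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            FeatureTable.from_frame(df)


class TestPCASelection:
    def test_importances_match_bruteforce_correlation_oracle(self, rng):
        # brute-force oracle: eigendecomposition of the 3x3 correlation
        # matrix, 95% component cut, summed |loadings|.  With two duplicated
        # columns plus independent noise, both routes agree that the second
        # PC is pure noise — so the noise column carries the largest summed
        # loading while the duplicates split the first PC between them.
        n = 2000
        f = rng.normal(size=n)
        X = np.column_stack([f + 0.01 * rng.normal(size=n),
                             f + 0.01 * rng.normal(size=n),
                             rng.normal(size=n)])
        sel = PCAFeatureSelector().fit(X)

        Z = (X - X.mean(0)) / X.std(0)
        corr = Z.T @ Z / n
        w, v = np.linalg.eigh(corr)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        k = int(np.searchsorted(np.cumsum(w / w.sum()), 0.95 - 1e-12) + 1)
        oracle_importance = np.abs(v[:, :k]).sum(axis=1)
        assert k == sel.k_ == 2
        assert np.allclose(np.sort(oracle_importance),
                           np.sort(sel.importances_), atol=1e-3)
        assert np.array_equal(np.argsort(oracle_importance),
                              np.argsort(sel.importances_))

    def test_identity_correlation_gives_equal_variance_ratios(self, rng):
        # columns orthonormal and zero-mean: sample correlation is exactly
        # the identity, so every component explains 1/3 of the variance and
        # all three components are needed for the 95% cut (the loading
        # basis itself is arbitrary in the degenerate subspace)
        n = 60
        A = rng.normal(size=(n, 3))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        sel = PCAFeatureSelector().fit(Q)
        assert sel.k_ == 3
        assert np.allclose(sel.explained_variance_ratio_, 1 / 3, atol=1e-9)

    def test_planted_cohort_selects_mean_and_mode(self, rng):
        df, _ = _severity_feature_frame(rng)
        sel = select_features(FeatureTable.from_frame(df))
        assert set(sel.top_features_) == {"mean_intensity", "mode_intensity"}

    def test_deterministic_loadings_sign(self, rng):
        df, _ = _severity_feature_frame(rng)
        X = df[["mean_intensity", "mode_intensity", "fwhm"]].to_numpy()
        s1 = PCAFeatureSelector().fit(X)
        s2 = PCAFeatureSelector().fit(X)
        assert np.array_equal(s1.loadings_, s2.loadings_)
        for j in range(s1.loadings_.shape[1]):
            i = np.argmax(np.abs(s1.loadings_[:, j]))
            assert s1.loadings_[i, j] > 0


class TestFuzzyCMeans:
    def _two_clouds(self, rng, n=60):
        return np.vstack([rng.normal((0, 0), 0.3, (n, 2)),
                          rng.normal((5, 5), 0.3, (n, 2))])

    def test_separated_clouds_confident_memberships(self, rng):
        X = self._two_clouds(rng)
        fcm = fcm_cluster(X, c=2, seed=0)
        assert fcm.membership_.max(axis=1).min() > 0.95

    def test_partition_matches_kmeans_oracle(self, rng):
        X = self._two_clouds(rng)
        fcm = fcm_cluster(X, c=2, seed=0)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        agree = (fcm.labels_ == km.labels_).mean()
        assert agree in (0.0, 1.0)  # identical partition up to relabeling

    def test_equidistant_point_gets_half_memberships(self, rng):
        X = np.vstack([self._two_clouds(rng), [[2.5, 2.5]]])
        fcm = fcm_cluster(X, c=2, m=2.0, seed=0)
        assert np.allclose(fcm.membership_[-1], [0.5, 0.5], atol=0.01)

    def test_objective_monotone_nonincreasing(self, rng):
        X = rng.normal(size=(80, 2))
        fcm = fcm_cluster(X, c=3, seed=1)
        assert np.all(np.diff(fcm.objective_history_) <= 1e-9)

    def test_memberships_row_stochastic(self, rng):
        X = rng.normal(size=(50, 2))
        fcm = fcm_cluster(X, c=4, seed=2)
        assert np.allclose(fcm.membership_.sum(axis=1), 1.0, atol=1e-9)
        assert fcm.membership_.min() >= 0 and fcm.membership_.max() <= 1

    def test_coincident_point_and_centroid(self):
        X = np.array([[0.0, 0.0]] * 5 + [[4.0, 4.0]] * 5)
        fcm = fcm_cluster(X, c=2, seed=0)
        assert np.allclose(np.sort(fcm.membership_.max(axis=1)), 1.0)

    def test_hard_limit_matches_kmeans(self, rng):
        # m -> 1+ drives memberships toward hard k-means assignments
        X = self._two_clouds(rng)
        fcm = fcm_cluster(X, c=2, m=1.05, seed=0)
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        agree = (fcm.labels_ == km.labels_).mean()
        assert agree in (0.0, 1.0)

    def test_parameter_validation(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fcm_cluster(X, c=10)
        with pytest.raises(ValueError):
            fcm_cluster(X, c=2, m=1.0)

    def test_predict_consistent_with_fit(self, rng):
        X = self._two_clouds(rng)
        fcm = fcm_cluster(X, c=2, seed=0)
        assert np.array_equal(fcm.predict(X), fcm.labels_)


class TestSeparability:
    def test_disjoint_intervals_separable(self):
        x = np.concatenate([np.linspace(0, 1, 10), np.linspace(3, 4, 10)])
        labels = np.array([0] * 10 + [1] * 10)
        _, ok = assess_separability(x[:, None], labels)
        assert ok

    def test_xor_pattern_not_separable(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        labels = np.array([0, 0, 1, 1])
        _, ok = assess_separability(X, labels)
        assert not ok

    def test_random_labels_on_one_cloud_not_separable(self, rng):
        X = rng.normal(size=(100, 2))
        labels = rng.integers(0, 2, size=100)
        _, ok = assess_separability(X, labels)
        assert not ok

    def test_single_label_rejected(self, rng):
        with pytest.raises(ValueError):
            assess_separability(rng.normal(size=(10, 2)), np.zeros(10))


class TestChooseClusterCount:
    def test_four_planted_gaussians_recovered(self, rng):
        centers = np.array([[0, 0], [4, 0], [0, 4], [5, 5]], dtype=float)
        X = np.vstack([rng.normal(c, 0.35, (40, 2)) for c in centers])
        c, diag = choose_cluster_count(X, seed=1)
        assert c == 4
        assert list(diag["c"]) == [3, 4, 5]
        assert set(diag.columns) >= {"c", "objective", "separable"}

    def test_single_gaussian_warns_and_falls_back(self, rng):
        X = rng.normal(size=(100, 2))
        with pytest.warns(UserWarning, match="separable"):
            c, diag = choose_cluster_count(X, seed=1)
        assert c == 3
        assert not diag["separable"].any()


class TestAssignSeverity:
    def test_clusters_named_by_ascending_mean_centroid(self, rng):
        df, classes = _severity_feature_frame(rng)
        table = FeatureTable.from_frame(df)
        Z = table.zscored[["mean_intensity", "mode_intensity"]].to_numpy()
        fcm = fcm_cluster(Z, c=4, seed=0)
        sev = assign_severity(fcm)
        order = ["normal", "mild", "moderate", "severe"]
        assert sev.class_names == order
        # centroid mean-intensity coordinate must increase along the order
        means = [fcm.cluster_centers_[np.where(sev.cluster_order == k)[0][0], 0]
                 for k in range(4)]
        assert np.all(np.diff(means) > 0)

    def test_planted_severity_recovery_at_least_90pc(self, rng):
        df, classes = _severity_feature_frame(rng)
        table = FeatureTable.from_frame(df)
        Z = table.zscored[["mean_intensity", "mode_intensity"]].to_numpy()
        fcm = fcm_cluster(Z, c=4, seed=0)
        sev = assign_severity(fcm)
        order = {"normal": 0, "mild": 1, "moderate": 2, "severe": 3}
        predicted = np.array([order[s] for s in sev.labels])
        assert (predicted == classes).mean() >= 0.90

    def test_mean_only_clustering_similar_groups(self, rng):
        # single-feature FCM on the mean index alone finds comparable groups
        df, classes = _severity_feature_frame(rng)
        table = FeatureTable.from_frame(df)
        z1 = table.zscored[["mean_intensity"]].to_numpy()
        fcm = fcm_cluster(z1, c=4, seed=0)
        sev = assign_severity(fcm, mean_col=0, mode_col=None)
        order = {"normal": 0, "mild": 1, "moderate": 2, "severe": 3}
        predicted = np.array([order[s] for s in sev.labels])
        assert (predicted == classes).mean() >= 0.80

    def test_labels_invariant_to_feature_order_and_affine_rescale(self, rng):
        df, _ = _severity_feature_frame(rng)
        t1 = FeatureTable.from_frame(df)
        Z1 = t1.zscored[["mean_intensity", "mode_intensity"]].to_numpy()
        s1 = assign_severity(fcm_cluster(Z1, c=4, seed=0))

        df2 = df.copy()
        df2["mean_intensity"] = df2["mean_intensity"] * 3.0 + 10.0
        df2 = df2[["fwhm", "mode_intensity", "mean_intensity", "subject_id"]]
        t2 = FeatureTable.from_frame(
            df2, columns=("fwhm", "mode_intensity", "mean_intensity")
        )
        Z2 = t2.zscored[["mean_intensity", "mode_intensity"]].to_numpy()
        s2 = assign_severity(fcm_cluster(Z2, c=4, seed=0))
        assert s1.labels == s2.labels

    def test_group_profiles_population_average(self, rng):
        from calfmfi.histogram import HistogramProfile

        df, _ = _severity_feature_frame(rng, sizes=(5, 5, 5, 5))
        table = FeatureTable.from_frame(df)
        Z = table.zscored[["mean_intensity", "mode_intensity"]].to_numpy()
        fcm = fcm_cluster(Z, c=4, seed=0)
        x = np.arange(0, 400, 2.0) + 1.0
        profiles = []
        for mu in df["mean_intensity"]:
            y = np.exp(-((x - mu) ** 2) / (2 * 40**2))
            y *= 100.0 / np.trapezoid(y, x)
            profiles.append(HistogramProfile(x=x, y=y, bin_width=2.0,
                                             provenance={}))
        sev = assign_severity(fcm, profiles=profiles)
        for name in sev.class_names:
            prof = sev.group_profiles[name]
            assert prof is not None
            assert np.trapezoid(prof.y, prof.x) == pytest.approx(100.0, abs=1e-9)
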