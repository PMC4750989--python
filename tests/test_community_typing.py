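import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

from glvtypes import (characterize_clusters, cluster_ensemble, jsd_distance,
                      jsd_matrix, kmedoids, pcoa, relative_abundance,
                      select_k, silhouette, simulate_ensemble, variance_ratio)


def two_blob_distance(n_per=10, within=0.05, between=0.9, seed=0):
    rng = np.random.default_rng(seed)
    q = 2 * n_per
    D = np.zeros((q, q))
    for i, j in itertools.combinations(range(q), 2):
        same = (i < n_per) == (j < n_per)
        base = within if same else between
        D[i, j] = D[j, i] = base * (0.5 + rng.random())
    return D


def simplex_points(m, n, seed):
    rng = np.random.default_rng(seed)
    X = rng.dirichlet(np.ones(n), size=m)
    return X


class TestRelativeAbundance:
    def test_simple(self):
        assert np.allclose(relative_abundance(np.array([[2.0, 2.0]])), 0.5)

    def test_idempotent(self):
        row = np.array([[0.2, 0.3, 0.5]])
        assert np.allclose(relative_abundance(row), row)

    def test_rows_sum_to_one(self):
        X = np.random.default_rng(0).uniform(0, 5, (20, 7))
        assert np.allclose(relative_abundance(X).sum(1), 1.0, atol=1e-12)

    def test_rejects_negative_and_zero_rows(self):
        with pytest.raises(ValueError):
            relative_abundance(np.array([[1.0, -0.1]]))
        with pytest.raises(ValueError):
            relative_abundance(np.array([[0.0, 0.0]]))


class TestJSD:
    def test_identity(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jsd_distance(p, p) == 0.0

    def test_disjoint_supports_max(self):
        assert jsd_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == \
            pytest.approx(1.0)

    def test_hand_case_against_scipy(self):
        p, q = np.array([1.0, 0.0]), np.array([0.5, 0.5])
        assert jsd_distance(p, q) == pytest.approx(
            jensenshannon(p, q, base=2), abs=1e-12)

    def test_matrix_against_scipy_pairwise(self):
        X = simplex_points(8, 5, seed=1)
        D = jsd_matrix(X)
        for i in range(8):
            for j in range(8):
                assert D[i, j] == pytest.approx(
                    jensenshannon(X[i], X[j], base=2), abs=1e-10)

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=25)
    def test_metric_axioms_sampled(self, seed):
        p, q, r = simplex_points(3, 6, seed)
        dpq, dqp = jsd_distance(p, q), jsd_distance(q, p)
        assert dpq == pytest.approx(dqp, abs=1e-12)
        assert 0 <= dpq <= 1
        assert jsd_distance(p, r) <= dpq + jsd_distance(q, r) + 1e-12

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            jsd_distance(np.array([0.5, 0.6]), np.array([0.5, 0.5]))


class TestKMedoids:
    def test_k_equals_q(self):
        D = two_blob_distance()
        labels, medoids, cost = kmedoids(D, k=len(D))
        assert cost == 0.0
        assert len(set(medoids)) == len(D)

    def test_two_blobs_recovered(self):
        D = two_blob_distance()
        labels, medoids, cost = kmedoids(D, 2, seed=0)
        first = labels[:10]
        assert len(set(first)) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_matches_exhaustive_optimum(self):
        # PAM equals the global optimum on small instances
        rng = np.random.default_rng(3)
        for trial in range(4):
            X = rng.uniform(0, 1, (11, 3))
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            for k in (2, 3):
                _, _, cost = kmedoids(D, k, seed=trial)
                best = min(D[:, list(combo)].min(1).sum()
                           for combo in itertools.combinations(range(11), k))
                assert cost == pytest.approx(best, abs=1e-9)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            kmedoids(two_blob_distance(), 21)


class TestSilhouette:
    def test_perfect_separation(self):
        D = two_blob_distance(within=0.0, between=1.0)
        labels = np.repeat([0, 1], 10)
        assert silhouette(D, labels) == pytest.approx(1.0)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 4))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        labels = rng.integers(0, 2, 60)
        assert abs(silhouette(D, labels)) < 0.1

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(9, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        vals = []
        for i in range(9):
            own = labels == labels[i]
            a = D[i, own & (np.arange(9) != i)].mean()
            b = min(D[i, labels == c].mean() for c in set(labels) - {labels[i]})
            vals.append((b - a) / max(a, b))
        assert silhouette(D, labels) == pytest.approx(np.mean(vals), abs=1e-12)

    def test_single_cluster_undefined(self):
        with pytest.raises(ValueError):
            silhouette(two_blob_distance(), np.zeros(20, dtype=int))


class TestVarianceRatio:
    def test_textbook_formula(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(c, 0.3, (15, 3)) for c in (0, 3, 6)])
        labels = np.repeat([0, 1, 2], 15)
        # independent evaluation of the Calinski-Harabasz definition
        q, k = 45, 3
        overall = X.mean(0)
        between = sum(15 * ((X[labels == c].mean(0) - overall) ** 2).sum()
                      for c in range(3))
        within = sum(((X[labels == c] - X[labels == c].mean(0)) ** 2).sum()
                     for c in range(3))
        expected = (between / within) * (q - k) / (k - 1)
        assert variance_ratio(X, labels) == pytest.approx(expected, rel=1e-9)

    def test_separated_beats_shuffled(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.2, (10, 2)), rng.normal(5, 0.2, (10, 2))])
        labels = np.repeat([0, 1], 10)
        shuffled = rng.permutation(labels)
        assert variance_ratio(X, labels) > variance_ratio(X, shuffled)

    def test_degenerate_returns_inf(self):
        X = np.repeat(np.array([[0.0, 0.0], [1.0, 1.0]]), 5, axis=0)
        labels = np.repeat([0, 1], 5)
        assert variance_ratio(X, labels) == np.inf


class TestSelectK:
    def test_argmax(self):
        assert select_k({2: 0.9, 3: 0.4}) == (2, 0.9)

    def test_tie_to_smallest(self):
        assert select_k({k: 0.5 for k in range(2, 11)})[0] == 2

    def test_empty(self):
        with pytest.raises(ValueError):
            select_k({})


class TestPCoA:
    def test_recovers_planar_configuration(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]], float)
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, eigval, neg = pcoa(D)
        # distances reproduced exactly (configuration up to rigid motion)
        D2 = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.allclose(D2, D, atol=1e-8)
        assert neg < 1e-10

    def test_identical_points_coincide(self):
        D = np.zeros((3, 3))
        D[0, 2] = D[2, 0] = D[1, 2] = D[2, 1] = 1.0
        coords, _, _ = pcoa(D)
        assert np.allclose(coords[0], coords[1], atol=1e-9)

    def test_jsd_input_reports_negative_mass(self):
        X = simplex_points(12, 6, seed=9)
        coords, eigval, neg = pcoa(jsd_matrix(X))
        assert np.all(eigval > 0)
        assert neg >= 0.0

    def test_against_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as skbio_pcoa
        X = simplex_points(10, 5, seed=11)
        D = jsd_matrix(X)
        ours, _, _ = pcoa(D, dims=2)
        theirs = skbio_pcoa(skbio.DistanceMatrix(D)).samples.to_numpy()[:, :2]
        # same embedding up to per-axis sign
        for j in range(2):
            assert min(np.abs(ours[:, j] - theirs[:, j]).max(),
                       np.abs(ours[:, j] + theirs[:, j]).max()) < 1e-8


class TestPipeline:
    def test_ensemble_and_profiles(self, small_meta, small_lcs):
        ens = simulate_ensemble(small_meta, small_lcs, seed=7)
        assert ens.q + ens.n_unstable == len(small_lcs)
        assert np.allclose(ens.relative.sum(1), 1.0)
        clus = cluster_ensemble(ens, krange=range(2, 5), restarts=3)
        assert clus.k_opt in range(2, 5)
        assert np.all(clus.distance >= 0)
        assert np.allclose(clus.distance, clus.distance.T)
        profiles = characterize_clusters(ens, np.zeros(ens.q, dtype=int),
                                         sis_ids=small_meta.sis_ranking()[:2])
        # a single cluster reproduces the global abundance ranking
        mean_rel = ens.relative.mean(0)
        top = [sp for sp, _ in profiles[0].top_species]
        assert top == list(np.argsort(-mean_rel, kind="stable")[:6])
        assert all(0 <= f <= 1 for f in profiles[0].sis_presence.values())

    def test_unknown_sis_id_rejected(self, small_meta, small_lcs):
        ens = simulate_ensemble(small_meta, small_lcs, seed=7)
        with pytest.raises(ValueError):
            characterize_clusters(ens, np.zeros(ens.q, dtype=int), sis_ids=[999])
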