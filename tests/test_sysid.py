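import numpy as np
import pytest

from glvtypes import (MetacommunityConfig, RegressionProblem, TaxaTimeSeries,
                      build_regression, cross_validate_lambda,
                      generate_metacommunity, permute_days, ridge_fit,
                      sample_local_communities, sis_scores, synth_timeseries)


@pytest.fixture(scope="module")
def small_lc():
    meta = generate_metacommunity(MetacommunityConfig(n=12, alpha=2.0, seed=3))
    return sample_local_communities(meta, q=1, p=10, seed=3)[0]


def recovery_error(lc, ts, lam, count_scale):
    prob = build_regression(ts, relative=False, count_scale=count_scale)
    fit = ridge_fit(prob, lam)
    return (np.linalg.norm(fit.A_hat - lc.A_local) / np.linalg.norm(lc.A_local),
            np.linalg.norm(fit.r_hat - lc.r_local) / np.linalg.norm(lc.r_local))


class TestBuildRegression:
    def test_consecutive_day_rule(self):
        counts = np.array([[5, 6, 7, 8], [5, 4, 3, 2]])
        ts = TaxaTimeSeries(taxa=["a", "b"], counts=counts,
                            timestamps=np.array([1, 2, 4, 5]))
        prob = build_regression(ts)
        assert prob.pair_index == [(0, 1), (2, 3)]
        assert prob.Y.shape == (2, 2)
        assert np.all(prob.Phi[0] == 1.0)

    def test_constant_composition_zero_target(self):
        counts = np.tile(np.array([[10], [30]]), (1, 4))
        ts = TaxaTimeSeries(taxa=["a", "b"], counts=counts,
                            timestamps=np.arange(1, 5))
        assert np.allclose(build_regression(ts).Y, 0.0)

    def test_hand_computed_with_zero_count(self):
        # zero read -> one read inserted, then per-day normalization
        counts = np.array([[4, 0, 2], [2, 3, 2], [4, 7, 6]])
        ts = TaxaTimeSeries(taxa=list("abc"), counts=counts,
                            timestamps=np.array([3, 4, 5]))
        prob = build_regression(ts)
        cols = counts.astype(float)
        cols[0, 1] = 1.0
        rel = cols / cols.sum(0)
        Y_expected = np.log(rel[:, 1:]) - np.log(rel[:, :-1])
        assert np.allclose(prob.Y, Y_expected)
        assert np.allclose(prob.Phi[1:], rel[:, :2])

    def test_no_pairs_raises(self):
        ts = TaxaTimeSeries(taxa=["a"], counts=np.array([[1, 2]]),
                            timestamps=np.array([1, 5]))
        with pytest.raises(ValueError):
            build_regression(ts)


class TestRidgeFit:
    def test_noiseless_generative_recovery(self, small_lc):
        ts = synth_timeseries(small_lc, days=120, depth=10**9, seed=0,
                              scheme="euler", count_mode="rounded",
                              restart_every=20)
        errA, errR = recovery_error(small_lc, ts, lam=0.0, count_scale=10**9)
        assert errA < 1e-6 and errR < 1e-6

    def test_shrinkage_limit(self, small_lc):
        ts = synth_timeseries(small_lc, days=60, seed=1, restart_every=20)
        prob = build_regression(ts)
        norms = [np.linalg.norm(ridge_fit(prob, lam).Theta_hat)
                 for lam in (0.01, 1.0, 100.0, 1e6)]
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3 * norms[0]

    def test_matches_sklearn_ridge(self):
        # independent minimizer of the same penalized objective
        from sklearn.linear_model import Ridge
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(4, 30))
        Phi = np.vstack([np.ones(30), rng.uniform(0, 1, (4, 30))])
        prob = RegressionProblem(Y=Y, Phi=Phi, pair_index=[])
        lam = 0.37
        ours = ridge_fit(prob, lam).Theta_hat
        ref = Ridge(alpha=lam, fit_intercept=False).fit(Phi.T, Y.T).coef_
        assert np.allclose(ours, ref, atol=1e-8)

    def test_rank_deficient_lam_zero_raises(self):
        Phi = np.ones((3, 5))  # rank 1
        prob = RegressionProblem(Y=np.ones((2, 5)), Phi=Phi, pair_index=[])
        with pytest.raises(np.linalg.LinAlgError):
            ridge_fit(prob, 0.0)


class TestCrossValidation:
    def test_single_value_grid(self, small_lc):
        ts = synth_timeseries(small_lc, days=60, seed=4, restart_every=20)
        lam, errors = cross_validate_lambda([ts], grid=[0.3])
        assert lam == 0.3 and set(errors) == {0.3}

    def test_noiseless_prefers_smallest(self, small_lc):
        ts = synth_timeseries(small_lc, days=120, depth=10**9, seed=0,
                              scheme="euler", count_mode="rounded",
                              restart_every=20)
        lam, _ = cross_validate_lambda([ts], grid=[1e-6, 1e-2, 1.0, 10.0],
                                       relative=False)
        assert lam == 1e-6

    def test_noisy_prefers_larger(self, small_lc):
        grid = [1e-6, 1e-2, 1.0, 10.0]
        clean = synth_timeseries(small_lc, days=120, depth=10**9, seed=0,
                                 scheme="euler", count_mode="rounded",
                                 restart_every=20)
        noisy = synth_timeseries(small_lc, days=120, depth=2000, noise_c=0.3,
                                 seed=2, restart_every=20)
        lam_clean, _ = cross_validate_lambda([clean], grid=grid, relative=False)
        lam_noisy, _ = cross_validate_lambda([noisy], grid=grid, relative=False)
        assert lam_noisy > lam_clean


class TestSisScores:
    def test_dominant_column_ranks_first(self):
        A_hat = np.zeros((6, 6))
        A_hat[:, 3] = [10, -10, 10, -10, 10, -10]
        theta = np.hstack([np.zeros((6, 1)), A_hat])
        from glvtypes import SysIdResult
        res = SysIdResult(Theta_hat=theta, lam=0.1, taxa=list("abcdef"))
        assert sis_scores(res).index[0] == "d"

    def test_all_zero(self):
        from glvtypes import SysIdResult
        res = SysIdResult(Theta_hat=np.zeros((3, 4)), lam=0.1)
        assert np.all(sis_scores(res) == 0)

    def test_generative_sis_recovered(self):
        # noiseless fit reproduces the true interaction-strength ranking
        meta = generate_metacommunity(MetacommunityConfig(n=12, alpha=1.2, seed=9))
        lc = sample_local_communities(meta, q=1, p=10, seed=9)[0]
        ts = synth_timeseries(lc, days=120, depth=10**9, seed=1,
                              scheme="euler", count_mode="rounded",
                              restart_every=20)
        fit = ridge_fit(build_regression(ts, relative=False, count_scale=10**9),
                        1e-8)
        fit.taxa = list(lc.members)
        true_order = lc.members[np.argsort(-lc.A_local.std(axis=0, ddof=0),
                                           kind="stable")]
        assert list(sis_scores(fit).index) == list(true_order)


class TestPermutation:
    def test_multiset_preserved(self, small_lc):
        ts = synth_timeseries(small_lc, days=40, seed=5)
        perm = permute_days(ts, seed=1)
        assert np.array_equal(perm.timestamps, ts.timestamps)
        assert np.array_equal(np.sort(perm.counts, axis=1),
                              np.sort(ts.counts, axis=1))

    def test_recovery_degrades_under_permutation(self, small_lc):
        ts = synth_timeseries(small_lc, days=120, depth=10**9, seed=0,
                              scheme="euler", count_mode="rounded",
                              restart_every=20)
        base, _ = recovery_error(small_lc, ts, lam=1e-8, count_scale=10**9)
        permuted = [recovery_error(small_lc, permute_days(ts, seed=s),
                                   lam=1e-8, count_scale=10**9)[0]
                    for s in range(10)]
        assert np.median(permuted) > base


class TestSynthTimeseries:
    def test_multinomial_counts_sum_to_depth(self, small_lc):
        ts = synth_timeseries(small_lc, days=25, depth=5000, seed=6)
        assert np.all(ts.counts.sum(axis=0) == 5000)
        assert ts.counts.shape == (10, 25)

    def test_full_dropout_raises(self, small_lc):
        with pytest.raises(ValueError):
            synth_timeseries(small_lc, days=10, dropout_prob=1.0, seed=0)

    def test_dropout_keeps_consecutive_rule_working(self, small_lc):
        ts = synth_timeseries(small_lc, days=60, dropout_prob=0.3, seed=7)
        prob = build_regression(ts)
        for a, b in prob.pair_index:
            assert ts.timestamps[b] - ts.timestamps[a] == 1

    def test_tsv_roundtrip(self, small_lc, tmp_path):
        ts = synth_timeseries(small_lc, days=15, seed=8)
        ts.to_tsv(tmp_path / "table.tsv")
        back = TaxaTimeSeries.from_tsv(tmp_path / "table.tsv")
        assert np.array_equal(back.counts, ts.counts)
        assert np.array_equal(back.timestamps, ts.timestamps)
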