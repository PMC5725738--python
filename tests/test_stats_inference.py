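"""Cluster permutation, max-statistic thresholds, Wilcoxon/Spearman."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from mswtk import stats_inference as si


class TestClusterPermutation:
    def test_identical_conditions_give_no_clusters(self, rng):
        a = rng.standard_normal((10, 30))
        res = si.cluster_permutation(a, a.copy(), rng=rng)
        assert res.clusters == []

    def test_matches_exhaustive_sign_flip_enumeration(self, rng):
        """Permutation p at n=8 subjects ~ exact p over all 2^8 sign flips."""
        n_sub, n_time = 8, 25
        d = rng.standard_normal((n_sub, n_time)) * 0.8
        d[:, 10:16] += 1.3          # injected effect
        params = si.ClusterParams(n_perm=4000)
        res = si.cluster_permutation(d, None, params=params, rng=rng)
        assert res.clusters, "expected at least one cluster"

        # oracle: exhaustive null of the max cluster size
        null = []
        for signs in itertools.product([1, -1], repeat=n_sub):
            t = si._paired_t(np.asarray(signs)[:, None] * d)
            sizes = [b - a for a, b, _ in si._clusters_from_t(t, 1.8, 2)]
            null.append(max(sizes, default=0))
        null = np.asarray(null)
        for c in res.clusters:
            exact = (1 + np.sum(null >= c.stat)) / (1 + len(null))
            assert c.p_value == pytest.approx(exact, abs=0.02)

    def test_detects_strong_contiguous_effect(self, rng):
        n_sub = 14
        a = rng.standard_normal((n_sub, 40))
        b = rng.standard_normal((n_sub, 40))
        a[:, 20:30] += 2.0
        res = si.cluster_permutation(a, b, rng=rng)
        sig = res.significant(0.005)
        assert sig
        best = max(sig, key=lambda c: c.stat)
        assert best.stat >= 8
        assert 0 <= best.t_start <= 21 and 28 <= best.t_end <= 39

    def test_p_values_never_zero(self, rng):
        a = rng.standard_normal((8, 20))
        a[:, 5:15] += 5
        res = si.cluster_permutation(a, None, params=si.ClusterParams(n_perm=200), rng=rng)
        assert all(c.p_value >= 1 / 201 for c in res.clusters)

    def test_nan_columns_break_clusters(self, rng):
        a = rng.standard_normal((10, 20)) + 3
        a[0, 10] = np.nan
        res = si.cluster_permutation(a, None, rng=rng)
        assert all(not (c.t_start <= 10 <= c.t_end) for c in res.clusters)

    def test_too_few_subjects_raise(self, rng):
        with pytest.raises(ValueError):
            si.cluster_permutation(rng.standard_normal((3, 10)), None, rng=rng)


class TestMaxStatThreshold:
    def test_threshold_monotone_in_alpha(self, rng):
        null = rng.standard_normal((500, 30))
        it = iter(null)

        def shuffler(r, data=null):
            return data[r.integers(len(data))]

        thrs = [
            si.max_stat_threshold(shuffler, n_perm=500, alpha=a,
                                  rng=np.random.default_rng(0))[0]
            for a in (0.01, 0.05, 0.2)
        ]
        assert thrs[0] >= thrs[1] >= thrs[2]

    def test_warns_on_unstable_quantile(self, rng):
        with pytest.warns(UserWarning):
            si.max_stat_threshold(lambda r: r.standard_normal(5),
                                  n_perm=100, alpha=0.01, rng=rng)

    def test_deterministic_under_seed(self):
        def shuffler(r):
            return r.standard_normal(20)

        a = si.max_stat_threshold(shuffler, n_perm=300, rng=np.random.default_rng(7))
        b = si.max_stat_threshold(shuffler, n_perm=300, rng=np.random.default_rng(7))
        assert a[0] == b[0]


class TestWilcoxonEffect:
    def test_effect_size_identity(self):
        # r = Z / sqrt(N): the printed pairing for Z=-2.688 at N=40
        assert si.effect_size_r(-2.688, 40) == pytest.approx(-0.425, abs=5e-4)

    def test_zero_difference_flagged(self):
        z, p, r = si.wilcoxon_effect(np.ones(10), np.ones(10))
        assert np.isnan(z) and np.isnan(p) and np.isnan(r)

    def test_small_n_p_matches_exact_enumeration(self, rng):
        """Normal-approx p is close to the exact signed-rank p at n=6."""
        d = np.array([1.2, -0.4, 2.3, 0.7, -1.5, 0.9])
        z, p, r = si.wilcoxon_effect(d)
        exact = sps.wilcoxon(d, method="exact").pvalue
        # oracle: enumerate all 2^6 sign assignments of the ranks
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        stats = np.asarray([
            np.sum(ranks[np.asarray(s) > 0])
            for s in itertools.product([1, -1], repeat=6)
        ])
        mu = stats.mean()
        p_enum = np.mean(np.abs(stats - mu) >= np.abs(w_obs - mu) - 1e-12)
        assert exact == pytest.approx(p_enum, abs=1e-12)
        # the normal approximation is close (not equal) to exact at tiny n
        assert p == pytest.approx(exact, abs=0.12)
        assert r == pytest.approx(z / np.sqrt(6))

    def test_consistent_z_sign(self, rng):
        x = rng.standard_normal(40)
        z, p, r = si.wilcoxon_effect(x - 2, x)
        assert z < 0 and p < 0.001 and r < -0.4


class TestSpearman:
    def test_monotone_invariance(self, rng):
        x = rng.standard_normal(30)
        rho, _ = si.spearman(x, x**3)
        assert rho == pytest.approx(1.0)
        rho, _ = si.spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_matches_pearson_on_ranks_with_ties(self, rng):
        x = rng.integers(0, 5, 50).astype(float)
        y = rng.integers(0, 5, 50).astype(float)
        rho, _ = si.spearman(x, y)
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_flagged(self):
        rho, p = si.spearman(np.ones(10), np.arange(10))
        assert np.isnan(rho) and np.isnan(p)


class TestCorrelationCluster:
    def test_perfect_coupling_detected(self, rng):
        n_sub, n_time = 15, 30
        latent = rng.standard_normal(n_sub)
        x = latent[:, None] + 0.3 * rng.standard_normal((n_sub, n_time))
        y = latent[:, None] + 0.3 * rng.standard_normal((n_sub, n_time))
        rho, res = si.correlation_cluster(x, y, params=si.ClusterParams(n_perm=300), rng=rng)
        assert np.nanmean(rho) > 0.7
        assert res.significant(0.05)

    def test_independent_series_mostly_clean(self, rng):
        hits = 0
        for _ in range(20):
            x = rng.standard_normal((12, 25))
            y = rng.standard_normal((12, 25))
            _, res = si.correlation_cluster(x, y, params=si.ClusterParams(n_perm=150), rng=rng)
            hits += bool(res.significant(0.05))
        assert hits <= 3
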