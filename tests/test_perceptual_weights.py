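"""Time-resolved logistic evidence weights, Az, reliability influence."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from mswtk import perceptual_weights as pw
from mswtk.perceptual_weights import WeightSeries


class TestTimeResolvedWeights:
    def test_recovers_logistic_coefficients(self, rng):
        """Known-beta choices with orthogonal regressors -> betas within 10%."""
        n = 5000
        acc_a = rng.standard_normal(n)
        acc_v = rng.standard_normal(n)
        b_true = np.array([1.2, 0.5])
        p = 1 / (1 + np.exp(-(acc_a * b_true[0] + acc_v * b_true[1])))
        y = (rng.random(n) < p).astype(int)
        Z = np.column_stack([acc_a, acc_v])
        got = pw._logistic((Z - Z.mean(0)) / Z.std(0), y)
        assert np.allclose(got, b_true, rtol=0.10, atol=0.05)

    def test_weights_and_az_on_real_trial_table(self, av_trials):
        ws = pw.time_resolved_weights(av_trials, compute_az=True,
                                      rng=np.random.default_rng(0))
        assert set(ws.beta) == set(pw.CONDITIONS)
        late = ws.times >= 300
        # auditory dominance (generator weight 0.8/0.84) in normalised weights
        assert np.nanmean(ws.w["AVH-aud"][late]) > np.nanmean(ws.w["AVH-vis"][late])
        # evidence accumulates: late Az beats early Az
        for rel in ("high", "low"):
            az = ws.az[rel]
            assert np.nanmean(az[ws.times >= 400]) > np.nanmean(az[ws.times <= 100])
        # weights grow with accumulated evidence
        b = ws.beta["AVH-aud"] + ws.beta["AVL-aud"]
        assert np.nanmean(b[ws.times >= 400]) > np.nanmean(b[ws.times <= 100])

    def test_requires_both_reliabilities(self, av_trials):
        high_only = av_trials[av_trials["reliability"] == "high"]
        with pytest.raises(ValueError):
            pw.time_resolved_weights(high_only)

    def test_normalized_weights_sum_to_one_when_flagged(self, av_trials):
        ws = pw.time_resolved_weights(av_trials)
        for rel, tag in (("high", "AVH"), ("low", "AVL")):
            flag = ws.normalized[rel]
            s = ws.w[f"{tag}-aud"][flag] + ws.w[f"{tag}-vis"][flag]
            assert np.allclose(s, 1.0)


class TestModelAz:
    def test_separable_data_reaches_one(self, rng):
        X = np.concatenate([rng.normal(-5, 0.1, (40, 2)), rng.normal(5, 0.1, (40, 2))])
        y = np.repeat([0, 1], 40)
        assert pw.model_az(X, y, rng=rng) == pytest.approx(1.0)

    def test_az_equals_mann_whitney_u_identity(self, rng):
        """ROC area equals U/(n0*n1) on the same scores."""
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, 200)
        scores = rng.standard_normal(200) + y
        az = roc_auc_score(y, scores)
        u = mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        assert az == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()), abs=1e-12)

    def test_null_az_near_half(self, rng):
        # null ROC-area SD at n=500 is ~0.026 and CV adds a slight
        # pessimistic bias, so bracket at ~3 SD around chance
        azs = []
        for _ in range(40):
            X = rng.standard_normal((500, 2))
            y = rng.integers(0, 2, 500)
            azs.append(pw.model_az(X, y, rng=rng))
        azs = np.asarray(azs)
        assert np.mean((azs >= 0.42) & (azs <= 0.58)) >= 0.95
        assert 0.46 <= azs.mean() <= 0.54

    def test_refold_when_small_class(self, rng):
        X = rng.standard_normal((30, 2))
        y = np.array([0] * 25 + [1] * 5)
        az = pw.model_az(X, y, k=10, rng=rng)   # silently re-stratifies to 5 folds
        assert 0 <= az <= 1
        with pytest.raises(ValueError):
            pw.model_az(X[:26], np.array([0] * 25 + [1]), rng=rng)


class TestReliabilityInfluence:
    def _ws(self, w):
        times = np.arange(24, 120, 12.0)
        arrs = {c: np.full(len(times), w[c]) for c in pw.CONDITIONS}
        return WeightSeries(times, beta=arrs, w=arrs)

    def test_identical_conditions_give_zero(self):
        ws = self._ws({c: 0.4 for c in pw.CONDITIONS})
        assert np.allclose(pw.reliability_influence(ws), 0.0)

    def test_hand_computed_value(self):
        ws = self._ws({"AVH-aud": 0.8, "AVH-vis": 0.2, "AVL-aud": 0.6, "AVL-vis": 0.4})
        assert np.allclose(pw.reliability_influence(ws), 0.4)

    def test_matches_brute_force_recompute_and_nan_propagation(self, rng):
        times = np.arange(24, 360, 12.0)
        arrs = {c: rng.standard_normal(len(times)) for c in pw.CONDITIONS}
        arrs["AVH-aud"][3] = np.nan
        ws = WeightSeries(times, beta=arrs, w=arrs)
        d = pw.reliability_influence(ws)
        for i in range(len(times)):
            expect = (arrs["AVH-aud"][i] - arrs["AVH-vis"][i]) - (
                arrs["AVL-aud"][i] - arrs["AVL-vis"][i]
            )
            if np.isnan(expect):
                assert np.isnan(d[i])
            else:
                assert d[i] == pytest.approx(expect)


class TestWeightCorrelation:
    def test_perfect_agreement_gives_rho_one(self, rng):
        d = rng.standard_normal((10, 6))
        rho, _ = pw.weight_correlation(d, d[:, 0] ** 3)   # monotone of column 0
        assert rho[0] == pytest.approx(1.0)

    def test_independent_noise_mostly_small(self, rng):
        ok = 0
        for _ in range(30):
            d = rng.standard_normal((20, 1))
            s = rng.standard_normal(20)
            rho, _ = pw.weight_correlation(d, s)
            ok += abs(rho[0]) < 0.3
        assert ok >= 24   # >= ~90% of null runs

    def test_constant_input_flagged(self, rng):
        d = np.ones((8, 4))
        rho, p = pw.weight_correlation(d, rng.standard_normal(8))
        assert np.isnan(rho).all()


def test_resample_to_grid_nearest_neighbour():
    times = np.array([0.0, 12.0, 24.0])
    vals = np.array([[1.0, 2.0, 3.0]])
    out = pw.resample_to_grid(vals, times, np.array([5.0, 11.0, 20.0]))
    assert np.array_equal(out, [[1.0, 2.0, 3.0]])
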