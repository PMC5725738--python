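"""Regularised LDA decoding: Fisher oracle, application, Az, forward model."""

import numpy as np
import pytest

from mswtk import decoding as dec
from mswtk.experiments import EEG_EPOCH_MS, _av_design
from mswtk.stimgen import generate_trial_table
from mswtk.synthetic_data import (
    EEGForwardParams,
    EpochedEEG,
    ObserverParams,
    simulate_choices,
    simulate_eeg,
)


def _epochs_from_matrix(X: np.ndarray) -> EpochedEEG:
    """Wrap a trials x channels matrix as single-sample epochs at t=0."""
    return EpochedEEG(
        data=X[:, :, None], times=np.array([0.0]),
        channels=[f"c{i}" for i in range(X.shape[1])],
        trial_id=np.arange(len(X)),
    )


@pytest.fixture(scope="module")
def eeg_subject():
    """One synthetic subject with EEG (moderate noise for decodability)."""
    rng = np.random.default_rng(2024)
    trials = generate_trial_table(_av_design(480), rng)
    simulate_choices(trials, ObserverParams(), rng)
    eeg = simulate_eeg(trials, EEGForwardParams(), rng, epoch_window_ms=EEG_EPOCH_MS)
    return trials, eeg


class TestTrainDiscriminant:
    def test_matches_analytic_fisher_direction(self, rng):
        mean0, mean1 = np.array([0.0, 0.0]), np.array([2.0, 1.0])
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        n = 20_000
        X = np.concatenate([
            rng.multivariate_normal(mean0, cov, n),
            rng.multivariate_normal(mean1, cov, n),
        ])
        labels = np.repeat([0, 1], n)
        m = dec.train_discriminant(_epochs_from_matrix(X), labels, 0.0,
                                   window_ms=1.0, shrinkage=0.0)
        fisher = np.linalg.solve(cov, mean1 - mean0)
        cos = m.w @ fisher / (np.linalg.norm(m.w) * np.linalg.norm(fisher))
        assert cos > 0.999

    def test_matches_explicit_inverse_oracle(self, rng):
        """Shrinkage-LDA weights equal a direct matrix-inverse solve, <=3 ch."""
        for p in (2, 3):
            X = rng.standard_normal((40, p))
            labels = rng.permutation(np.repeat([0, 1], 20))
            for gamma in (0.1, 0.5, 0.9):
                m = dec.train_discriminant(_epochs_from_matrix(X), labels, 0.0,
                                           window_ms=1.0, shrinkage=gamma)
                m0, m1 = X[labels == 0].mean(0), X[labels == 1].mean(0)
                Xc = np.concatenate([X[labels == 0] - m0, X[labels == 1] - m1])
                S = Xc.T @ Xc / len(X)
                cov = (1 - gamma) * S + gamma * np.trace(S) / p * np.eye(p)
                w_oracle = np.linalg.inv(cov) @ (m1 - m0)
                assert np.allclose(m.w, w_oracle, atol=1e-10)
                assert m.c == pytest.approx(-w_oracle @ (m0 + m1) / 2, abs=1e-10)

    def test_full_shrinkage_is_mean_difference(self, rng):
        X = rng.standard_normal((60, 5))
        labels = np.repeat([0, 1], 30)
        m = dec.train_discriminant(_epochs_from_matrix(X), labels, 0.0,
                                   window_ms=1.0, shrinkage=1.0)
        m0, m1 = X[labels == 0].mean(0), X[labels == 1].mean(0)
        nu = np.trace(np.cov((X - np.where(labels[:, None], m1, m0)).T, bias=True))
        assert np.allclose(m.w * (nu / 5), m1 - m0, atol=1e-10)

    def test_rank_deficient_requires_shrinkage(self, rng):
        X = rng.standard_normal((10, 30))   # fewer trials than channels
        labels = np.repeat([0, 1], 5)
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            dec.train_discriminant(_epochs_from_matrix(X), labels, 0.0,
                                   window_ms=1.0, shrinkage=0.0)

    def test_single_class_raises(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            dec.train_discriminant(_epochs_from_matrix(X), np.ones(10, int), 0.0)


class TestApplyDiscriminant:
    def test_training_scores_reproduced(self, rng):
        X = rng.standard_normal((50, 4)) + np.repeat([0, 1], 25)[:, None]
        labels = np.repeat([0, 1], 25)
        ep = _epochs_from_matrix(X)
        m = dec.train_discriminant(ep, labels, 0.0, window_ms=1.0)
        out = dec.apply_discriminant([m], ep)
        assert np.allclose(out.y[:, 0], X @ m.w + m.c)

    def test_channel_mismatch_raises(self, rng):
        m = dec.train_discriminant(
            _epochs_from_matrix(rng.standard_normal((20, 3))),
            np.repeat([0, 1], 10), 0.0, window_ms=1.0)
        with pytest.raises(ValueError):
            dec.apply_discriminant([m], _epochs_from_matrix(rng.standard_normal((20, 4))))


class TestDecoderAz:
    def test_informative_channel_gives_high_az(self, rng):
        labels = rng.permutation(np.repeat([0, 1], 60))
        X = rng.standard_normal((120, 8)) * 0.05
        X[:, 3] += labels * 3.0
        res = dec.decoder_az(_epochs_from_matrix(X), labels, np.array([0.0]),
                             window_ms=1.0, rng=rng)
        assert res["az"][0] > 0.99

    def test_max_stat_threshold_reproducible_and_null_az(self, rng):
        X = rng.standard_normal((80, 6, 12))
        ep = EpochedEEG(X, np.arange(12.0), [f"c{i}" for i in range(6)], np.arange(80))
        labels = rng.permutation(np.repeat([0, 1], 40))
        times = np.array([0.0, 4.0, 8.0])
        kw = dict(window_ms=4.0, n_perm=80, k=5)
        with pytest.warns(UserWarning):
            r1 = dec.decoder_az(ep, labels, times, rng=np.random.default_rng(3), **kw)
        with pytest.warns(UserWarning):
            r2 = dec.decoder_az(ep, labels, times, rng=np.random.default_rng(3), **kw)
        assert r1["threshold"] == r2["threshold"]
        assert np.all(np.abs(np.asarray(r1["az"]) - 0.5) < 0.2)

    def test_transfer_to_incongruent_trials(self, eeg_subject):
        """Congruent-trained decoder separates rate on held-out conflict trials."""
        trials, eeg = eeg_subject
        times = np.arange(96.0, 300.0, 12.0)
        out = dec.decode_subject(eeg, trials, times=times)
        inc = (trials["modality"].isin(["AVH", "AVL"])
               & (trials["delta"] != 0) & trials["label"].notna()).to_numpy()
        labels = trials.loc[inc, "label"].astype(int).to_numpy()
        from sklearn.metrics import roc_auc_score

        az = np.mean([
            roc_auc_score(labels, out.y[inc, i]) for i in range(len(times))
        ])
        assert az > 0.53


class TestForwardModel:
    def test_self_channel_correlation_is_one(self, rng):
        X = rng.standard_normal((60, 3))
        ep = _epochs_from_matrix(X)
        m = dec.DiscriminantModel(w=np.array([1.0, 0, 0]), c=0.0, t_onset=0.0, window_ms=1.0)
        out = dec.apply_discriminant([m], ep)
        a = dec.forward_model(out, ep, window_ms=1.0)
        assert a[0, 0] == pytest.approx(1.0)
        assert np.all(np.abs(a) <= 1.0)

    def test_recovers_generator_mixing_vector(self, rng):
        """On noiseless epochs the forward map aligns with the source topography."""
        fwd = EEGForwardParams(noise_sd=0.0, gain_aud={"high": 0.0, "low": 0.0})
        trials = generate_trial_table(_av_design(160), rng)
        simulate_choices(trials, ObserverParams(), rng)
        eeg = simulate_eeg(trials, fwd, rng, epoch_window_ms=EEG_EPOCH_MS)
        times = np.array([160.0])   # visual kernel peak region
        out = dec.decode_subject(eeg, trials, times=times)
        a = np.nan_to_num(dec.forward_model(out, eeg)[:, 0])
        cos = abs(a @ fwd.mix_vis) / np.linalg.norm(a)
        assert cos > 0.99

    def test_zero_variance_channel_flagged(self, rng):
        X = rng.standard_normal((40, 2))
        X[:, 1] = 0.0
        ep = _epochs_from_matrix(X)
        m = dec.DiscriminantModel(w=np.array([1.0, 0.0]), c=0.0, t_onset=0.0, window_ms=1.0)
        out = dec.apply_discriminant([m], ep)
        a = dec.forward_model(out, ep, window_ms=1.0)
        assert np.isnan(a[1, 0])
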