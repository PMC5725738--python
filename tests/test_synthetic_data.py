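"""Observer model, EEG forward model, study writer."""

import numpy as np
import pytest

from mswtk import psychometrics as psy
from mswtk import stimgen as sg
from mswtk import synthetic_data as sd


class TestObserver:
    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            sd.ObserverParams(sigma_aud=0.0)
        with pytest.raises(ValueError):
            sd.ObserverParams(w_aud_high=1.4)
        with pytest.raises(ValueError):
            sd.ObserverParams(lapse=0.5)

    def test_easy_trial_limit(self, rng):
        """Tiny sensory noise at rate 14 vs the 11 Hz standard -> P(first) ~ 1."""
        design = sg.TrialDesign(n_trials=200, condition_weights=(1, 0, 0, 0, 0, 0, 0, 0, 0),
                                equal_rate_fraction=0)
        trials = sg.generate_trial_table(design, rng)
        obs = sd.ObserverParams(sigma_aud=0.01, lapse=0.0)
        sd.simulate_choices(trials, obs, rng)
        hard = trials[trials["rate"] == 14]
        assert hard["choice"].mean() == 1.0
        low = trials[trials["rate"] == 8]
        assert low["choice"].mean() == 0.0

    def test_symmetric_weights_give_balanced_choices(self, rng):
        design = sg.TrialDesign(n_trials=3000, condition_weights=(0, 0, 0, 1, 0, 0, 0, 0, 0),
                                equal_rate_fraction=1.0)   # all equal-rate AV trials
        trials = sg.generate_trial_table(design, rng)
        obs = sd.ObserverParams(sigma_vis_high=sd.ObserverParams().sigma_aud,
                                w_aud_high=0.5, lapse=0.0)
        sd.simulate_choices(trials, obs, rng)
        assert abs(trials["choice"].mean() - 0.5) < 0.05

    def test_missing_rate_raises(self, rng):
        design = sg.TrialDesign(n_trials=20, condition_weights=(1, 0, 0, 0, 0, 0, 0, 0, 0))
        trials = sg.generate_trial_table(design, rng)
        trials.loc[:, "rate_aud"] = np.nan
        with pytest.raises(ValueError):
            sd.simulate_choices(trials, sd.ObserverParams(), rng)

    def test_psychometric_pse_near_standard_at_delta_zero(self, rng):
        """Unbiased congruent observer -> fitted PSE ~ 11 Hz within CI."""
        design = sg.TrialDesign(n_trials=4000, condition_weights=(0, 0, 0, 1, 0, 0, 0, 0, 0))
        trials = sg.generate_trial_table(design, rng)
        sd.simulate_choices(trials, sd.ObserverParams(lapse=0.0), rng)
        fit = psy.fit_psychometric(trials["rate"], trials["choice"].astype(int),
                                   n_boot=200, rng=rng)
        lo, hi = fit.ci("mu")
        assert lo < 11.0 < hi

    def test_optimal_threshold_relation(self, rng):
        """Optimal-weight observer: sigma_AV^2 ~ harmonic combination of
        unisensory variances (the hallmark of statistically optimal fusion)."""
        obs0 = sd.ObserverParams()
        w_opt = sd.optimal_weight(obs0.sigma_aud, obs0.sigma_vis_high)
        obs = sd.ObserverParams(w_aud_high=w_opt, lapse=0.0)
        design = sg.TrialDesign(n_trials=10_000, condition_weights=(0, 0, 0, 1, 0, 0, 0, 0, 0))
        trials = sg.generate_trial_table(design, rng)
        sd.simulate_choices(trials, obs, rng)
        fit = psy.fit_psychometric(trials["rate"], trials["choice"].astype(int),
                                   n_boot=200, lapse=0.0, rng=rng)
        pred = np.sqrt(
            obs.sigma_aud**2 * obs.sigma_vis_high**2
            / (obs.sigma_aud**2 + obs.sigma_vis_high**2)
        )
        lo, hi = fit.ci("sigma")
        assert lo < pred < hi


class TestEEGForward:
    def test_zero_gain_zero_noise_gives_zero_epochs(self, rng):
        design = sg.TrialDesign(n_trials=12, condition_weights=(0, 0, 0, 1, 0, 0, 1, 0, 0))
        trials = sg.generate_trial_table(design, rng)
        fwd = sd.EEGForwardParams(noise_sd=0.0,
                                  gain_aud={"high": 0, "low": 0},
                                  gain_vis={"high": 0, "low": 0})
        eeg = sd.simulate_eeg(trials, fwd, rng)
        assert np.allclose(eeg.data, 0.0)

    def test_single_event_trace_is_shifted_kernel(self, rng):
        """Noiseless single click: channel trace = gain * mix * kernel at latency."""
        trials = sg.generate_trial_table(
            sg.TrialDesign(n_trials=10, condition_weights=(1, 0, 0, 0, 0, 0, 0, 0, 0)), rng)
        trials = trials.iloc[[0]].copy()
        trials["onsets_aud"] = "[0.0]"
        fwd = sd.EEGForwardParams(noise_sd=0.0, gain_vis={"high": 0, "low": 0},
                                  latency_aud_ms=100.0)
        fs = 200.0
        eeg = sd.simulate_eeg(trials, fwd, rng, fs=fs)
        kernel = fwd.kernel(fs)
        start = np.searchsorted(eeg.times, 100.0)
        ch = np.argmax(np.abs(fwd.mix_aud))
        got = eeg.data[0, ch, start:start + 20]
        expect = fwd.gain_aud["high"] * fwd.mix_aud[ch] * kernel[:20]
        assert np.allclose(got, expect, atol=1e-12)

    def test_linearity_in_gains(self, rng):
        design = sg.TrialDesign(n_trials=16, condition_weights=(0, 0, 0, 1, 1, 1, 0, 0, 0))
        trials = sg.generate_trial_table(design, rng)
        k1 = sd.EEGForwardParams(noise_sd=0.0)
        k2 = sd.EEGForwardParams(noise_sd=0.0,
                                 gain_aud={k: 2 * v for k, v in k1.gain_aud.items()},
                                 gain_vis={k: 2 * v for k, v in k1.gain_vis.items()})
        e1 = sd.simulate_eeg(trials, k1, np.random.default_rng(0))
        e2 = sd.simulate_eeg(trials, k2, np.random.default_rng(0))
        assert np.allclose(e2.data, 2 * e1.data, atol=1e-12)

    def test_short_epoch_window_raises(self, rng):
        trials = sg.generate_trial_table(
            sg.TrialDesign(n_trials=10, condition_weights=(1, 0, 0, 0, 0, 0, 0, 0, 0)), rng)
        with pytest.raises(ValueError):
            sd.simulate_eeg(trials, sd.EEGForwardParams(), rng, epoch_window_ms=(-50, 100))

    def test_mixing_vector_validation(self):
        with pytest.raises(ValueError):
            sd.EEGForwardParams(mix_aud=np.ones(64))   # not unit norm


class TestMakeStudy:
    def test_files_written_and_deterministic(self, tmp_path, rng):
        design = sg.TrialDesign(n_trials=60)
        kw = dict(n_subjects=3, seed=11, design=design, with_eeg=False)
        truth1 = sd.make_study(tmp_path / "a", **kw)
        truth2 = sd.make_study(tmp_path / "b", **kw)
        assert len(truth1) == 3
        for sid in range(3):
            f1 = (tmp_path / "a" / f"sub-{sid:02d}_trials.csv").read_bytes()
            f2 = (tmp_path / "b" / f"sub-{sid:02d}_trials.csv").read_bytes()
            assert f1 == f2
        assert truth1.equals(truth2)

    def test_eeg_roundtrip(self, tmp_path):
        design = sg.TrialDesign(n_trials=18, condition_weights=(0, 0, 0, 1, 1, 1, 0, 0, 0))
        sd.make_study(tmp_path, n_subjects=1, seed=2, design=design, with_eeg=True)
        sub = sd.load_subject(tmp_path, 0)
        assert sub.eeg is not None
        assert sub.eeg.data.shape[0] == len(sub.trials)
        assert sub.eeg.data.shape[1] == 64
        assert len(sub.eeg.channels) == 64

    def test_heterogeneity_injects_weight_spread(self, tmp_path):
        het = sd.SubjectHeterogeneity()
        truth = sd.make_study(tmp_path, n_subjects=12, seed=3,
                              design=sg.TrialDesign(n_trials=30),
                              het=het, with_eeg=False)
        shifts = truth["w_aud_low"] - truth["w_aud_high"]
        assert shifts.std() > 0.1
        assert (shifts < 0).any() and (shifts > 0).any()   # some subjects reversed
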