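"""Synthetic behaviour + EEG study generator with known ground truth.

The observer model follows the standard cue-combination account: on each
trial the internal rate estimates are corrupted by Gaussian sensory noise
whose SD depends on modality and (for vision) on reliability, audio-visual
estimates are combined with a fixed weight, and the observer reports "first
stream higher" when the combined estimate exceeds an internal criterion
(the 11 Hz standard by default).  Placing the noise directly on the rate
estimates (in Hz) means the psychometric threshold sigma fitted downstream
estimates the generator's sigma in the same units, so the whole
psychometric stage is a closed-loop parameter-recovery test.

The EEG side is an explicitly artifact-side generative stand-in (the study
this emulates *measures* neural weights, it does not model them): per trial,
auditory and visual event trains are convolved with an evoked-response
kernel, delayed by a modality-specific latency, scaled by a
reliability-dependent gain, mixed linearly into 64 channels through fixed
unit-norm topographies, and buried in spatially correlated Gaussian noise.
Reliability-dependent gains are what downstream "neural weight" analyses
should recover; the gain defaults emulate the phenomenon under study
(visual gain drops and auditory gain rises when visual reliability is low,
at visual/auditory response latencies of 90 and 160 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import stimgen
from .stimgen import STANDARD_RATE, TrialDesign, generate_trial_table, onsets_from_json

# ---------------------------------------------------------------------------
# observer model


@dataclass(frozen=True)
class ObserverParams:
    """Noisy cue-combination observer.

    Sigmas are sensory-noise SDs in Hz (defaults follow typical human
    thresholds on this task: auditory ~2.2 Hz, visual ~2.9/4.6 Hz for
    high/low reliability).  ``w_aud_high``/``w_aud_low`` are the *true*
    auditory combination weights per visual-reliability condition; values
    above the statistically optimal weight encode an auditory bias.
    ``criterion`` is the internal decision boundary in Hz.
    """

    sigma_aud: float = 2.19
    sigma_vis_high: float = 2.87
    sigma_vis_low: float = 4.55
    w_aud_high: float = 0.80
    w_aud_low: float = 0.84
    lapse: float = 0.01
    criterion: float = float(STANDARD_RATE)
    standard_rate: float = float(STANDARD_RATE)

    def __post_init__(self) -> None:
        if min(self.sigma_aud, self.sigma_vis_high, self.sigma_vis_low) <= 0:
            raise ValueError("sensory noise SDs must be > 0")
        for w in (self.w_aud_high, self.w_aud_low):
            if not 0 <= w <= 1:
                raise ValueError("combination weights must lie in [0, 1]")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")

    def sigma_vis(self, reliability: str) -> float:
        return self.sigma_vis_high if reliability == "high" else self.sigma_vis_low

    def w_aud(self, reliability: str) -> float:
        return self.w_aud_high if reliability == "high" else self.w_aud_low


def optimal_weight(sigma_aud: float, sigma_vis: float) -> float:
    """Statistically optimal auditory weight from unisensory noise SDs."""
    return (1 / sigma_aud**2) / (1 / sigma_aud**2 + 1 / sigma_vis**2)


def simulate_choices(
    trials: pd.DataFrame, obs: ObserverParams, rng: np.random.Generator
) -> np.ndarray:
    """Simulate the "first stream higher" choice for every trial, in place.

    Internal estimates: r_A ~ N(rate_aud, sigma_aud), r_V ~ N(rate_vis,
    sigma_vis(reliability)); combined = w*r_A + (1-w)*r_V on AV trials,
    the unisensory estimate otherwise; choice = combined > criterion,
    flipped with probability ``lapse``.
    """
    n = len(trials)
    modality = trials["modality"].to_numpy()
    rel = trials["reliability"].to_numpy()
    has_aud = np.isin(modality, ("AUD", "AVH", "AVL"))
    has_vis = np.isin(modality, ("VH", "VL", "AVH", "AVL"))
    rate_aud = pd.to_numeric(trials["rate_aud"], errors="coerce").to_numpy(float)
    rate_vis = pd.to_numeric(trials["rate_vis"], errors="coerce").to_numpy(float)
    if np.any(has_aud & ~np.isfinite(rate_aud)) or np.any(has_vis & ~np.isfinite(rate_vis)):
        raise ValueError("trial missing a rate for a presented modality")

    sig_v = np.where(rel == "high", obs.sigma_vis_high, obs.sigma_vis_low)
    r_hat_a = rate_aud + obs.sigma_aud * rng.standard_normal(n)
    r_hat_v = rate_vis + sig_v * rng.standard_normal(n)
    w = np.where(rel == "high", obs.w_aud_high, obs.w_aud_low)

    est = np.where(has_aud & has_vis, w * r_hat_a + (1 - w) * r_hat_v,
                   np.where(has_aud, r_hat_a, r_hat_v))
    choice = (est > obs.criterion).astype(int)
    flip = rng.random(n) < obs.lapse
    choice[flip] = 1 - choice[flip]
    trials["choice"] = choice
    return choice


# ---------------------------------------------------------------------------
# EEG forward model


def _bump(n_channels: int, center: float, width: float) -> np.ndarray:
    """Unit-norm Gaussian topography over the channel index axis."""
    idx = np.arange(n_channels)
    v = np.exp(-0.5 * ((idx - center) / width) ** 2)
    return v / np.linalg.norm(v)


def default_channel_names(n: int = 64) -> list[str]:
    """BioSemi-style 64-channel labels A1..A32, B1..B32."""
    return [f"{bank}{i}" for bank in "AB" for i in range(1, n // 2 + 1)][:n]


@dataclass(frozen=True)
class EEGForwardParams:
    """Linear generative model of epoched EEG.

    ``gain_*`` map the trial's visual-reliability condition to a source
    gain; latencies are the modality response delays in ms; the kernel is a
    causal gamma-shaped pulse (unit peak) parameterised by its peak time and
    FWHM.  Noise is Gaussian, white in time, with exp(-d/corr_scale)
    spatial correlation across the channel index.
    """

    n_channels: int = 64
    mix_aud: np.ndarray | None = None     # unit-norm channel topographies
    mix_vis: np.ndarray | None = None
    gain_aud: dict = field(default_factory=lambda: {"high": 1.0, "low": 1.5})
    gain_vis: dict = field(default_factory=lambda: {"high": 1.0, "low": 0.45})
    latency_aud_ms: float = 160.0
    latency_vis_ms: float = 90.0
    kernel_peak_ms: float = 100.0
    kernel_fwhm_ms: float = 50.0
    noise_sd: float = 0.4
    noise_spatial_corr: float = 5.0

    def __post_init__(self) -> None:
        for g in (*self.gain_aud.values(), *self.gain_vis.values()):
            if g < 0:
                raise ValueError("gains must be >= 0")
        if min(self.latency_aud_ms, self.latency_vis_ms) < 0:
            raise ValueError("latencies must be >= 0")
        if self.mix_aud is None:
            object.__setattr__(self, "mix_aud", _bump(self.n_channels, 0.35 * self.n_channels, 4.0))
        if self.mix_vis is None:
            object.__setattr__(self, "mix_vis", _bump(self.n_channels, 0.85 * self.n_channels, 4.0))
        for v in (self.mix_aud, self.mix_vis):
            if v.shape != (self.n_channels,):
                raise ValueError("mixing vector shape mismatch")
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
                raise ValueError("mixing vectors must be unit norm")

    def kernel(self, fs: float) -> np.ndarray:
        """Sampled causal gamma pulse, unit peak amplitude."""
        alpha = (2.355 * self.kernel_peak_ms / self.kernel_fwhm_ms) ** 2
        dt = 1000.0 / fs
        support = self.kernel_peak_ms + 6 * self.kernel_fwhm_ms
        t = np.arange(0.0, support, dt)   # k(0) = 0: response starts after the event
        with np.errstate(divide="ignore"):
            x = t / self.kernel_peak_ms
            k = x**alpha * np.exp(alpha * (1 - x))
        k[0] = 0.0
        return k

    def kernel_support_ms(self) -> float:
        return self.kernel_peak_ms + 6 * self.kernel_fwhm_ms


@dataclass
class EpochedEEG:
    """Trials x channels x time array with channel labels and a ms time axis."""

    data: np.ndarray
    times: np.ndarray                      # ms relative to stream onset
    channels: list[str]
    trial_id: np.ndarray

    def __post_init__(self) -> None:
        n_tr, n_ch, n_t = self.data.shape
        if len(self.channels) != n_ch or len(self.times) != n_t or len(self.trial_id) != n_tr:
            raise ValueError("EpochedEEG axis metadata does not match data shape")

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            f.create_dataset("channels", data=np.array(self.channels, dtype="S"))
            f.create_dataset("trial_id", data=self.trial_id)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "EpochedEEG":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                times=f["times"][()],
                channels=[c.decode() for c in f["channels"][()]],
                trial_id=f["trial_id"][()],
            )


def _source_timecourses(
    onset_lists: list[np.ndarray],
    times_ms: np.ndarray,
    latency_ms: float,
    kernel: np.ndarray,
    fs: float,
) -> np.ndarray:
    """Event trains -> kernel-convolved source signals (trials x time)."""
    dt = 1000.0 / fs
    n_t = len(times_ms)
    impulses = np.zeros((len(onset_lists), n_t))
    t0 = times_ms[0]
    for i, on in enumerate(onset_lists):
        if len(on) == 0:
            continue
        idx = np.round((np.asarray(on) + latency_ms - t0) / dt).astype(int)
        idx = idx[(idx >= 0) & (idx < n_t)]
        np.add.at(impulses[i], idx, 1.0)
    full = np.apply_along_axis(lambda x: np.convolve(x, kernel), 1, impulses)
    return full[:, :n_t]


def simulate_eeg(
    trials: pd.DataFrame,
    fwd: EEGForwardParams,
    rng: np.random.Generator,
    *,
    fs: float = 200.0,
    epoch_window_ms: tuple[float, float] = (-200.0, 800.0),
) -> EpochedEEG:
    """Generate one subject's epoched EEG for a trial table.

    channels = gain_aud * mix_aud (x) s_aud + gain_vis * mix_vis (x) s_vis
    + spatially correlated Gaussian noise, sampled at ``fs`` (200 Hz
    default, i.e. 5 ms steps).  The pre-onset baseline is pure noise.
    """
    t0, t1 = epoch_window_ms
    if t1 <= max(fwd.latency_aud_ms, fwd.latency_vis_ms):
        raise ValueError(
            "epoch window ends before the slowest response latency; widen it"
        )
    dt = 1000.0 / fs
    times = np.arange(t0, t1, dt)
    kernel = fwd.kernel(fs)
    n, n_ch = len(trials), fwd.n_channels

    rel = trials["reliability"].to_numpy()
    g_aud = np.array([fwd.gain_aud[r] for r in rel])
    g_vis = np.array([fwd.gain_vis[r] for r in rel])
    has_aud = np.isin(trials["modality"].to_numpy(), ("AUD", "AVH", "AVL"))
    has_vis = np.isin(trials["modality"].to_numpy(), ("VH", "VL", "AVH", "AVL"))
    on_aud = [onsets_from_json(s) if a else np.empty(0)
              for s, a in zip(trials["onsets_aud"], has_aud)]
    on_vis = [onsets_from_json(s) if v else np.empty(0)
              for s, v in zip(trials["onsets_vis"], has_vis)]

    s_aud = g_aud[:, None] * _source_timecourses(on_aud, times, fwd.latency_aud_ms, kernel, fs)
    s_vis = g_vis[:, None] * _source_timecourses(on_vis, times, fwd.latency_vis_ms, kernel, fs)

    data = (
        fwd.mix_aud[None, :, None] * s_aud[:, None, :]
        + fwd.mix_vis[None, :, None] * s_vis[:, None, :]
    )
    if fwd.noise_sd > 0:
        d = np.abs(np.subtract.outer(np.arange(n_ch), np.arange(n_ch)))
        cov = np.exp(-d / fwd.noise_spatial_corr)
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n_ch))
        white = rng.standard_normal((n, n_ch, len(times)))
        data = data + fwd.noise_sd * np.einsum("ij,njt->nit", chol, white)

    return EpochedEEG(
        data=data,
        times=times,
        channels=default_channel_names(n_ch),
        trial_id=trials["trial_id"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# whole studies


@dataclass(frozen=True)
class SubjectHeterogeneity:
    """Across-subject spread of true weights and their neural coupling.

    Each subject s draws a latent u_s ~ N(0,1) setting the behavioural
    reliability shift w_aud_low - w_aud_high (mean +0.05, SD 0.12: most
    subjects raise the auditory weight when vision degrades, some shift the
    opposite way).  With ``coupling="coupled"`` the same u_s also scales the
    subject's visual-gain drop under low reliability, so behavioural and
    neural reliability influences share a common cause across subjects;
    ``"decoupled"`` uses an independent draw for the neural side.
    """

    mean_w_high: float = 0.70
    sd_w_high: float = 0.10
    mean_shift: float = 0.05
    sd_shift: float = 0.30
    coupling: str = "coupled"            # "coupled" | "decoupled" | "none"
    gain_drop_base: float = 0.50         # mean fractional visual gain drop (low rel)
    gain_drop_scale: float = 0.45        # modulation by the latent

    def draw(
        self, obs: ObserverParams, fwd: EEGForwardParams, rng: np.random.Generator
    ) -> tuple[ObserverParams, EEGForwardParams, dict]:
        u = rng.standard_normal()
        v = u if self.coupling == "coupled" else rng.standard_normal()
        w_high = float(np.clip(self.mean_w_high + self.sd_w_high * rng.standard_normal(), 0.05, 0.95))
        shift = self.mean_shift + self.sd_shift * u
        w_low = float(np.clip(w_high + shift, 0.05, 0.95))
        obs_s = replace(obs, w_aud_high=w_high, w_aud_low=w_low)
        if self.coupling == "none":
            fwd_s = fwd
            drop = 1 - fwd.gain_vis["low"] / fwd.gain_vis["high"]
        else:
            # one reweighting process: under low visual reliability the
            # visual gain drops and the auditory gain rises by the same
            # subject-specific amount
            drop = float(np.clip(self.gain_drop_base + self.gain_drop_scale * np.tanh(v), 0.0, 0.95))
            gv = dict(fwd.gain_vis)
            gv["low"] = gv["high"] * (1 - drop)
            ga = dict(fwd.gain_aud)
            ga["low"] = ga["high"] * (1 + drop)
            fwd_s = replace(fwd, gain_vis=gv, gain_aud=ga)
        truth = {
            "w_aud_high": w_high, "w_aud_low": w_low, "latent_u": u,
            "gain_vis_low": fwd_s.gain_vis["low"], "gain_drop": drop,
        }
        return obs_s, fwd_s, truth


@dataclass
class SubjectData:
    """In-memory bundle for one synthetic subject."""

    subject_id: int
    trials: pd.DataFrame
    eeg: EpochedEEG | None
    truth: dict


def simulate_subject(
    subject_id: int,
    seed_seq: np.random.SeedSequence,
    *,
    design: TrialDesign | None = None,
    obs: ObserverParams | None = None,
    fwd: EEGForwardParams | None = None,
    het: SubjectHeterogeneity | None = None,
    with_eeg: bool = True,
    fs: float = 200.0,
    epoch_window_ms: tuple[float, float] = (-200.0, 800.0),
) -> SubjectData:
    """Simulate one subject end to end (streams, choices, optionally EEG)."""
    rng = np.random.default_rng(seed_seq)
    design = design or TrialDesign()
    obs = obs or ObserverParams()
    fwd = fwd or EEGForwardParams()
    truth: dict = {}
    if het is not None:
        obs, fwd, truth = het.draw(obs, fwd, rng)
    trials = generate_trial_table(design, rng, subject_id=subject_id)
    simulate_choices(trials, obs, rng)
    eeg = (
        simulate_eeg(trials, fwd, rng, fs=fs, epoch_window_ms=epoch_window_ms)
        if with_eeg else None
    )
    truth.update({
        "sigma_aud": obs.sigma_aud, "sigma_vis_high": obs.sigma_vis_high,
        "sigma_vis_low": obs.sigma_vis_low,
        "w_aud_high": obs.w_aud_high, "w_aud_low": obs.w_aud_low,
        "gain_vis_high": fwd.gain_vis["high"], "gain_vis_low": fwd.gain_vis["low"],
        "gain_aud_high": fwd.gain_aud["high"], "gain_aud_low": fwd.gain_aud["low"],
    })
    return SubjectData(subject_id, trials, eeg, truth)


def make_study(
    out_dir: str | Path,
    *,
    n_subjects: int = 20,
    seed: int = 0,
    design: TrialDesign | None = None,
    obs: ObserverParams | None = None,
    fwd: EEGForwardParams | None = None,
    het: SubjectHeterogeneity | None = None,
    with_eeg: bool = True,
    fs: float = 200.0,
) -> pd.DataFrame:
    """Write a full synthetic study to disk; returns the ground-truth table.

    Per subject: ``sub-XX_trials.csv`` and (optionally) ``sub-XX_eeg.h5``;
    plus ``ground_truth.csv``.  Deterministic given ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    truths = []
    for sid, ss in enumerate(root.spawn(n_subjects)):
        sub = simulate_subject(
            sid, ss, design=design, obs=obs, fwd=fwd, het=het,
            with_eeg=with_eeg, fs=fs,
        )
        sub.trials.to_csv(out / f"sub-{sid:02d}_trials.csv", index=False)
        if sub.eeg is not None:
            sub.eeg.to_hdf5(out / f"sub-{sid:02d}_eeg.h5")
        truths.append({"subject_id": sid, **sub.truth})
    truth = pd.DataFrame(truths)
    truth.to_csv(out / "ground_truth.csv", index=False)
    return truth


def load_subject(study_dir: str | Path, subject_id: int, with_eeg: bool = True) -> SubjectData:
    """Read one subject back from a study directory."""
    study_dir = Path(study_dir)
    trials = pd.read_csv(study_dir / f"sub-{subject_id:02d}_trials.csv")
    eeg_path = study_dir / f"sub-{subject_id:02d}_eeg.h5"
    eeg = EpochedEEG.from_hdf5(eeg_path) if with_eeg and eeg_path.exists() else None
    truth_path = study_dir / "ground_truth.csv"
    truth = {}
    if truth_path.exists():
        row = pd.read_csv(truth_path).set_index("subject_id").loc[subject_id]
        truth = row.to_dict()
    return SubjectData(subject_id, trials, eeg, truth)
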