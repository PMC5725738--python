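"""Single-trial EEG decoding with sliding-window regularised LDA.

At each window onset t (5 ms steps, 24-600 ms by default) the 64-channel
EEG is averaged over [t, t + 55) ms and projected onto a discriminant
direction

    Y(t) = W(t) . X(t) + C,

where W solves the shrinkage-regularised Fisher problem
Sigma_hat w = m1 - m0 with Sigma_hat = (1 - gamma) S + gamma nu I
(nu = trace(S)/p), and C centres Y at the class midpoint.  The classifier
is trained to separate trials with event rates above vs below the 11 Hz
standard using *congruent* audio-visual trials only (so neither modality's
conflict drives the weights) and then applied to all trials at the same
time point, producing a trials x time "sensory matrix" of single-trial
evidence.  Scalp patterns for the component are recovered with the forward
model: the normalised (Pearson) correlation between Y and each channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import ledoit_wolf
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .synthetic_data import EpochedEEG

WINDOW_MS = 55.0
STEP_MS = 5.0
DECODE_SPAN_MS = (24.0, 600.0)
NEURAL_WEIGHT_SPAN_MS = (24.0, 400.0)


def decode_time_grid(
    span: tuple[float, float] = DECODE_SPAN_MS, step: float = STEP_MS
) -> np.ndarray:
    return np.arange(span[0], span[1] + step / 2, step)


@dataclass
class DiscriminantModel:
    """Spatial discriminant for one 55 ms window: Y = w.x_bar + c."""

    w: np.ndarray
    c: float
    t_onset: float
    window_ms: float = WINDOW_MS
    shrinkage: float = 0.0

    def project(self, xw: np.ndarray) -> np.ndarray:
        return xw @ self.w + self.c


@dataclass
class DiscriminantOutput:
    """Single-trial discriminant values: trials x time with trial metadata."""

    y: np.ndarray
    times: np.ndarray        # window onsets, ms
    trial_id: np.ndarray
    trained_on: np.ndarray   # trial ids used to fit the models


def window_mean(epochs: EpochedEEG, t_onset: float, window_ms: float = WINDOW_MS) -> np.ndarray:
    """Channel data averaged over [t_onset, t_onset + window) -> trials x channels."""
    mask = (epochs.times >= t_onset) & (epochs.times < t_onset + window_ms)
    if not mask.any():
        raise ValueError(f"window onset {t_onset} ms outside the epoch")
    return epochs.data[:, :, mask].mean(axis=2)


def _shrunk_cov(Xc: np.ndarray, shrinkage) -> tuple[np.ndarray, float]:
    """Within-class covariance with scalar-target shrinkage.

    ``shrinkage`` is either a float gamma in [0, 1] or "lw" for the
    analytic Ledoit-Wolf intensity.  Target is nu*I with nu = trace(S)/p.
    """
    n, p = Xc.shape
    if shrinkage == "lw":
        cov, gamma = ledoit_wolf(Xc, assume_centered=True)
        if gamma < 1e-6:   # keep the solve defined on rank-deficient data
            gamma = 1e-6
            S = Xc.T @ Xc / n
            cov = (1 - gamma) * S + gamma * (np.trace(S) / p) * np.eye(p)
        return cov, float(gamma)
    gamma = float(shrinkage)
    if not 0 <= gamma <= 1:
        raise ValueError("shrinkage gamma must lie in [0, 1]")
    S = Xc.T @ Xc / n
    nu = np.trace(S) / p
    return (1 - gamma) * S + gamma * nu * np.eye(p), gamma


def train_discriminant(
    epochs: EpochedEEG,
    labels: np.ndarray,
    t_onset: float,
    *,
    window_ms: float = WINDOW_MS,
    shrinkage="lw",
) -> DiscriminantModel:
    """Fit the regularised LDA direction for one time window.

    ``labels`` are binary (1 = event rate above the standard).  With
    gamma = 0 this is the plain Fisher discriminant and requires a
    full-rank within-class covariance; gamma = 1 reduces to the class-mean
    difference.
    """
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("need both classes (labels 0/1) to train")
    Xw = window_mean(epochs, t_onset, window_ms)
    m0 = Xw[labels == 0].mean(axis=0)
    m1 = Xw[labels == 1].mean(axis=0)
    Xc = np.concatenate([Xw[labels == 0] - m0, Xw[labels == 1] - m1])
    if np.allclose(Xw, 0):   # silent window (e.g. pre-response, noiseless data)
        return DiscriminantModel(w=np.zeros(Xw.shape[1]), c=0.0,
                                 t_onset=float(t_onset), window_ms=window_ms,
                                 shrinkage=1.0)
    cov, gamma = _shrunk_cov(Xc, shrinkage)
    try:
        w = np.linalg.solve(cov, m1 - m0)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "within-class covariance is singular; use shrinkage gamma > 0"
        ) from err
    if gamma == 0 and np.linalg.cond(cov) > 1e12:
        raise np.linalg.LinAlgError(
            "within-class covariance is rank deficient; use shrinkage gamma > 0"
        )
    c = -float(w @ (m0 + m1) / 2)
    return DiscriminantModel(w=w, c=c, t_onset=float(t_onset),
                             window_ms=window_ms, shrinkage=gamma)


def apply_discriminant(
    models: list[DiscriminantModel],
    epochs: EpochedEEG,
    *,
    trained_on: np.ndarray | None = None,
) -> DiscriminantOutput:
    """Project all trials through per-window models (same t, same model)."""
    p = len(epochs.channels)
    for m in models:
        if m.w.shape != (p,):
            raise ValueError("channel count mismatch between model and epochs")
    y = np.column_stack([
        m.project(window_mean(epochs, m.t_onset, m.window_ms)) for m in models
    ])
    times = np.array([m.t_onset for m in models])
    return DiscriminantOutput(
        y=y, times=times, trial_id=epochs.trial_id,
        trained_on=np.asarray(trained_on) if trained_on is not None else np.empty(0, int),
    )


def decode_subject(
    epochs: EpochedEEG,
    trials: pd.DataFrame,
    *,
    times: np.ndarray | None = None,
    window_ms: float = WINDOW_MS,
    shrinkage="lw",
) -> DiscriminantOutput:
    """Standard training scheme: fit on congruent AV trials, apply to all.

    Congruent audio-visual trials (delta = 0) with a defined high/low label
    (equal-rate trials excluded) train each window's model; the discriminant
    is then applied to every trial at the same time point.
    """
    times = decode_time_grid() if times is None else np.asarray(times, dtype=float)
    train_mask = (
        trials["modality"].isin(("AVH", "AVL"))
        & (trials["delta"] == 0)
        & trials["label"].notna()
    ).to_numpy()
    if train_mask.sum() < 10:
        raise ValueError("too few congruent labelled trials to train")
    labels = trials.loc[train_mask, "label"].astype(int).to_numpy()
    sub_epochs = EpochedEEG(
        data=epochs.data[train_mask], times=epochs.times,
        channels=epochs.channels, trial_id=epochs.trial_id[train_mask],
    )
    models = [
        train_discriminant(sub_epochs, labels, t, window_ms=window_ms, shrinkage=shrinkage)
        for t in times
    ]
    return apply_discriminant(models, epochs, trained_on=epochs.trial_id[train_mask])


def decoder_az(
    epochs: EpochedEEG,
    labels: np.ndarray,
    times: np.ndarray,
    *,
    k: int = 10,
    window_ms: float = WINDOW_MS,
    shrinkage="lw",
    rng: np.random.Generator | None = None,
    n_perm: int = 0,
    alpha: float = 0.01,
) -> dict:
    """Cross-validated decoder Az per time point, optionally with a
    max-statistic significance threshold from label permutations.

    Returns {"az": series, "threshold": float | None, "null_max": array}.
    With ``n_perm`` > 0 the labels are shuffled n_perm times, the CV Az
    series recomputed, and the (1 - alpha) quantile of the null max over
    time taken as the family-wise threshold.
    """
    import warnings

    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < 2:
        raise ValueError("need both classes")
    if counts.max() / counts.min() > 4:
        warnings.warn("classes unbalanced beyond 4:1; stratification enforced", stacklevel=2)
    if 0 < n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100 gives unstable thresholds", stacklevel=2)
    rng = rng or np.random.default_rng()
    Xw = np.stack([window_mean(epochs, t, window_ms) for t in times], axis=-1)

    def cv_az_series(lab: np.ndarray) -> np.ndarray:
        kk = min(k, np.bincount(lab, minlength=2).min())
        cv = StratifiedKFold(n_splits=kk, shuffle=True,
                             random_state=int(rng.integers(2**31)))
        az = np.empty(len(times))
        for i in range(len(times)):
            scores = np.empty(len(lab))
            X = Xw[:, :, i]
            for tr, te in cv.split(X, lab):
                sub = EpochedEEG(
                    data=X[tr][:, :, None], times=np.array([0.0]),
                    channels=epochs.channels, trial_id=epochs.trial_id[tr],
                )
                m = train_discriminant(sub, lab[tr], 0.0, window_ms=1.0, shrinkage=shrinkage)
                scores[te] = X[te] @ m.w + m.c
            az[i] = roc_auc_score(lab, scores)
        return az

    az = cv_az_series(labels)
    threshold = None
    null_max = np.empty(0)
    if n_perm > 0:
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            null_max[i] = cv_az_series(rng.permutation(labels)).max()
        threshold = float(np.quantile(null_max, 1 - alpha))
    return {"az": az, "times": times, "threshold": threshold, "null_max": null_max}


def forward_model(
    y: DiscriminantOutput,
    epochs: EpochedEEG,
    *,
    window_ms: float = WINDOW_MS,
) -> np.ndarray:
    """Forward-model scalp map of the discriminating component.

    Per channel and time, the correlation of Y with the windowed channel
    data across trials, normalised by the variance of Y:
    a = cov(x, y) / var(y) (equivalently X'y / y'y on centred data).  This
    is the activation-pattern estimate that recovers the generative mixing
    vector: a channel whose data equal Y gets a = 1.  Channels with zero
    variance are flagged NaN.
    """
    if len(y.trial_id) != len(epochs.trial_id) or np.any(y.trial_id != epochs.trial_id):
        raise ValueError("discriminant output and epochs must hold the same trials")
    n_ch = len(epochs.channels)
    a = np.full((n_ch, len(y.times)), np.nan)
    for i, t in enumerate(y.times):
        Xw = window_mean(epochs, t, window_ms)
        yv = y.y[:, i] - y.y[:, i].mean()
        Xc = Xw - Xw.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            a[:, i] = (Xc.T @ yv) / (yv @ yv)
        a[Xc.std(axis=0) == 0, i] = np.nan
    return a
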