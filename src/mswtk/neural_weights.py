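"""Neural sensory weights: regressing discriminant output on accumulated rates.

For every time point where the decoder carries rate information (24-400 ms
by default) the single-trial discriminant output Y(t) is regressed, on
cue-conflict audio-visual trials only, onto the accumulated auditory and
visual event counts at that time:

    Y(t) ~ b0 + b_aud * accA(t) + b_vis * accV(t),

separately for the high- and low-visual-reliability conditions.  This
yields four unnormalised neural weights per time point (AVH-aud, AVH-vis,
AVL-aud, AVL-vis); unlike the behavioural weights they are *not*
constrained to sum to one, since the neural generators of the auditory and
visual contributions need not share a scale.  Predictors are z-scored per
time point, so b is in discriminant units per SD of accumulated evidence.
The neural reliability influence applies the same contrast as the
behavioural one, and the neuro-behavioural correlation relates the two
across subjects at each time point with cluster-corrected significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoding import NEURAL_WEIGHT_SPAN_MS, DiscriminantOutput
from .perceptual_weights import CONDITIONS, _acc_matrix, resample_to_grid
from .stats_inference import ClusterParams, ClusterResult, correlation_cluster

_COND_NUMBER_RIDGE = 1e6


@dataclass
class NeuralWeightSeries:
    """Unnormalised per-condition regression weights on the neural time grid."""

    times: np.ndarray
    b: dict[str, np.ndarray]     # keys: AVH-aud, AVH-vis, AVL-aud, AVL-vis
    se: dict[str, np.ndarray]

    def to_frame(self, subject_id: int | None = None) -> pd.DataFrame:
        rows = []
        for cond in self.b:
            for i, t in enumerate(self.times):
                rows.append({
                    "subject_id": subject_id, "condition": cond,
                    "time_ms": t, "b": self.b[cond][i], "se": self.se[cond][i],
                })
        return pd.DataFrame(rows)


def _ols(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS with intercept; ridge fallback if badly conditioned."""
    X = np.column_stack([np.ones(len(y)), Z])
    XtX = X.T @ X
    if np.linalg.cond(XtX) > _COND_NUMBER_RIDGE:
        XtX = XtX + 1e-6 * np.trace(XtX) / XtX.shape[0] * np.eye(XtX.shape[0])
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta[1:], se[1:]


def neural_weight_regression(
    y: DiscriminantOutput,
    trials: pd.DataFrame,
    *,
    window: tuple[float, float] = NEURAL_WEIGHT_SPAN_MS,
    standardize_y: bool = True,
) -> NeuralWeightSeries:
    """Per-condition OLS of Y on accumulated rates over the analysis window.

    ``trials`` must align with ``y.trial_id``; only incongruent
    (delta = +/-2) audio-visual trials enter the regression.  Collinear or
    constant predictors at a time point are flagged NaN.

    The raw discriminant scale is arbitrary (it depends on the shrinkage
    solve), so by default Y is standardised across the incongruent trials
    at each time point before regressing.  This is a single scale factor
    shared by both reliability conditions, so within-subject contrasts are
    unaffected while weights become comparable across subjects.
    """
    trials = trials.set_index("trial_id").loc[y.trial_id].reset_index()
    keep = (y.times >= window[0]) & (y.times <= window[1])
    times = y.times[keep]
    ymat = y.y[:, keep]
    inc_mask = (trials["modality"].isin(("AVH", "AVL")) & (trials["delta"] != 0)).to_numpy()
    if standardize_y:
        sd = ymat[inc_mask].std(axis=0)
        ymat = ymat / np.where(sd > 0, sd, 1.0)

    b = {c: np.full(len(times), np.nan) for c in CONDITIONS}
    se = {c: np.full(len(times), np.nan) for c in CONDITIONS}
    for rel, tag in (("high", "AVH"), ("low", "AVL")):
        mask = inc_mask & (trials["reliability"] == rel).to_numpy()
        if mask.sum() < 8:
            raise ValueError(f"too few incongruent {tag} trials for regression")
        sub = trials[mask]
        acc_a, acc_v = _acc_matrix(sub, times)
        ysub = ymat[mask]
        for i in range(len(times)):
            X = np.column_stack([acc_a[:, i], acc_v[:, i]])
            sd = X.std(axis=0)
            if np.any(sd < 1e-12):
                continue
            Z = (X - X.mean(axis=0)) / sd
            r = np.corrcoef(Z.T)[0, 1]
            if abs(r) > 0.9999:
                continue
            (b_a, b_v), (se_a, se_v) = _ols(Z, ysub[:, i])
            b[f"{tag}-aud"][i], b[f"{tag}-vis"][i] = b_a, b_v
            se[f"{tag}-aud"][i], se[f"{tag}-vis"][i] = se_a, se_v
    return NeuralWeightSeries(times, b, se)


def neural_reliability_influence(nw: NeuralWeightSeries) -> np.ndarray:
    """D(t) = [b_aud - b_vis](AVH) - [b_aud - b_vis](AVL) on raw weights."""
    return (nw.b["AVH-aud"] - nw.b["AVH-vis"]) - (nw.b["AVL-aud"] - nw.b["AVL-vis"])


def neural_reliability_influence_matrix(nw_list: list[NeuralWeightSeries]) -> np.ndarray:
    return np.stack([neural_reliability_influence(nw) for nw in nw_list])


def neuro_behavioral_correlation(
    d_neural: np.ndarray,
    d_perceptual: np.ndarray,
    *,
    neural_times: np.ndarray,
    perceptual_times: np.ndarray | None = None,
    params: ClusterParams = ClusterParams(),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, ClusterResult]:
    """Across-subject Spearman correlation of neural vs perceptual
    reliability influences per time point, cluster-corrected.

    ``d_neural`` is subjects x neural-time; ``d_perceptual`` is either a
    per-subject scalar, or subjects x perceptual-time in which case it is
    nearest-neighbour resampled onto the neural grid.
    """
    d_neural = np.asarray(d_neural, dtype=float)
    n_sub, n_time = d_neural.shape
    if n_sub < 5:
        raise ValueError("need >= 5 subjects")
    d_perceptual = np.asarray(d_perceptual, dtype=float)
    if d_perceptual.ndim == 1:
        d_b = np.repeat(d_perceptual[:, None], n_time, axis=1)
    else:
        if perceptual_times is None:
            raise ValueError("perceptual_times required for a time-resolved series")
        d_b = resample_to_grid(d_perceptual, perceptual_times, neural_times)
    rho, result = correlation_cluster(
        d_neural, d_b, times=neural_times, params=params, rng=rng
    )
    return rho, result
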