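"""Time-resolved perceptual weights from accumulated sensory evidence.

At each time point t the accumulated auditory and visual event counts on
cue-conflict (delta = +/-2) audio-visual trials are regressed against the
behavioural choice with a logistic model

    P(choice = "first higher") = logistic(b0 + b_aud * accA(t) + b_vis * accV(t)),

fit separately per visual-reliability condition on a 12 ms grid from 24 to
600 ms (earlier points hold no events, later points make the two
accumulated counts nearly collinear).  Predictors are z-scored within time
point across trials, so coefficients are comparable over time.  Model
performance is the cross-validated area under the ROC (Az); the
reliability influence D(t) contrasts the auditory-visual weight asymmetry
across reliability conditions:

    D(t) = [w_aud - w_vis](high) - [w_aud - w_vis](low).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .stimgen import accumulated_counts, onsets_from_json

BEHAV_WINDOW_MS = (24, 600)
BEHAV_STEP_MS = 12
RIDGE = 1e-6         # L2 intensity for numerical stability near collinearity
CONDITIONS = ("AVH-aud", "AVH-vis", "AVL-aud", "AVL-vis")


def behaviour_time_grid(window: tuple[float, float] = BEHAV_WINDOW_MS) -> np.ndarray:
    return np.arange(window[0], window[1] + 1, BEHAV_STEP_MS, dtype=float)


@dataclass
class WeightSeries:
    """Per-time-point weights for the four reliability x modality series.

    ``beta`` holds the raw logistic coefficients; ``w`` the normalised
    weights w_aud = b_aud / (b_aud + b_vis) where both coefficients are
    positive (``normalized`` flags those time points), raw coefficients
    elsewhere.  ``az`` is the cross-validated ROC area per reliability.
    """

    times: np.ndarray
    beta: dict[str, np.ndarray]
    w: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray] = field(default_factory=dict)
    az: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self, subject_id: int | None = None) -> pd.DataFrame:
        rows = []
        for cond in self.beta:
            for i, t in enumerate(self.times):
                rows.append({
                    "subject_id": subject_id, "condition": cond, "time_ms": t,
                    "beta": self.beta[cond][i], "weight": self.w[cond][i],
                })
        return pd.DataFrame(rows)


def _zscore_cols(X: np.ndarray) -> np.ndarray | None:
    """Column z-score; None if any column is (near-)degenerate."""
    sd = X.std(axis=0)
    if np.any(sd < 1e-12):
        return None
    Z = (X - X.mean(axis=0)) / sd
    r = np.corrcoef(Z.T)
    if Z.shape[1] > 1 and np.any(np.abs(r[np.triu_indices_from(r, 1)]) > 0.9999):
        return None
    return Z


def _logistic(Z: np.ndarray, y: np.ndarray, ridge: float = RIDGE) -> np.ndarray:
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000)
    clf.fit(Z, y)
    return clf.coef_[0]


def accumulated_design(
    trials: pd.DataFrame, t: float
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulated auditory/visual counts at time t for each trial (ms)."""
    acc_a = np.array([
        accumulated_counts(onsets_from_json(s), [t])[0] for s in trials["onsets_aud"]
    ])
    acc_v = np.array([
        accumulated_counts(onsets_from_json(s), [t])[0] for s in trials["onsets_vis"]
    ])
    return acc_a, acc_v


def _acc_matrix(trials: pd.DataFrame, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(trials x times) accumulated counts for both modalities at once."""
    acc_a = np.stack([
        accumulated_counts(onsets_from_json(s), times) for s in trials["onsets_aud"]
    ])
    acc_v = np.stack([
        accumulated_counts(onsets_from_json(s), times) for s in trials["onsets_vis"]
    ])
    return acc_a, acc_v


def time_resolved_weights(
    trials: pd.DataFrame,
    *,
    times: np.ndarray | None = None,
    compute_az: bool = False,
    az_folds: int = 10,
    rng: np.random.Generator | None = None,
) -> WeightSeries:
    """Fit the time-resolved logistic evidence model for one subject.

    Uses only incongruent (delta = +/-2) audio-visual trials with recorded
    choices; both reliability conditions must be present.  Degenerate
    designs at a time point (constant or collinear accumulated counts)
    yield NaN there rather than aborting.
    """
    times = behaviour_time_grid() if times is None else np.asarray(times, dtype=float)
    av = trials[(trials["modality"].isin(("AVH", "AVL"))) & (trials["delta"] != 0)]
    av = av.dropna(subset=["choice"])
    rels = set(av["reliability"])
    if not {"high", "low"} <= rels:
        raise ValueError("need incongruent AV trials at both reliabilities")

    beta = {c: np.full(len(times), np.nan) for c in CONDITIONS}
    w = {c: np.full(len(times), np.nan) for c in CONDITIONS}
    normalized = {rel: np.zeros(len(times), dtype=bool) for rel in ("high", "low")}
    az = {rel: np.full(len(times), np.nan) for rel in ("high", "low")}

    for rel, tag in (("high", "AVH"), ("low", "AVL")):
        sub = av[av["reliability"] == rel]
        y = sub["choice"].astype(int).to_numpy()
        acc_a, acc_v = _acc_matrix(sub, times)
        for i in range(len(times)):
            Z = _zscore_cols(np.column_stack([acc_a[:, i], acc_v[:, i]]))
            if Z is None or y.min() == y.max():
                continue
            b_a, b_v = _logistic(Z, y)
            beta[f"{tag}-aud"][i], beta[f"{tag}-vis"][i] = b_a, b_v
            # sign-robust normalisation: equals b/(b_a+b_v) when both are
            # positive (flagged), stays defined and scale-free otherwise
            denom = abs(b_a) + abs(b_v)
            if denom > 0:
                w[f"{tag}-aud"][i] = b_a / denom
                w[f"{tag}-vis"][i] = b_v / denom
                normalized[rel][i] = b_a > 0 and b_v > 0
            if compute_az:
                az[rel][i] = model_az(Z, y, k=az_folds, rng=rng)
    return WeightSeries(times, beta, w, normalized, az)


def model_az(
    X: np.ndarray,
    y: np.ndarray,
    *,
    k: int = 10,
    rng: np.random.Generator | None = None,
    ridge: float = RIDGE,
) -> float:
    """Cross-validated ROC area of the logistic evidence model.

    Stratified k-fold; held-out predicted probabilities are pooled across
    folds before computing the ROC area.
    """
    y = np.asarray(y, dtype=int)
    n_min = np.bincount(y, minlength=2).min()
    if n_min < k:
        if n_min < 2:
            raise ValueError("need both classes with >= 2 trials each")
        k = int(n_min)   # re-stratify with fewer folds
    seed = int(rng.integers(2**31)) if rng is not None else None
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for tr, te in cv.split(X, y):
        clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000)
        clf.fit(X[tr], y[tr])
        scores[te] = clf.predict_proba(X[te])[:, 1]
    return float(roc_auc_score(y, scores))


def trial_az_series(
    trials: pd.DataFrame,
    *,
    times: np.ndarray | None = None,
    k: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Az of the joint evidence model over time, pooled across reliabilities."""
    times = behaviour_time_grid() if times is None else np.asarray(times, dtype=float)
    av = trials[(trials["modality"].isin(("AVH", "AVL"))) & (trials["delta"] != 0)]
    av = av.dropna(subset=["choice"])
    y = av["choice"].astype(int).to_numpy()
    acc_a, acc_v = _acc_matrix(av, times)
    az = np.full(len(times), np.nan)
    for i in range(len(times)):
        Z = _zscore_cols(np.column_stack([acc_a[:, i], acc_v[:, i]]))
        if Z is None:
            continue
        az[i] = model_az(Z, y, k=k, rng=rng)
    return times, az


def reliability_influence(ws: WeightSeries) -> np.ndarray:
    """D(t) = [w_aud - w_vis](AVH) - [w_aud - w_vis](AVL); NaN propagates."""
    return (ws.w["AVH-aud"] - ws.w["AVH-vis"]) - (ws.w["AVL-aud"] - ws.w["AVL-vis"])


def reliability_influence_matrix(weight_list: list[WeightSeries]) -> np.ndarray:
    """Stack D(t) over subjects into a subject x time array."""
    return np.stack([reliability_influence(ws) for ws in weight_list])


def weight_correlation(
    d_regression: np.ndarray,
    d_psychometric: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Across-subject Spearman correlation of reliability influences per time.

    ``d_regression`` is subject x time; ``d_psychometric`` is a per-subject
    scalar (or subject x time array).  Undefined correlations (constant
    input) come back as NaN.
    """
    from .stats_inference import spearman

    d_regression = np.asarray(d_regression, dtype=float)
    d_psychometric = np.asarray(d_psychometric, dtype=float)
    n_sub, n_time = d_regression.shape
    if n_sub < 5:
        raise ValueError("need >= 5 subjects")
    if d_psychometric.ndim == 1:
        d_psychometric = np.repeat(d_psychometric[:, None], n_time, axis=1)
    rho = np.full(n_time, np.nan)
    p = np.full(n_time, np.nan)
    for i in range(n_time):
        x, y = d_regression[:, i], d_psychometric[:, i]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 5 or np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
            continue
        rho[i], p[i] = spearman(x[ok], y[ok])
    return rho, p


def resample_to_grid(values: np.ndarray, times: np.ndarray, new_times: np.ndarray) -> np.ndarray:
    """Nearest-neighbour resampling of a (.., time) array onto a new ms grid."""
    idx = np.abs(np.subtract.outer(np.asarray(new_times, float), np.asarray(times, float))).argmin(axis=1)
    return np.asarray(values)[..., idx]
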