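"""Psychometric curve fitting and perceptual-weight estimation.

Performance on the rate-discrimination task is summarised per condition by
a cumulative-Gaussian psychometric function

    P("first higher" | rate r) = lambda + (1 - 2*lambda) * Phi((r - mu) / sigma)

whose PSE (mu) and threshold (sigma) feed two weight estimates:

* the *predicted* auditory weight a statistically optimal observer would
  use, from unisensory thresholds:  w = (1/sigma_aud^2) / (1/sigma_aud^2 +
  1/sigma_vis^2);
* the *observed* auditory weight, from PSE shifts on audio-visual
  cue-conflict trials:  w = (mu_AV(delta) - mu_AV(0) + delta/2) / delta,
  averaged over the two conflict levels delta = +/-2.

Auditory and visual weights are taken to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

DEFAULT_N_BOOT = 2000
DEFAULT_LAPSE = 0.01
_SIGMA_MIN = 0.05
_SIGMA_MAX = 100.0


@dataclass
class PsychometricFit:
    """Cumulative-Gaussian fit with nonparametric bootstrap uncertainty."""

    mu: float
    sigma: float
    lapse: float
    n_per_rate: dict[float, int]
    boot_mu: np.ndarray
    boot_sigma: np.ndarray
    separable: bool = False      # sigma pinned at its lower bound
    condition: str | None = None

    def ci(self, which: str = "mu", level: float = 0.95) -> tuple[float, float]:
        boot = self.boot_mu if which == "mu" else self.boot_sigma
        if boot.size == 0:
            return (np.nan, np.nan)
        lo, hi = np.quantile(boot, [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)

    def predict(self, rates) -> np.ndarray:
        r = np.asarray(rates, dtype=float)
        return self.lapse + (1 - 2 * self.lapse) * norm.cdf((r - self.mu) / self.sigma)


def _nll(params, rates, k, n, lapse):
    mu, log_sigma = params
    sigma = np.exp(log_sigma)
    p = lapse + (1 - 2 * lapse) * norm.cdf((rates - mu) / sigma)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))


def _fit_once(rates, k, n, lapse, mu0, sigma0):
    res = minimize(
        _nll, x0=[mu0, np.log(sigma0)], args=(rates, k, n, lapse),
        method="L-BFGS-B",
        bounds=[(rates.min() - 20, rates.max() + 20),
                (np.log(_SIGMA_MIN), np.log(_SIGMA_MAX))],
    )
    return float(res.x[0]), float(np.exp(res.x[1]))


def fit_psychometric(
    rates,
    choices,
    *,
    n_boot: int = DEFAULT_N_BOOT,
    lapse: float = DEFAULT_LAPSE,
    rng: np.random.Generator | None = None,
    condition: str | None = None,
) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit to binary choice data.

    ``rates`` are the per-trial comparison rates in Hz; ``choices`` the
    binary "first stream higher" responses.  The lapse rate is held fixed
    (default 0.01).  Uncertainty comes from a nonparametric bootstrap over
    trials (default 2000 resamples).  Perfect separation is flagged via
    ``separable`` (sigma pinned to its lower bound by the box constraint).
    """
    rates = np.asarray(rates, dtype=float)
    choices = np.asarray(choices, dtype=float)
    if rates.shape != choices.shape:
        raise ValueError("rates and choices must align")
    uniq = np.unique(rates)
    if len(uniq) < 2:
        raise ValueError("need >= 2 distinct rates to fit a psychometric curve")
    if choices.min() == choices.max():
        raise ValueError("need both choice outcomes present")

    def aggregate(r, c):
        u, inv = np.unique(r, return_inverse=True)
        k = np.bincount(inv, weights=c)
        n = np.bincount(inv).astype(float)
        return u, k, n

    u, k, n = aggregate(rates, choices)
    mu0 = float(np.average(u, weights=n))
    sigma0 = max(float(np.std(rates)), 0.5)
    mu, sigma = _fit_once(u, k, n, lapse, mu0, sigma0)
    separable = sigma <= _SIGMA_MIN * (1 + 1e-6)

    rng = rng or np.random.default_rng()
    boot_mu = np.empty(n_boot)
    boot_sigma = np.empty(n_boot)
    idx_all = np.arange(len(rates))
    for b in range(n_boot):
        idx = rng.choice(idx_all, size=len(idx_all), replace=True)
        rb, cb = rates[idx], choices[idx]
        if cb.min() == cb.max() or len(np.unique(rb)) < 2:
            boot_mu[b], boot_sigma[b] = np.nan, np.nan
            continue
        ub, kb, nb = aggregate(rb, cb)
        boot_mu[b], boot_sigma[b] = _fit_once(ub, kb, nb, lapse, mu, sigma)
    return PsychometricFit(
        mu=mu, sigma=sigma, lapse=lapse,
        n_per_rate={float(r): int(c) for r, c in zip(u, n)},
        boot_mu=boot_mu[np.isfinite(boot_mu)],
        boot_sigma=boot_sigma[np.isfinite(boot_sigma)],
        separable=separable, condition=condition,
    )


def predicted_weight(sigma_aud: float, sigma_vis: float) -> float:
    """Optimal auditory weight from unisensory thresholds (reliability ratio)."""
    if sigma_aud <= 0 or sigma_vis <= 0:
        raise ValueError("thresholds must be > 0")
    ja, jv = 1 / sigma_aud**2, 1 / sigma_vis**2
    return ja / (ja + jv)


def observed_weight(mu_delta: float, mu_congruent: float, delta: float) -> float:
    """Auditory weight from the PSE shift on cue-conflict trials.

    w = (mu_AV(delta) - mu_AV(0) + delta/2) / delta, undefined at delta = 0.
    """
    if delta == 0:
        raise ValueError("observed weight undefined at delta = 0")
    return (mu_delta - mu_congruent + delta / 2) / delta


@dataclass
class PerceptualWeights:
    """Predicted and observed auditory weights for one reliability condition."""

    w_aud_pred: float
    w_aud_obs_per_delta: dict[int, float]
    condition: str | None = None

    @property
    def w_aud_obs(self) -> float:
        return float(np.mean(list(self.w_aud_obs_per_delta.values())))

    @property
    def w_vis_pred(self) -> float:
        return 1 - self.w_aud_pred

    @property
    def w_vis_obs(self) -> float:
        return 1 - self.w_aud_obs


def perceptual_weights(
    sigma_aud: float,
    sigma_vis: float,
    mu_by_delta: dict[int, float],
    *,
    condition: str | None = None,
) -> PerceptualWeights:
    """Combine unisensory thresholds and AV PSEs into one weight summary.

    ``mu_by_delta`` maps conflict level (0, +2, -2) to the fitted AV PSE.
    The observed weight averages the two conflict levels.
    """
    if 0 not in mu_by_delta:
        raise ValueError("need the congruent (delta=0) PSE")
    per_delta = {
        int(d): observed_weight(mu, mu_by_delta[0], d)
        for d, mu in mu_by_delta.items() if d != 0
    }
    if not per_delta:
        raise ValueError("need at least one conflict-level PSE")
    return PerceptualWeights(
        w_aud_pred=predicted_weight(sigma_aud, sigma_vis),
        w_aud_obs_per_delta=per_delta,
        condition=condition,
    )


def subject_psychometrics(
    trials: pd.DataFrame,
    *,
    n_boot: int = DEFAULT_N_BOOT,
    lapse: float = DEFAULT_LAPSE,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fit every condition of one subject's trial table.

    Returns a tidy frame (condition, modality, reliability, delta, mu,
    sigma, CI bounds, n) using the nominal/average rate as the x-axis.
    """
    rng = rng or np.random.default_rng()
    rows = []
    for cond, sub in trials.groupby("condition"):
        sub = sub.dropna(subset=["choice"])
        fit = fit_psychometric(
            sub["rate"], sub["choice"].astype(int),
            n_boot=n_boot, lapse=lapse, rng=rng, condition=cond,
        )
        lo_m, hi_m = fit.ci("mu")
        lo_s, hi_s = fit.ci("sigma")
        rows.append({
            "condition": cond,
            "modality": sub["modality"].iloc[0],
            "reliability": sub["reliability"].iloc[0],
            "delta": sub["delta"].iloc[0],
            "mu": fit.mu, "mu_lo": lo_m, "mu_hi": hi_m,
            "sigma": fit.sigma, "sigma_lo": lo_s, "sigma_hi": hi_s,
            "n": len(sub), "separable": fit.separable,
        })
    return pd.DataFrame(rows)


def weights_from_condition_fits(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-reliability predicted/observed weights from a condition-fit table.

    Expects the 9-condition layout (AUD, VH, VL and AV deltas 0/+2/-2 for
    each reliability).  Returns one row per reliability with predicted and
    observed auditory weights and the psychometric reliability influence
    contribution (w_aud - w_vis = 2*w_aud - 1).
    """
    fits = fits.set_index("condition")
    sigma_aud = fits.loc["AUD", "sigma"]
    rows = []
    for rel, mod, vis in (("high", "AVH", "VH"), ("low", "AVL", "VL")):
        mu_by_delta = {
            0: fits.loc[f"{mod}_d0", "mu"],
            2: fits.loc[f"{mod}_d+2", "mu"],
            -2: fits.loc[f"{mod}_d-2", "mu"],
        }
        pw = perceptual_weights(
            sigma_aud, fits.loc[vis, "sigma"], mu_by_delta, condition=mod
        )
        rows.append({
            "reliability": rel, "condition": mod,
            "w_aud_pred": pw.w_aud_pred, "w_aud_obs": pw.w_aud_obs,
            "w_aud_obs_dpos": pw.w_aud_obs_per_delta[2],
            "w_aud_obs_dneg": pw.w_aud_obs_per_delta[-2],
        })
    return pd.DataFrame(rows)


def observed_weights_by_reliability(fits: pd.DataFrame) -> dict[str, float]:
    """Observed auditory weight per reliability from AV condition fits only.

    Needs the six audio-visual cells (AVH/AVL x delta 0,+2,-2); does not
    require unisensory fits (those only enter the *predicted* weights).
    """
    fits = fits.set_index("condition")
    out = {}
    for rel, mod in (("high", "AVH"), ("low", "AVL")):
        mu0 = fits.loc[f"{mod}_d0", "mu"]
        w = np.mean([
            observed_weight(fits.loc[f"{mod}_d+2", "mu"], mu0, 2),
            observed_weight(fits.loc[f"{mod}_d-2", "mu"], mu0, -2),
        ])
        out[rel] = float(w)
    return out


def psychometric_reliability_influence(weights: pd.DataFrame, kind: str = "obs") -> float:
    """Scalar reliability influence from psychometric weights.

    D = (w_aud - w_vis)_high - (w_aud - w_vis)_low = 2*(w_high - w_low)
    with w_vis = 1 - w_aud.
    """
    col = f"w_aud_{kind}"
    w = weights.set_index("reliability")[col]
    return float(2 * (w["high"] - w["low"]))


def select_reliability_levels(
    snr_grid,
    performance_per_snr,
    auditory_performance: float,
    *,
    drop: float = 0.30,
    guess: float = 0.5,
) -> tuple[float, float]:
    """Pick high/low visual SNR levels from a calibration performance curve.

    Fits proportion-correct vs SNR with a guessing-floor cumulative
    Gaussian p(s) = guess + (1-guess)*Phi((s-mu)/sigma) and inverts it
    analytically: the high-reliability SNR matches auditory performance,
    the low-reliability SNR sits ``drop`` (default 30 percentage points)
    below it.  Raises if a target lies outside the achievable range.
    """
    s = np.asarray(snr_grid, dtype=float)
    p = np.asarray(performance_per_snr, dtype=float)
    if s.shape != p.shape or len(s) < 3:
        raise ValueError("need matching SNR/performance arrays, >= 3 points")

    def nll(params):
        mu, log_sigma = params
        q = guess + (1 - guess) * norm.cdf((s - mu) / np.exp(log_sigma))
        q = np.clip(q, 1e-9, 1 - 1e-9)
        return -np.sum(p * np.log(q) + (1 - p) * np.log1p(-q))

    res = minimize(nll, x0=[np.median(s), np.log(np.ptp(s) / 4 + 1e-3)], method="Nelder-Mead")
    mu, sigma = res.x[0], float(np.exp(res.x[1]))

    def invert(target: float) -> float:
        if not guess < target < 1.0:
            raise ValueError(
                f"target performance {target:.3f} outside achievable range "
                f"({guess:.2f}, 1.0)"
            )
        return float(mu + sigma * norm.ppf((target - guess) / (1 - guess)))

    return invert(auditory_performance), invert(auditory_performance - drop)
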