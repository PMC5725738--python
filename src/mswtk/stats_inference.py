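"""Nonparametric group statistics for paired time series.

Implements the inference toolkit used throughout the pipeline:

* cluster-based permutation tests on paired subject x time series
  (pointwise paired t, fixed cluster-forming threshold |t| > 1.8, minimum
  cluster size 2, cluster statistic = cluster *size*, null = permutation
  distribution of the maximum cluster size under within-subject condition
  sign flips, 1000 randomisations by default);
* the same machinery for across-subject correlation time series (subject
  permutation instead of sign flips);
* max-statistic family-wise thresholds for arbitrary statistics over time;
* two-sided Wilcoxon signed-rank with the normal-approximation Z and the
  effect size r = Z / sqrt(N), N counting observations;
* Spearman rank correlation.

Permutation p-values carry the +1 correction and are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class ClusterParams:
    t_threshold: float = 1.8
    min_size: int = 2
    n_perm: int = 1000
    statistic: str = "max-size"
    tail: str = "two-sided"


@dataclass(frozen=True)
class Cluster:
    t_start: float
    t_end: float
    stat: float
    p_value: float
    sign: int


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_values: np.ndarray
    times: np.ndarray
    params: ClusterParams
    null_max: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]

    def to_dict(self) -> dict:
        return {
            "params": vars(self.params) | {},
            "clusters": [
                {"t_start": c.t_start, "t_end": c.t_end, "size": c.stat,
                 "p_value": c.p_value, "sign": c.sign}
                for c in self.clusters
            ],
        }


def _paired_t(d: np.ndarray) -> np.ndarray:
    """Columnwise one-sample t on difference scores; NaN -> 0 (no cluster)."""
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def _find_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs, stop exclusive."""
    out = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for a, b in zip(idx[::2], idx[1::2]):
        out.append((int(a), int(b)))
    return out


def _clusters_from_t(t: np.ndarray, thr: float, min_size: int) -> list[tuple[int, int, int]]:
    """Supra-threshold runs of consistent sign: (start, stop, sign)."""
    out = []
    for sign in (1, -1):
        for a, b in _find_runs(sign * t > thr):
            if b - a >= min_size:
                out.append((a, b, sign))
    return sorted(out)


def _max_cluster_sizes(t_mat: np.ndarray, thr: float, min_size: int) -> np.ndarray:
    """Per row of a (n_perm x time) t matrix, the largest cluster size."""
    out = np.zeros(t_mat.shape[0])
    for i, t in enumerate(t_mat):
        sizes = [b - a for a, b, _ in _clusters_from_t(t, thr, min_size)]
        out[i] = max(sizes, default=0)
    return out


def cluster_permutation(
    a: np.ndarray,
    b: np.ndarray | None,
    *,
    times: np.ndarray | None = None,
    params: ClusterParams = ClusterParams(),
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Paired cluster-based permutation test between two subject x time series.

    Passing ``b=None`` tests ``a`` against zero.  The null shuffles the
    condition assignment within subject (sign flips of the paired
    difference), each flip applied to the whole time course.  Cluster
    p-values are (1 + #{null max size >= observed size}) / (1 + n_perm).
    NaN time points are treated as sub-threshold so isolated undefined
    estimates break clusters rather than abort the test.
    """
    a = np.asarray(a, dtype=float)
    d = a if b is None else a - np.asarray(b, dtype=float)
    if d.ndim != 2:
        raise ValueError("expected subject x time arrays")
    n_sub, n_time = d.shape
    if n_sub < 5:
        raise ValueError("need >= 5 subjects for the permutation null")
    times = np.arange(n_time, dtype=float) if times is None else np.asarray(times, dtype=float)

    t_obs = _paired_t(d)
    obs = _clusters_from_t(t_obs, params.t_threshold, params.min_size)

    rng = rng or np.random.default_rng()
    signs = rng.integers(0, 2, size=(params.n_perm, n_sub)) * 2 - 1
    # vectorised sign-flip t: mean of s_i*d_i and second moment of d are enough
    nan_cols = ~np.all(np.isfinite(d), axis=0)
    m2 = np.mean(np.nan_to_num(d) ** 2, axis=0)
    m2[nan_cols] = 0.0          # NaN columns carry no signal under the null
    d0 = np.nan_to_num(d)
    d0[:, nan_cols] = 0.0
    mean_p = signs @ d0 / n_sub
    var_p = (m2[None, :] - mean_p**2) * n_sub / (n_sub - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = mean_p / np.sqrt(var_p / n_sub)
    t_perm = np.where(np.isfinite(t_perm), t_perm, 0.0)
    null_max = _max_cluster_sizes(t_perm, params.t_threshold, params.min_size)

    clusters = [
        Cluster(
            t_start=float(times[a0]), t_end=float(times[b0 - 1]),
            stat=float(b0 - a0),
            p_value=float((1 + np.sum(null_max >= (b0 - a0))) / (1 + params.n_perm)),
            sign=s,
        )
        for a0, b0, s in obs
    ]
    return ClusterResult(clusters, t_obs, times, params, null_max)


def _corr_t_series(x: np.ndarray, y: np.ndarray, method: str) -> np.ndarray:
    """Across-subject correlation per time point, mapped to a t statistic."""
    n, n_time = x.shape
    if method == "spearman":
        xr = np.apply_along_axis(sps.rankdata, 0, x)
        yr = np.apply_along_axis(sps.rankdata, 0, y)
    else:
        xr, yr = x, y
    xr = xr - xr.mean(axis=0)
    yr = yr - yr.mean(axis=0)
    denom = np.sqrt((xr**2).sum(axis=0) * (yr**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (xr * yr).sum(axis=0) / denom
        rho = np.clip(rho, -0.999999, 0.999999)
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return np.where(np.isfinite(t), t, 0.0), np.where(np.isfinite(rho), rho, np.nan)


def correlation_cluster(
    x: np.ndarray,
    y: np.ndarray,
    *,
    times: np.ndarray | None = None,
    params: ClusterParams = ClusterParams(),
    method: str = "spearman",
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, ClusterResult]:
    """Cluster test on the across-subject correlation of two time series.

    The pointwise statistic is the (Spearman by default) correlation across
    subjects, converted to a t value; the null permutes the subject order
    of ``y`` (one permutation per randomisation, shared over time, which
    preserves each series' temporal autocorrelation).  Returns the rho
    series and the cluster result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("expected matching subject x time arrays")
    n_sub, n_time = x.shape
    if n_sub < 5:
        raise ValueError("need >= 5 subjects")
    times = np.arange(n_time, dtype=float) if times is None else np.asarray(times, dtype=float)

    t_obs, rho = _corr_t_series(x, y, method)
    obs = _clusters_from_t(t_obs, params.t_threshold, params.min_size)

    rng = rng or np.random.default_rng()
    null_max = np.zeros(params.n_perm)
    for i in range(params.n_perm):
        perm = rng.permutation(n_sub)
        t_p, _ = _corr_t_series(x, y[perm], method)
        sizes = [b - a for a, b, _ in _clusters_from_t(t_p, params.t_threshold, params.min_size)]
        null_max[i] = max(sizes, default=0)

    clusters = [
        Cluster(
            t_start=float(times[a0]), t_end=float(times[b0 - 1]),
            stat=float(b0 - a0),
            p_value=float((1 + np.sum(null_max >= (b0 - a0))) / (1 + params.n_perm)),
            sign=s,
        )
        for a0, b0, s in obs
    ]
    return rho, ClusterResult(clusters, t_obs, times, params, null_max)


def max_stat_threshold(
    shuffler: Callable[[np.random.Generator], np.ndarray],
    *,
    n_perm: int = 2000,
    alpha: float = 0.01,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """Family-wise threshold from the permutation distribution of the max.

    ``shuffler(rng)`` must recompute the statistic's time course under one
    random relabelling of the data; the threshold is the (1 - alpha)
    quantile of the null maximum over time.  Returns (threshold, null max
    distribution).
    """
    import warnings

    if n_perm * alpha < 5:
        warnings.warn(
            f"n_perm*alpha = {n_perm * alpha:.1f} < 5: tail quantile is unstable",
            stacklevel=2,
        )
    rng = rng or np.random.default_rng()
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.nanmax(shuffler(rng))
    return float(np.quantile(null, 1 - alpha)), null


def wilcoxon_effect(x, y=None) -> tuple[float, float, float]:
    """Two-sided Wilcoxon signed-rank with Z-based effect size.

    Returns (Z, p, r) with r = Z / sqrt(N), N = number of paired
    observations entering the test.  All-tied data leaves the statistic
    undefined and returns NaNs.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if d.size < 5:
        raise ValueError("need >= 5 paired observations")
    if np.all(d == 0):
        return float("nan"), float("nan"), float("nan")
    res = sps.wilcoxon(d, method="approx")
    z = float(res.zstatistic)
    return z, float(res.pvalue), effect_size_r(z, d.size)


def effect_size_r(z: float, n: int) -> float:
    """Effect size r = Z / sqrt(N) for a rank test's normal-approximation Z."""
    return z / np.sqrt(n)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p; constant input -> NaNs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
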