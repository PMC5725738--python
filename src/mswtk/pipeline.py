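"""End-to-end study pipeline: simulate -> psychfit -> pweights -> decode ->
nweights -> stats -> report.

Every stage reads only the declared artifacts of earlier stages inside one
study directory, so the pipeline is re-entrant: with ``resume=True`` a
stage whose outputs already exist is skipped.  All randomness flows from
the single config seed; per-stage seeds are derived deterministically and
logged into the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import perceptual_weights as pw
from . import psychometrics as psy
from . import stats_inference as si
from .decoding import decode_subject, forward_model
from .neural_weights import (
    neural_weight_regression,
    neuro_behavioral_correlation,
)
from .stimgen import TrialDesign
from .synthetic_data import SubjectHeterogeneity, load_subject, make_study

log = logging.getLogger("mswtk")

STAGES = ("simulate", "psychfit", "pweights", "decode", "nweights", "stats", "report")


@dataclass
class StudyConfig:
    """Serializable configuration for one synthetic study run.

    Defaults mirror the task parameters (510 trials/block, 20 subjects,
    12 ms stimulus bins, 55 ms decoding windows at 5 ms steps, cluster
    threshold t=1.8 with minimum size 2, 2000/1000 permutations); the
    smaller ``n_boot``/permutation values used by the demo drivers are set
    explicitly in their configs.
    """

    seed: int = 1
    n_subjects: int = 20
    n_trials: int = 510
    equal_rate_fraction: float = 0.02
    condition_weights: list[float] | None = None
    coupling: str = "coupled"
    n_boot: int = 2000
    decode_step_ms: float = 5.0
    decode_span_ms: tuple[float, float] = (24.0, 600.0)
    nweight_span_ms: tuple[float, float] = (24.0, 400.0)
    behav_span_ms: tuple[float, float] = (24.0, 600.0)
    epoch_window_ms: tuple[float, float] = (-200.0, 800.0)
    fs: float = 200.0
    cluster_t_threshold: float = 1.8
    cluster_min_size: int = 2
    cluster_n_perm: int = 1000
    az_n_perm: int = 2000
    az_alpha: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("decode_span_ms", "nweight_span_ms", "behav_span_ms", "epoch_window_ms"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=True)

    def design(self) -> TrialDesign:
        return TrialDesign(
            n_trials=self.n_trials,
            equal_rate_fraction=self.equal_rate_fraction,
            condition_weights=tuple(self.condition_weights) if self.condition_weights else None,
        )

    def cluster_params(self) -> si.ClusterParams:
        return si.ClusterParams(
            t_threshold=self.cluster_t_threshold,
            min_size=self.cluster_min_size,
            n_perm=self.cluster_n_perm,
        )


def _stage_rng(cfg: StudyConfig, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence([cfg.seed, STAGES.index(stage)])
    return np.random.default_rng(ss)


def _done(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


def stage_simulate(cfg: StudyConfig, out: Path, resume: bool = False) -> None:
    study = out / "study"
    if resume and _done([study / "ground_truth.csv"]):
        log.info("simulate: outputs exist, skipping")
        return
    log.info("simulate: %d subjects x %d trials", cfg.n_subjects, cfg.n_trials)
    make_study(
        study, n_subjects=cfg.n_subjects, seed=cfg.seed,
        design=cfg.design(),
        het=SubjectHeterogeneity(coupling=cfg.coupling),
        fs=cfg.fs,
    )


def stage_psychfit(cfg: StudyConfig, out: Path, resume: bool = False) -> None:
    fit_path = out / "psychometrics.csv"
    w_path = out / "psychometric_weights.csv"
    if resume and _done([fit_path, w_path]):
        log.info("psychfit: outputs exist, skipping")
        return
    rng = _stage_rng(cfg, "psychfit")
    fits, weights = [], []
    for sid in range(cfg.n_subjects):
        sub = load_subject(out / "study", sid, with_eeg=False)
        f = psy.subject_psychometrics(sub.trials, n_boot=cfg.n_boot, rng=rng)
        f.insert(0, "subject_id", sid)
        fits.append(f)
        if {"AUD", "VH", "VL"} <= set(f["condition"]):
            w = psy.weights_from_condition_fits(f)
        else:
            # AV-only design: observed weights only (predicted weights
            # need unisensory thresholds)
            obs_w = psy.observed_weights_by_reliability(f)
            w = pd.DataFrame([
                {"reliability": rel, "condition": mod, "w_aud_pred": np.nan,
                 "w_aud_obs": obs_w[rel]}
                for rel, mod in (("high", "AVH"), ("low", "AVL"))
            ])
        w.insert(0, "subject_id", sid)
        weights.append(w)
    pd.concat(fits).to_csv(fit_path, index=False)
    pd.concat(weights).to_csv(w_path, index=False)
    log.info("psychfit: wrote %s", fit_path)


def stage_pweights(cfg: StudyConfig, out: Path, resume: bool = False) -> None:
    path = out / "perceptual_weights.csv"
    az_path = out / "behaviour_az.csv"
    if resume and _done([path, az_path]):
        log.info("pweights: outputs exist, skipping")
        return
    rng = _stage_rng(cfg, "pweights")
    times = np.arange(cfg.behav_span_ms[0], cfg.behav_span_ms[1] + 1, 12.0)
    frames, az_rows = [], []
    for sid in range(cfg.n_subjects):
        sub = load_subject(out / "study", sid, with_eeg=False)
        ws = pw.time_resolved_weights(sub.trials, times=times)
        frames.append(ws.to_frame(sid))
        t_az, az = pw.trial_az_series(sub.trials, times=times, rng=rng)
        az_rows.append(pd.DataFrame({"subject_id": sid, "time_ms": t_az, "az": az}))
    pd.concat(frames).to_csv(path, index=False)
    pd.concat(az_rows).to_csv(az_path, index=False)
    log.info("pweights: wrote %s", path)


def stage_decode(cfg: StudyConfig, out: Path, resume: bool = False) -> None:
    import h5py

    times = np.arange(cfg.decode_span_ms[0], cfg.decode_span_ms[1] + 1e-9, cfg.decode_step_ms)
    paths = [out / f"sub-{sid:02d}_decode.h5" for sid in range(cfg.n_subjects)]
    if resume and _done(paths):
        log.info("decode: outputs exist, skipping")
        return
    for sid, path in enumerate(paths):
        sub = load_subject(out / "study", sid)
        y = decode_subject(sub.eeg, sub.trials, times=times)
        fm = forward_model(y, sub.eeg)
        with h5py.File(path, "w") as f:
            f.create_dataset("y", data=y.y)
            f.create_dataset("times", data=y.times)
            f.create_dataset("trial_id", data=y.trial_id)
            f.create_dataset("forward_model", data=fm)
        log.info("decode: subject %d -> %s", sid, path)


def stage_nweights(cfg: StudyConfig, out: Path, resume: bool = False) -> None:
    import h5py

    path = out / "neural_weights.csv"
    if resume and _done([path]):
        log.info("nweights: outputs exist, skipping")
        return
    frames = []
    for sid in range(cfg.n_subjects):
        sub = load_subject(out / "study", sid, with_eeg=False)
        with h5py.File(out / f"sub-{sid:02d}_decode.h5") as f:
            from .decoding import DiscriminantOutput

            y = DiscriminantOutput(
                y=f["y"][()], times=f["times"][()],
                trial_id=f["trial_id"][()], trained_on=np.empty(0, int),
            )
        nw = neural_weight_regression(y, sub.trials, window=cfg.nweight_span_ms)
        frames.append(nw.to_frame(sid))
    pd.concat(frames).to_csv(path, index=False)
    log.info("nweights: wrote %s", path)


def _pivot(df: pd.DataFrame, value: str) -> dict[str, np.ndarray]:
    """condition -> subject x time array from a long-format weight table."""
    out = {}
    for cond, sub in df.groupby("condition"):
        mat = sub.pivot(index="subject_id", columns="time_ms", values=value)
        out[cond] = mat.to_numpy()
        out["_times_" + cond] = mat.columns.to_numpy(dtype=float)
    return out


def stage_stats(cfg: StudyConfig, out: Path, resume: bool = False) -> None:
    path = out / "clusters.json"
    if resume and _done([path]):
        log.info("stats: outputs exist, skipping")
        return
    rng = _stage_rng(cfg, "stats")
    params = cfg.cluster_params()
    pweights = pd.read_csv(out / "perceptual_weights.csv")
    nweights = pd.read_csv(out / "neural_weights.csv")
    pv = _pivot(pweights, "weight")
    nv = _pivot(nweights, "b")
    report: dict = {}
    contrasts = {
        "perceptual_aud_high_vs_low": ("AVH-aud", "AVL-aud", pv),
        "perceptual_vis_high_vs_low": ("AVH-vis", "AVL-vis", pv),
        "neural_aud_high_vs_low": ("AVH-aud", "AVL-aud", nv),
        "neural_vis_high_vs_low": ("AVH-vis", "AVL-vis", nv),
        "neural_modality_high": ("AVH-aud", "AVH-vis", nv),
        "neural_modality_low": ("AVL-aud", "AVL-vis", nv),
    }
    for name, (a, b, src) in contrasts.items():
        res = si.cluster_permutation(
            src[a], src[b], times=src["_times_" + a], params=params, rng=rng
        )
        report[name] = res.to_dict()

    # neuro-behavioural correlation of reliability influences
    d_b = (pv["AVH-aud"] - pv["AVH-vis"]) - (pv["AVL-aud"] - pv["AVL-vis"])
    d_n = (nv["AVH-aud"] - nv["AVH-vis"]) - (nv["AVL-aud"] - nv["AVL-vis"])
    rho, res = neuro_behavioral_correlation(
        d_n, d_b,
        neural_times=nv["_times_AVH-aud"],
        perceptual_times=pv["_times_AVH-aud"],
        params=params, rng=rng,
    )
    report["neuro_behavioural_correlation"] = res.to_dict()
    report["neuro_behavioural_rho"] = [None if not np.isfinite(r) else float(r) for r in rho]
    with open(path, "w") as f:
        json.dump(report, f, indent=1)
    log.info("stats: wrote %s", path)


def stage_report(cfg: StudyConfig, out: Path, resume: bool = False) -> None:
    path = out / "report.json"
    artifacts = [
        "psychometrics.csv", "psychometric_weights.csv",
        "perceptual_weights.csv", "behaviour_az.csv",
        "neural_weights.csv", "clusters.json",
    ]
    hashes = {}
    for name in artifacts:
        p = out / name
        if p.exists():
            hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    report = {
        "config": asdict(cfg),
        "stage_seeds": {s: [cfg.seed, STAGES.index(s)] for s in STAGES},
        "artifact_sha256": hashes,
    }
    with open(path, "w") as f:
        json.dump(report, f, indent=1, sort_keys=True, default=str)
    _figures(cfg, out)
    log.info("report: wrote %s", path)


def _figures(cfg: StudyConfig, out: Path) -> None:
    """Az curve, weight time courses and neuro-behavioural correlation."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 3.5))
    az = pd.read_csv(out / "behaviour_az.csv")
    g = az.groupby("time_ms")["az"].mean()
    axes[0].plot(g.index, g.values)
    axes[0].axhline(0.5, ls="--", c="k", lw=0.8)
    axes[0].set(xlabel="time (ms)", ylabel="Az", title="evidence-model performance")

    nweights = pd.read_csv(out / "neural_weights.csv")
    for cond, sub in nweights.groupby("condition"):
        m = sub.groupby("time_ms")["b"].mean()
        axes[1].plot(m.index, m.values, label=cond)
    axes[1].legend(fontsize=7)
    axes[1].set(xlabel="time (ms)", ylabel="b", title="neural weights")

    with open(out / "clusters.json") as f:
        clusters = json.load(f)
    rho = np.array([np.nan if r is None else r
                    for r in clusters["neuro_behavioural_rho"]], dtype=float)
    nv_times = np.sort(nweights["time_ms"].unique())
    axes[2].plot(nv_times, rho)
    for c in clusters["neuro_behavioural_correlation"]["clusters"]:
        if c["p_value"] < 0.05:
            axes[2].axvspan(c["t_start"], c["t_end"], alpha=0.2, color="orange")
    axes[2].axhline(0, ls="--", c="k", lw=0.8)
    axes[2].set(xlabel="time (ms)", ylabel="rho", title="neuro-behavioural correlation")
    fig.tight_layout()
    fig.savefig(out / "summary.png", dpi=120)
    plt.close(fig)


_STAGE_FN = {
    "simulate": stage_simulate,
    "psychfit": stage_psychfit,
    "pweights": stage_pweights,
    "decode": stage_decode,
    "nweights": stage_nweights,
    "stats": stage_stats,
    "report": stage_report,
}


def run_pipeline(
    cfg: StudyConfig,
    out_dir: str | Path,
    *,
    stages: tuple[str, ...] = STAGES,
    resume: bool = False,
) -> Path:
    """Run the requested stages in order inside one study directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    for s in stages:
        if s not in _STAGE_FN:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
        try:
            _STAGE_FN[s](cfg, out, resume=resume)
        except FileNotFoundError as err:
            raise RuntimeError(
                f"stage {s!r} is missing an input artifact ({err}); "
                f"run earlier stages first"
            ) from err
    return out
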