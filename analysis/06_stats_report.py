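"""Cluster statistics and the summary report/figures for the demo study.

Runs the cluster-permutation contrasts (reliability and modality effects
on perceptual and neural weights) and the cluster-corrected
neuro-behavioural correlation, then writes clusters.json, report.json and
summary.png.
"""

import json
import runpy
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = runpy.run_path(Path(__file__).parent / "00_config.py")

from mswtk.pipeline import run_pipeline  # noqa: E402

if __name__ == "__main__":
    cfg = cfg_mod["demo_config"]()
    out = run_pipeline(cfg, cfg_mod["STUDY_DIR"], stages=("stats", "report"), resume=True)
    clusters = json.loads((out / "clusters.json").read_text())
    for name, res in clusters.items():
        if not isinstance(res, dict) or "clusters" not in res:
            continue
        sig = [c for c in res["clusters"] if c["p_value"] < 0.05]
        if sig:
            spans = ", ".join(
                f"{c['t_start']:.0f}-{c['t_end']:.0f} ms (p={c['p_value']:.3f})"
                for c in sig
            )
            print(f"{name}: {spans}")
        else:
            print(f"{name}: no significant clusters")
    print(f"\nreport and figures in {out}")
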