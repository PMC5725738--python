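"""Time-resolved perceptual weights from accumulated sensory evidence.

Per subject and reliability condition, logistic regression of choice on
the accumulated auditory/visual event counts on a 12 ms grid, plus the
cross-validated Az of the evidence model.  Writes perceptual_weights.csv
and behaviour_az.csv and prints when evidence becomes predictive.
"""

import runpy
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = runpy.run_path(Path(__file__).parent / "00_config.py")

from mswtk.pipeline import run_pipeline  # noqa: E402

if __name__ == "__main__":
    cfg = cfg_mod["demo_config"]()
    out = run_pipeline(cfg, cfg_mod["STUDY_DIR"], stages=("pweights",), resume=True)
    az = pd.read_csv(out / "behaviour_az.csv")
    g = az.groupby("time_ms")["az"].mean()
    above = g[g > 0.55]
    print("group Az of the evidence model peaks at "
          f"{g.max():.3f} ({g.idxmax():.0f} ms)")
    if len(above):
        print(f"Az exceeds 0.55 from {above.index.min():.0f} ms onwards")
    w = pd.read_csv(out / "perceptual_weights.csv")
    late = w[w["time_ms"] >= 300]
    m = late.groupby("condition")["weight"].mean().round(3)
    print("mean normalised weights (>=300 ms):", m.to_dict())
    print("auditory dominance in both reliability conditions:",
          bool(m["AVH-aud"] > m["AVH-vis"] and m["AVL-aud"] > m["AVL-vis"]))
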