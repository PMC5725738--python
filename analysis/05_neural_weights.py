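"""Neural sensory weights: regress discriminant output on accumulated rates.

Per subject, reliability condition and time point, OLS of Y on the
accumulated auditory/visual counts (unnormalised coefficients).  Writes
neural_weights.csv and prints the group reliability contrasts.
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
    out = run_pipeline(cfg, cfg_mod["STUDY_DIR"], stages=("nweights",), resume=True)
    nw = pd.read_csv(out / "neural_weights.csv")
    band = nw[(nw["time_ms"] >= 120) & (nw["time_ms"] <= 300)]
    m = band.groupby("condition")["b"].mean().round(3)
    print("mean neural weights, 120-300 ms:", m.to_dict())
    print("visual weight drops under low reliability:",
          bool(m["AVH-vis"] > m["AVL-vis"]))
    print("auditory weight rises under low reliability:",
          bool(m["AVL-aud"] > m["AVH-aud"]))
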