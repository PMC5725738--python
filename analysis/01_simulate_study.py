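"""Simulate the demo study: streams, choices and 64-channel EEG epochs.

Writes per-subject trial tables (CSV) and epochs (HDF5) plus the ground
truth under results/demo_study/study/.
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
    out = run_pipeline(cfg, cfg_mod["STUDY_DIR"], stages=("simulate",), resume=True)
    truth = pd.read_csv(out / "study" / "ground_truth.csv")
    print(f"simulated {len(truth)} subjects x {cfg.n_trials} trials (seed {cfg.seed})")
    print("true auditory weights (high reliability):",
          truth["w_aud_high"].round(2).tolist())
    print("true weight shift low-high:",
          (truth["w_aud_low"] - truth["w_aud_high"]).round(2).tolist())
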