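"""Fit psychometric curves per condition and derive perceptual weights.

For each subject: cumulative-Gaussian fits (PSE mu, threshold sigma) per
condition, then predicted weights from unisensory thresholds and observed
weights from audio-visual PSE shifts.  Writes psychometrics.csv and
psychometric_weights.csv and prints the group medians next to the
generator's true weights.
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
    out = run_pipeline(cfg, cfg_mod["STUDY_DIR"], stages=("psychfit",), resume=True)
    fits = pd.read_csv(out / "psychometrics.csv")
    w = pd.read_csv(out / "psychometric_weights.csv")
    truth = pd.read_csv(out / "study" / "ground_truth.csv")
    med = fits.groupby("condition")[["mu", "sigma"]].median().round(2)
    print("median PSE / threshold per condition:")
    print(med.to_string())
    obs = w.groupby("reliability")["w_aud_obs"].median().round(3)
    print("\nmedian observed auditory weight:", obs.to_dict())
    print("generator median true weights: high",
          truth["w_aud_high"].median().round(3),
          "low", truth["w_aud_low"].median().round(3))
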