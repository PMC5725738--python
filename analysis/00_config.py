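"""Shared demo-study configuration for the numbered analysis drivers.

An 8-subject study with the full 9-condition design (510 trials/subject),
EEG decoded on a 12 ms grid over 24-400 ms.  Smaller than a real study but
large enough for every stage to produce meaningful group statistics in a
few minutes on one CPU.  All drivers write into results/demo_study/.
"""

from pathlib import Path

from mswtk.pipeline import StudyConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_DIR = RESULTS / "demo_study"


def demo_config() -> StudyConfig:
    return StudyConfig(
        seed=1,
        n_subjects=8,
        n_trials=510,
        n_boot=200,
        decode_step_ms=12.0,
        decode_span_ms=(24.0, 400.0),
        epoch_window_ms=(-100.0, 460.0),
        cluster_n_perm=500,
        az_n_perm=0,
    )
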