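#!/usr/bin/env python
"""Simulate and analyse the rhythmic vs. speech-like comparison at 3 Hz.

Two conditions share the dominant 3 Hz rate: a regular raised-cosine stream
and a quasi-rhythmic speech-like stream (jittered pulse train passing the
~3 Hz gate). The speech-like condition's true binding window is planted 17%
wider than the rhythmic one (each subject's base width x 1.17), so the
pipeline should report a wider mean TBW for speech-like streams after
fitting and exclusion.
"""

import shutil
from pathlib import Path

import pandas as pd

from avtbw import RunConfig, run_pipeline
from avtbw.pipeline import build_stimuli

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "exp3_run"
RESULTS = ROOT / "results"
SEED = 13
N_SUBJECTS = 30
TBW_SCALE = {"rhythmic-3Hz": 1.0, "speech-like": 1.17}

cfg = RunConfig.from_preset("exp3")
stimuli = build_stimuli(cfg, seed=SEED)
tokens = [k for k in stimuli if k.startswith("speech-like-")]
print(f"speech-like tokens passing the ~3 Hz gate: {len(tokens)} ({', '.join(tokens)})")

run_pipeline(cfg, SCRATCH, seed=SEED, n_subjects=N_SUBJECTS, condition_tbw_scale=TBW_SCALE)
RESULTS.mkdir(exist_ok=True)
shutil.copy(SCRATCH / "summary.csv", RESULTS / "exp3_summary.csv")

summary = pd.read_csv(SCRATCH / "summary.csv")
tbw = summary[summary.measure == "tbw_ms"].set_index("condition_label")
print("\nmean TBW (ms) by condition over kept subjects:")
print(tbw[["n", "mean", "se"]].round(2).to_string())
wider = tbw.loc["speech-like", "mean"] > tbw.loc["rhythmic-3Hz", "mean"]
print("\nspeech-like TBW wider than rhythmic:", bool(wider))
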