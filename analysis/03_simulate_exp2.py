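#!/usr/bin/env python
"""Simulate and analyse the fixed-pulse-count variant (3 pulses per stream).

Same SOA grid and frequencies as the fixed-duration experiment, but every
stream carries exactly 3 pulses, so durations fall to 3/1.5/1 s at 1/2/3 Hz.
The same frequency-dependent true binding windows are planted; recovering
the same ordering here shows the analysis separates stimulation frequency
from pulse count and stream duration.
"""

import shutil
from pathlib import Path

import pandas as pd

from avtbw import RunConfig, run_pipeline
from avtbw.envelopes import make_sinusoidal_envelope, make_stream_spec, count_pulses

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "exp2_run"
RESULTS = ROOT / "results"
SEED = 12
N_SUBJECTS = 30
TBW_SCALE = {"rhythmic-1Hz-3p": 1.31, "rhythmic-2Hz-3p": 0.88, "rhythmic-3Hz-3p": 0.78}

cfg = RunConfig.from_preset("exp2")
for cond in cfg.conditions:
    duration, n_pulses = make_stream_spec(cond.stream_mode, cond.freq_hz, cond.stream_value)
    counted = count_pulses(make_sinusoidal_envelope(cond.freq_hz, duration, cfg.sample_rate_hz))
    print(f"{cond.label}: {duration:g} s stream, {counted} pulses")

run_pipeline(cfg, SCRATCH, seed=SEED, n_subjects=N_SUBJECTS, condition_tbw_scale=TBW_SCALE)
RESULTS.mkdir(exist_ok=True)
shutil.copy(SCRATCH / "summary.csv", RESULTS / "exp2_summary.csv")

summary = pd.read_csv(SCRATCH / "summary.csv")
tbw = summary[summary.measure == "tbw_ms"].set_index("condition_label")
print("\nmean TBW (ms) by condition over kept subjects:")
print(tbw[["n", "mean", "se"]].round(2).to_string())
order = tbw["mean"]
print("\nTBW ordering 1 Hz > 2 Hz > 3 Hz recovered:",
      bool(order["rhythmic-1Hz-3p"] > order["rhythmic-2Hz-3p"] > order["rhythmic-3Hz-3p"]))
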