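#!/usr/bin/env python
"""Simulate and analyse a fixed-duration frequency experiment (1/2/3 Hz).

Thirty synthetic observers run the 165-trial session (11 SOAs x 3 rhythmic
conditions x 5 reps). True binding windows are scaled per condition to
shrink with stimulation frequency (ratios 1.31/0.88/0.78 of each subject's
base width, matching the relative group means the design is meant to
expose), so the analysis should recover the 1 Hz > 2 Hz > 3 Hz ordering
after fitting and exclusion. Bulky per-trial artifacts go to scratch/;
summary tables land in results/.
"""

import shutil
from pathlib import Path

import pandas as pd

from avtbw import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "exp1_run"
RESULTS = ROOT / "results"
SEED = 11
N_SUBJECTS = 30
TBW_SCALE = {"rhythmic-1Hz": 1.31, "rhythmic-2Hz": 0.88, "rhythmic-3Hz": 0.78}

cfg = RunConfig.from_preset("exp1")
run_pipeline(cfg, SCRATCH, seed=SEED, n_subjects=N_SUBJECTS, condition_tbw_scale=TBW_SCALE)

RESULTS.mkdir(exist_ok=True)
for name in ("parameters.csv", "summary.csv"):
    shutil.copy(SCRATCH / name, RESULTS / f"exp1_{name}")

fits = pd.read_csv(SCRATCH / "parameters.csv")
summary = pd.read_csv(SCRATCH / "summary.csv")
n_excl_g = N_SUBJECTS - fits.groupby("subject_id")["kept_gauss"].first().sum()
n_excl_l = N_SUBJECTS - fits.groupby("subject_id")["kept_logistic"].first().sum()
print(f"simulated {N_SUBJECTS} subjects; excluded {n_excl_g} (Gaussian adj R2 < .5), "
      f"{n_excl_l} (logistic adj R2 < .3 on either side)")

tbw = summary[summary.measure == "tbw_ms"].set_index("condition_label")
print("\nmean TBW (ms) by condition over kept subjects:")
print(tbw[["n", "mean", "se"]].round(2).to_string())
order = tbw["mean"]
print("\nTBW ordering 1 Hz > 2 Hz > 3 Hz recovered:",
      bool(order["rhythmic-1Hz"] > order["rhythmic-2Hz"] > order["rhythmic-3Hz"]))
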