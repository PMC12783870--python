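#!/usr/bin/env python
"""Verify the stimulus arithmetic and spectral content of every condition.

Builds the rhythmic streams of the fixed-duration design (3 s at 1/2/3 Hz),
the fixed-pulse design (3 pulses, so 3/1.5/1 s), and a pool of jittered
speech-like tokens; counts pulses from the rendered envelopes, measures each
envelope's dominant frequency, and reports the ~3 Hz gate pass rate of the
speech-like pool. Writes results/stimulus_checks.csv.
"""

from pathlib import Path

import pandas as pd

from avtbw import (
    count_pulses,
    fft_dominant_frequency,
    make_quasi_rhythmic_envelope,
    make_sinusoidal_envelope,
    make_stream_spec,
    select_speech_like,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 11

rows = []
for mode, value in (("fixed_duration", 3.0), ("fixed_pulses", 3)):
    for freq in (1, 2, 3):
        duration, n_pulses = make_stream_spec(mode, freq, value)
        env = make_sinusoidal_envelope(freq, duration, 1000)
        profile = fft_dominant_frequency(env)
        rows.append(
            {
                "design": mode,
                "freq_hz": freq,
                "duration_s": duration,
                "expected_pulses": n_pulses,
                "counted_pulses": count_pulses(env),
                "dominant_freq_hz": profile.dominant_frequency,
            }
        )

table = pd.DataFrame(rows)
RESULTS.mkdir(exist_ok=True)
table.to_csv(RESULTS / "stimulus_checks.csv", index=False)
print(table.to_string(index=False))

n_pool = 500
pool = [make_quasi_rhythmic_envelope(3.0, 0.2, 0.3, 3.0, 1000, seed=SEED + k) for k in range(n_pool)]
kept = select_speech_like(pool, target_freq=3.0, tol=0.5)
print(
    f"\nspeech-like pool: {len(kept)}/{n_pool} tokens "
    f"({100 * len(kept) / n_pool:.1f}%) show a dominant peak within 3.0 +/- 0.5 Hz; "
    f"the stimulus builder keeps the first 5 gate-passers."
)
assert (table.counted_pulses == table.expected_pulses).all()
print("pulse counts match the design arithmetic for every condition.")
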