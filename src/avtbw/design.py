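"""Factorial trial designs for simultaneity-judgement experiments.

A design crosses SOA x condition x repetition and shuffles the full list
once with a seeded uniform permutation. The canonical grid spans -500 to
+500 ms in 100 ms steps (11 SOAs); 11 SOAs x 3 conditions x 5 repetitions
gives the 165-trial session used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidDesignError

__all__ = ["Condition", "TrialSpec", "default_soa_grid", "build_design", "design_to_frame"]


@dataclass(frozen=True)
class Condition:
    """One stimulus condition: a modulation mode and its dominant frequency.

    ``stream_mode``/``stream_value`` record how the stream length was fixed:
    ("fixed_duration", seconds) or ("fixed_pulses", count). Speech-like
    conditions carry the label of the envelope token they play.
    """

    label: str
    mode: str  # "rhythmic" | "speech-like"
    freq_hz: float
    stream_mode: str = "fixed_duration"
    stream_value: float = 3.0
    envelope_label: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("rhythmic", "speech-like"):
            raise InvalidArgumentError(f"unknown condition mode {self.mode!r}")
        if self.freq_hz <= 0:
            raise InvalidArgumentError("freq_hz must be positive")


@dataclass(frozen=True)
class TrialSpec:
    """One designed trial: its post-shuffle position, cell, and replicate."""

    trial_index: int
    condition: Condition
    soa_ms: float
    repetition: int  # 1-based


def default_soa_grid() -> list[float]:
    """The canonical 11-point SOA grid: -500 .. +500 ms in 100 ms steps."""
    return [float(s) for s in range(-500, 501, 100)]


def build_design(
    soas: Sequence[float],
    conditions: Sequence[Condition],
    n_reps: int,
    seed: int,
) -> list[TrialSpec]:
    """Enumerate the factorial cells, replicate, and shuffle.

    Every (condition, soa) cell appears exactly ``n_reps`` times. The order
    is a single uniform random permutation of the full list, reproducible
    under ``seed``.
    """
    soas = [float(s) for s in soas]
    if not soas:
        raise InvalidDesignError("soas must be non-empty")
    if len(set(soas)) != len(soas):
        raise InvalidDesignError("duplicate SOAs in the design grid")
    if not conditions:
        raise InvalidDesignError("conditions must be non-empty")
    if n_reps < 1:
        raise InvalidDesignError("n_reps must be >= 1")

    cells = [
        (cond, soa, rep)
        for cond in conditions
        for soa in soas
        for rep in range(1, n_reps + 1)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cells))
    return [
        TrialSpec(trial_index=i, condition=cells[j][0], soa_ms=cells[j][1], repetition=cells[j][2])
        for i, j in enumerate(order)
    ]


def design_to_frame(trials: Sequence[TrialSpec], subject_id: str | None = None) -> pd.DataFrame:
    """Tidy trial-list table (one row per trial, in presentation order)."""
    rows = [
        {
            "trial_index": t.trial_index,
            "condition_label": t.condition.label,
            "mode": t.condition.mode,
            "freq_hz": t.condition.freq_hz,
            "soa_ms": t.soa_ms,
            "repetition": t.repetition,
        }
        for t in trials
    ]
    frame = pd.DataFrame(rows)
    if subject_id is not None:
        frame.insert(0, "subject_id", subject_id)
    return frame
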